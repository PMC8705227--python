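"""From labeled voxel series to interpolated, noise-regularized region series.

The stages, in pipeline order:

1. Per-voxel two-group (planning vs execution) one-way ANOVA F scores;
   rest/fixation volumes never enter the computation.
2. Voxel selection: the top-``n_keep`` scores (default 10,000) or an automated
   elbow on the sorted-score curve; cerebellar and unassigned voxels are never
   selected.
3. Region averaging: each retained region is represented by the mean series of
   its selected voxels; regions with no selected voxels become flat zero rows
   and are flagged inactive.
4. Temporal upsampling by cubic splines, confined to within-puzzle segments,
   inserting ``z`` points per gap so a puzzle of n measured volumes yields
   ``n + z*(n-1)`` columns.
5. Label assignment for interpolated columns (nearest measured volume).
6. Informed Gaussian noise: per-region noise drawn from
   N(alpha_noise * mean(r_j), beta_noise * var(r_j)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .io_core import (
    EventTable,
    LabeledVoxelSeries,
    Parcellation,
    TASK_LABELS,
    ValidationError,
)

log = logging.getLogger("dynmesh")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class VoxelScoreTable:
    f_score: np.ndarray  # (n_voxels,)
    msb: np.ndarray
    msw: np.ndarray
    df_between: int
    df_within: int
    flagged: np.ndarray  # MSW == 0 voxels (score +inf)
    selected: np.ndarray | None = None

    @property
    def n_selected(self) -> int:
        return 0 if self.selected is None else int(self.selected.sum())


@dataclass
class RegionSeries:
    """Region x time matrix of representative BOLD responses.

    Rows follow the canonical retained-region order (``region_ids``); columns
    carry a condition label, a puzzle id (-1 outside puzzles), a measured /
    interpolated flag and, for measured columns, the original measured-volume
    index (``measured_index``; -1 for interpolated columns).
    """

    values: np.ndarray  # (M, T)
    labels: np.ndarray  # (T,) str ("" = not yet assigned)
    puzzle_ids: np.ndarray  # (T,) int
    measured_mask: np.ndarray  # (T,) bool
    z: int
    active_regions: np.ndarray  # (M,) bool
    selected_sets: list  # per region, indices into the voxel series
    region_ids: np.ndarray
    measured_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.measured_index is None:
            idx = np.full(self.values.shape[1], -1, dtype=int)
            idx[self.measured_mask] = np.arange(int(self.measured_mask.sum()))
            self.measured_index = idx

    @property
    def M(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def task_columns(self) -> np.ndarray:
        return np.isin(self.labels, TASK_LABELS)

    def segments(self) -> list[np.ndarray]:
        """Column-index blocks of contiguous same-puzzle task columns."""
        out: list[np.ndarray] = []
        cols = np.arange(self.n_columns)
        task = self.task_columns()
        start = None
        for c in cols:
            if task[c] and (start is None):
                start = c
            elif start is not None and (
                not task[c] or self.puzzle_ids[c] != self.puzzle_ids[start]
            ):
                out.append(cols[start:c])
                start = c if task[c] else None
        if start is not None:
            out.append(cols[start:])
        return out


@dataclass
class NoiseConfig:
    alpha_noise: float = 0.025
    beta_noise: float = 0.075
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_noise < 0 or self.beta_noise < 0:
            raise ValidationError("noise scaling factors must be non-negative")


# ---------------------------------------------------------------------------
# ANOVA scores and voxel selection
# ---------------------------------------------------------------------------

def compute_f_scores(
    voxels: LabeledVoxelSeries, events: EventTable | None = None
) -> VoxelScoreTable:
    """Per-voxel one-way ANOVA F over the planning and execution groups.

    ``F = MSB / MSW`` with ``df_between = 1`` (two groups) and
    ``df_within = n_task_volumes - 2``.  Constant voxels (MSW = 0) score +inf
    and are flagged rather than silently topping the ranking.
    """
    labels = events.labels if events is not None else voxels.labels
    if labels is None:
        raise ValidationError("voxel series has no labels; pass an EventTable")
    labels = np.asarray(labels, dtype=object)
    masks = [labels == g for g in TASK_LABELS]
    ns = [int(m.sum()) for m in masks]
    if min(ns) < 2:
        raise ValidationError(f"each group needs >= 2 volumes, got planning/execution = {ns}")
    n = sum(ns)
    df_between = len(TASK_LABELS) - 1
    df_within = n - len(TASK_LABELS)

    data = voxels.data
    group_means = [data[:, m].mean(axis=1) for m in masks]
    grand = sum(gm * ng for gm, ng in zip(group_means, ns)) / n
    ssb = sum(ng * (gm - grand) ** 2 for gm, ng in zip(group_means, ns))
    ssw = sum(((data[:, m] - gm[:, None]) ** 2).sum(axis=1) for m, gm in zip(masks, group_means))
    msb = ssb / df_between
    msw = ssw / df_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    flagged = np.isfinite(msb) & (msw == 0)
    f[flagged] = np.inf
    return VoxelScoreTable(
        f_score=f, msb=msb, msw=msw, df_between=df_between, df_within=df_within, flagged=flagged
    )


def elbow_index(sorted_scores: np.ndarray) -> int:
    """Index of maximum perpendicular distance between the descending score
    curve and the chord joining its endpoints."""
    y = np.asarray(sorted_scores, dtype=float)
    n = y.size
    if n < 3:
        return n - 1
    x = np.arange(n, dtype=float)
    chord = np.array([x[-1] - x[0], y[-1] - y[0]])
    chord = chord / np.linalg.norm(chord)
    rel = np.stack([x - x[0], y - y[0]])
    # perpendicular distance = |rel - (rel . chord) chord|
    proj = chord @ rel
    perp = rel - np.outer(chord, proj)
    return int(np.argmax(np.linalg.norm(perp, axis=0)))


def select_voxels(
    scores: VoxelScoreTable,
    n_keep: int | None = 10_000,
    mode: str = "top",
    parcellation: Parcellation | None = None,
    include_flagged: bool = False,
) -> np.ndarray:
    """Top-``n_keep`` voxels by F score, or the automated elbow cut.

    Cerebellar and atlas-unassigned voxels are excluded before ranking, as are
    non-finite scores and (by default) flagged constant voxels.  Ties break by
    voxel index so selection is monotone in ``n_keep``.
    """
    f = scores.f_score.copy()
    eligible = np.isfinite(f)
    if include_flagged:
        eligible |= scores.flagged
        f[scores.flagged] = np.inf
    else:
        eligible &= ~scores.flagged
    if parcellation is not None:
        cereb_ids = set(parcellation.region_ids[parcellation.cerebellum_flags].tolist())
        vox_region = parcellation.voxel_labels
        eligible &= vox_region != 0
        if cereb_ids:
            eligible &= ~np.isin(vox_region, list(cereb_ids))
    idx = np.where(eligible)[0]
    order = idx[np.lexsort((idx, -f[idx]))]  # score desc, index asc on ties
    if mode == "elbow":
        n_keep = elbow_index(f[order]) + 1
    elif mode != "top":
        raise ValidationError(f"unknown selection mode {mode!r}")
    if n_keep is None:
        n_keep = order.size
    if n_keep > order.size:
        warnings.warn(
            f"n_keep={n_keep} exceeds the {order.size} eligible voxels; keeping all", stacklevel=2
        )
        n_keep = order.size
    mask = np.zeros(f.size, dtype=bool)
    mask[order[:n_keep]] = True
    scores.selected = mask
    return mask


# ---------------------------------------------------------------------------
# Region averaging and summaries
# ---------------------------------------------------------------------------

def average_regions(
    voxels: LabeledVoxelSeries, mask: np.ndarray, parcellation: Parcellation
) -> RegionSeries:
    """Mean selected-voxel series per retained region; empty regions get a zero
    row and are flagged inactive."""
    if voxels.labels is None:
        raise ValidationError("attach events to the voxel series before averaging")
    retained = parcellation.retained_ids()
    M = retained.size
    T = voxels.n_volumes
    values = np.zeros((M, T))
    active = np.zeros(M, dtype=bool)
    sets: list[np.ndarray] = []
    for row, rid in enumerate(retained):
        members = np.where(mask & (parcellation.voxel_labels == rid))[0]
        sets.append(members)
        if members.size:
            values[row] = voxels.data[members].mean(axis=0)
            active[row] = True
    return RegionSeries(
        values=values,
        labels=np.asarray(voxels.labels, dtype=object),
        puzzle_ids=np.asarray(voxels.puzzle_ids, dtype=int),
        measured_mask=np.ones(T, dtype=bool),
        z=0,
        active_regions=active,
        selected_sets=sets,
        region_ids=retained,
    )


def region_summary(series_list: list[RegionSeries], parcellation: Parcellation | None = None):
    """Across-subject descriptive table: mean and (population) variance of each
    region's activation, plus selected-voxel counts and percentages."""
    import pandas as pd

    if not series_list:
        raise ValidationError("need at least one subject")
    ref = series_list[0]
    means = np.stack([s.values.mean(axis=1) for s in series_list])  # (n_subjects, M)
    counts = np.stack([[len(zj) for zj in s.selected_sets] for s in series_list])
    out = pd.DataFrame(
        {
            "region_id": ref.region_ids,
            "mean_activation": means.mean(axis=0),
            "var_activation": means.var(axis=0),  # population variance
            "mean_selected_voxels": counts.mean(axis=0),
        }
    )
    if parcellation is not None:
        totals = np.array(
            [(parcellation.voxel_labels == rid).sum() for rid in ref.region_ids], dtype=float
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            out["pct_selected_voxels"] = np.where(
                totals > 0, 100.0 * counts.mean(axis=0) / totals, 0.0
            )
    return out


# ---------------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------------

def interpolate(series: RegionSeries, z: int) -> RegionSeries:
    """Cubic-spline upsampling of every within-puzzle segment by ``z`` points
    per gap.  Splines never cross rest gaps; rest/fixation columns pass
    through unchanged.  A segment of n measured volumes yields n + z*(n-1)
    columns, with the measured values reproduced exactly at the knots.
    """
    if z < 0:
        raise ValidationError("z must be >= 0")
    if not np.all(series.measured_mask):
        raise ValidationError("series is already interpolated")
    if z == 0:
        return series

    segs = series.segments()
    seg_start = {int(s[0]): s for s in segs}
    cols_v: list[np.ndarray] = []
    cols_lab: list = []
    cols_pid: list[int] = []
    cols_meas: list[bool] = []
    cols_midx: list[int] = []
    c = 0
    T = series.n_columns
    while c < T:
        seg = seg_start.get(c)
        if seg is None:
            cols_v.append(series.values[:, c])
            cols_lab.append(series.labels[c])
            cols_pid.append(int(series.puzzle_ids[c]))
            cols_meas.append(True)
            cols_midx.append(int(series.measured_index[c]))
            c += 1
            continue
        n = seg.size
        y = series.values[:, seg]
        if n == 1:
            warnings.warn("puzzle segment with a single measured volume passed through", stacklevel=2)
            grid = np.array([0.0])
            vals = y
        else:
            x = np.arange(n, dtype=float)
            grid = np.linspace(0.0, n - 1.0, n + z * (n - 1))
            if n == 2:
                # two knots: the cubic degenerates to the straight line
                vals = y[:, [0]] + (y[:, [1]] - y[:, [0]]) * grid[None, :]
            else:
                vals = CubicSpline(x, y, axis=1)(grid)
        for k, g in enumerate(grid):
            measured = k % (z + 1) == 0
            src = seg[int(round(g))] if measured else seg[0]
            cols_v.append(vals[:, k])
            cols_lab.append(series.labels[seg[k // (z + 1)]] if measured else "")
            cols_pid.append(int(series.puzzle_ids[seg[0]]))
            cols_meas.append(measured)
            cols_midx.append(int(series.measured_index[seg[k // (z + 1)]]) if measured else -1)
        c = int(seg[-1]) + 1

    return RegionSeries(
        values=np.stack(cols_v, axis=1),
        labels=np.array(cols_lab, dtype=object),
        puzzle_ids=np.array(cols_pid),
        measured_mask=np.array(cols_meas),
        z=z,
        active_regions=series.active_regions,
        selected_sets=series.selected_sets,
        region_ids=series.region_ids,
        measured_index=np.array(cols_midx),
    )


def assign_interpolated_labels(series: RegionSeries) -> RegionSeries:
    """Give every interpolated column the label of its nearest measured column
    (left neighbor on the exact midpoint, which only arises for odd ``z``)."""
    labels = np.asarray(series.labels, dtype=object).copy()
    measured = np.where(series.measured_mask)[0]
    for c in np.where(~series.measured_mask)[0]:
        d = np.abs(measured - c)
        labels[c] = labels[measured[int(np.argmin(d))]]
    series.labels = labels
    return series


# ---------------------------------------------------------------------------
# Informed noise
# ---------------------------------------------------------------------------

def inject_noise(series: RegionSeries, cfg: NoiseConfig) -> RegionSeries:
    """Add per-region colorful Gaussian noise tau_j ~ N(alpha*mu_j, beta*var_j).

    mu_j and var_j are computed over the run's task-labeled columns; inactive
    (flat zero) regions are left untouched.  With alpha = beta = 0 the series
    is returned unchanged.
    """
    if cfg.alpha_noise == 0 and cfg.beta_noise == 0:
        return series
    rng = np.random.default_rng(cfg.seed)
    task = series.task_columns()
    if not task.any():
        raise ValidationError("no task columns to estimate noise moments from")
    mu = series.values[:, task].mean(axis=1)
    var = series.values[:, task].var(axis=1)
    noise = rng.normal(
        loc=cfg.alpha_noise * mu[:, None],
        scale=np.sqrt(cfg.beta_noise * var)[:, None],
        size=series.values.shape,
    )
    noise[~series.active_regions] = 0.0
    series.values = series.values + noise
    return series


# ---------------------------------------------------------------------------
# Spectrum helpers (interpolation sanity checks)
# ---------------------------------------------------------------------------

def amplitude_spectrum(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Single-sided amplitude spectrum of a 1D signal sampled at ``fs`` Hz."""
    x = np.asarray(x, dtype=float)
    n = x.size
    spec = np.abs(np.fft.rfft(x)) / n
    spec[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, spec


def dominant_frequency(x: np.ndarray, fs: float, skip_dc: bool = True) -> float:
    freqs, spec = amplitude_spectrum(x, fs)
    start = 1 if skip_dc and spec.size > 1 else 0
    return float(freqs[start + int(np.argmax(spec[start:]))])


# ---------------------------------------------------------------------------
# Convenience pipeline
# ---------------------------------------------------------------------------

def preprocess_run(
    voxels: LabeledVoxelSeries,
    events: EventTable,
    parcellation: Parcellation,
    n_keep: int | None = 10_000,
    selection_mode: str = "top",
    z: int = 8,
    noise: NoiseConfig | None = NoiseConfig(),
) -> RegionSeries:
    """Full preprocessing chain for one run (scores -> selection -> averaging ->
    interpolation -> label assignment -> noise)."""
    voxels.attach_events(events)
    scores = compute_f_scores(voxels, events)
    mask = select_voxels(scores, n_keep=n_keep, mode=selection_mode, parcellation=parcellation)
    series = average_regions(voxels, mask, parcellation)
    series = interpolate(series, z)
    series = assign_interpolated_labels(series)
    if noise is not None:
        series = inject_noise(series, noise)
    return series
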