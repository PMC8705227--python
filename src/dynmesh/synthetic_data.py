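"""Synthetic multi-subject fMRI-like recordings with known mesh connectivity.

The generator emulates the structure of a Tower-of-London style study: runs of
timed puzzles, each with a planning block followed by an execution block, and
rest/fixation periods in between.  Region signals follow a linear latent
recursion driven by a known ground-truth coupling matrix so that downstream
network estimation has a recoverable target; voxels are noisy copies of their
region's latent signal, and a configurable fraction of voxels additionally
carry a condition effect (the substrate for voxel selection and decoding).

Defaults mirror the study conditions: 18 subjects x 4 runs, 18 puzzles per
run at TR = 1 s, mean planning/execution lengths of 5.91 / 5.63 measured
volumes per puzzle, 12 s rest after each puzzle and a 28 s closing fixation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_core import EventTable, LabeledVoxelSeries, Parcellation, ValidationError


@dataclass
class SyntheticConfig:
    n_subjects: int = 18
    n_runs: int = 4
    n_puzzles_per_run: int = 18
    tr: float = 1.0
    planning_len_mean: float = 5.91  # measured volumes per puzzle
    execution_len_mean: float = 5.63
    rest_len: int = 12
    fixation_len: int = 28
    M: int = 90
    voxels_per_region: int = 30
    frac_discriminative: float = 0.3
    effect_size: float = 1.0  # mean BOLD shift between conditions, in voxel-noise SDs
    latent_effect_size: float = 0.0  # per-region latent shift during planning, in innovation SDs
    W_true: np.ndarray | None = None  # M x M, zero diagonal, spectral radius < 1
    innovation_sd: float = 1.0
    voxel_noise_sd: float = 1.0
    mode: str = "lagged"  # "lagged" | "contemporaneous"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_runs", "n_puzzles_per_run", "M", "voxels_per_region"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.frac_discriminative <= 1.0:
            raise ValidationError("frac_discriminative must lie in [0, 1]")
        if self.mode not in ("lagged", "contemporaneous"):
            raise ValidationError(f"unknown latent mode {self.mode!r}")
        if self.W_true is not None:
            self.W_true = np.asarray(self.W_true, dtype=float)
            if self.W_true.shape != (self.M, self.M):
                raise ValidationError("W_true must be M x M")
            if np.any(np.diag(self.W_true) != 0):
                raise ValidationError("W_true must have a zero diagonal")
            if np.max(np.abs(np.linalg.eigvals(self.W_true))) >= 1.0:
                raise ValidationError("W_true is unstable (spectral radius >= 1)")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline is asked to recover."""

    W_true: np.ndarray
    discriminative: np.ndarray  # (n_voxels,) bool
    condition_pattern: np.ndarray  # (M,) latent planning offset direction
    latent: dict = field(default_factory=dict)  # (subject, run) -> (M, T) latent series
    behavior: dict = field(default_factory=dict)  # (subject, run) -> mean extra moves


def random_stable_weights(
    M: int, rng: np.random.Generator, spectral_radius: float = 0.4, density: float = 0.5,
    symmetric: bool = False,
) -> np.ndarray:
    """A random zero-diagonal coupling matrix rescaled to the requested spectral radius."""
    W = rng.normal(size=(M, M)) * (rng.random(size=(M, M)) < density)
    if symmetric:
        W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    rad = np.max(np.abs(np.linalg.eigvals(W)))
    if rad > 0:
        W *= spectral_radius / rad
    return W


def _puzzle_lengths(mean: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Shifted Poisson around the configured mean, minimum one volume per phase."""
    return 1 + rng.poisson(max(mean - 1.0, 0.0), size=n)


def generate_events(config: SyntheticConfig, rng: np.random.Generator) -> EventTable:
    """One run's label sequence: (planning block, execution block, rest) per puzzle
    plus a closing fixation block."""
    labels: list[str] = []
    puzzle_ids: list[int] = []
    for pid in range(config.n_puzzles_per_run):
        n_plan = int(_puzzle_lengths(config.planning_len_mean, 1, rng)[0])
        n_exec = int(_puzzle_lengths(config.execution_len_mean, 1, rng)[0])
        labels += ["planning"] * n_plan + ["execution"] * n_exec + ["rest"] * config.rest_len
        puzzle_ids += [pid] * (n_plan + n_exec) + [-1] * config.rest_len
    labels += ["fixation"] * config.fixation_len
    puzzle_ids += [-1] * config.fixation_len
    return EventTable(
        volume_index=np.arange(len(labels)),
        labels=np.array(labels, dtype=object),
        puzzle_ids=np.array(puzzle_ids),
    )


def _latent_series(
    W: np.ndarray,
    offsets: np.ndarray,  # (M, T) condition-dependent drive
    innovation_sd: float,
    mode: str,
    rng: np.random.Generator,
) -> np.ndarray:
    M, T = offsets.shape
    eps = rng.normal(scale=innovation_sd, size=(M, T)) if innovation_sd > 0 else np.zeros((M, T))
    drive = offsets + eps
    if mode == "contemporaneous":
        # x_t solves x = W^T x + drive  =>  x = (I - W^T)^-1 drive, column by column
        return np.linalg.solve(np.eye(M) - W.T, drive)
    x = np.zeros((M, T))
    for t in range(T):
        prev = x[:, t - 1] if t > 0 else np.zeros(M)
        x[:, t] = W.T @ prev + drive[:, t]
    return x


def synthetic_parcellation(config: SyntheticConfig) -> Parcellation:
    """A voxel grid with ``voxels_per_region`` contiguous voxels per region
    (no cerebellar regions: the generator emulates the retained 90-region set)."""
    n_vox = config.M * config.voxels_per_region
    return Parcellation(
        region_ids=np.arange(1, config.M + 1),
        names=[f"region_{j:03d}" for j in range(1, config.M + 1)],
        cerebellum_flags=np.zeros(config.M, dtype=bool),
        voxel_labels=np.repeat(np.arange(1, config.M + 1), config.voxels_per_region),
    )


def generate_study(
    config: SyntheticConfig,
) -> tuple[dict[tuple[str, int], LabeledVoxelSeries], dict[tuple[str, int], EventTable], GroundTruth]:
    """Generate every run of a study.  Identical config (incl. seed) gives
    bitwise-identical output."""
    root = np.random.default_rng(config.seed)
    W = config.W_true
    if W is None:
        W = random_stable_weights(config.M, root)
    else:
        # config validation already checked stability
        W = np.asarray(W, dtype=float)

    condition_pattern = root.normal(size=config.M)
    n_vox = config.M * config.voxels_per_region
    n_disc_per_region = int(round(config.frac_discriminative * config.voxels_per_region))
    discriminative = np.zeros(n_vox, dtype=bool)
    for j in range(config.M):
        picks = root.choice(config.voxels_per_region, size=n_disc_per_region, replace=False)
        discriminative[j * config.voxels_per_region + picks] = True

    region_of_voxel = np.repeat(np.arange(config.M), config.voxels_per_region)
    voxels: dict[tuple[str, int], LabeledVoxelSeries] = {}
    events: dict[tuple[str, int], EventTable] = {}
    truth = GroundTruth(W_true=W, discriminative=discriminative, condition_pattern=condition_pattern)

    for s in range(config.n_subjects):
        subject = f"sub-{s + 1:02d}"
        for run in range(config.n_runs):
            rng = np.random.default_rng([config.seed, s, run])
            ev = generate_events(config, rng)
            T = ev.n_volumes
            planning = np.asarray(ev.labels == "planning", dtype=float)
            offsets = (
                config.latent_effect_size
                * config.innovation_sd
                * np.outer(condition_pattern, planning)
            )
            x = _latent_series(W, offsets, config.innovation_sd, config.mode, rng)
            v = x[region_of_voxel]
            if config.effect_size != 0.0:
                shift = config.effect_size * config.voxel_noise_sd
                v = v + shift * np.outer(discriminative.astype(float), planning)
            if config.voxel_noise_sd > 0:
                v = v + rng.normal(scale=config.voxel_noise_sd, size=v.shape)
            grid = (config.voxels_per_region, config.M, 1)
            series = LabeledVoxelSeries(data=v, grid_shape=grid).attach_events(ev)
            voxels[(subject, run)] = series
            events[(subject, run)] = ev
            truth.latent[(subject, run)] = x
            truth.behavior[(subject, run)] = float(np.abs(rng.normal(loc=3.0, scale=1.5)))
    return voxels, events, truth


def ground_truth_recovery_fixture(
    M: int = 5,
    n_volumes: int = 1000,
    innovation_sd: float = 0.1,
    seed: int = 0,
    W_true: np.ndarray | None = None,
    mode: str = "contemporaneous",
):
    """Region series generated directly from ``W_true`` (no voxel stage, no voxel
    noise) for parameter-recovery checks against estimated networks.

    The default ground truth is a random *symmetric* stable coupling matrix in
    contemporaneous mixing mode: a simultaneous linear system is only
    identifiable by least squares up to reciprocal-pair mixing, so the
    symmetric case is the one where element-wise recovery is well-posed.
    Returns ``(series, W_true)`` where ``series`` is an un-interpolated
    :class:`~dynmesh.preprocessing.RegionSeries` labeled entirely as task.
    """
    from .preprocessing import RegionSeries  # local import: avoids a module cycle

    if n_volumes < 500:
        raise ValidationError("recovery fixture needs a long run (>= 500 volumes)")
    rng = np.random.default_rng(seed)
    if W_true is None:
        W_true = random_stable_weights(M, rng, spectral_radius=0.5, symmetric=True)
    else:
        W_true = np.asarray(W_true, dtype=float)
        if np.any(np.diag(W_true) != 0) or np.max(np.abs(np.linalg.eigvals(W_true))) >= 1:
            raise ValidationError("W_true must be zero-diagonal and stable")
    x = _latent_series(W_true, np.zeros((M, n_volumes)), innovation_sd, mode, rng)
    half = n_volumes // 2
    labels = np.array(["planning"] * half + ["execution"] * (n_volumes - half), dtype=object)
    series = RegionSeries(
        values=x,
        labels=labels,
        puzzle_ids=np.zeros(n_volumes, dtype=int),
        measured_mask=np.ones(n_volumes, dtype=bool),
        z=0,
        active_regions=np.ones(M, dtype=bool),
        selected_sets=[np.array([j]) for j in range(M)],
        region_ids=np.arange(1, M + 1),
    )
    return series, W_true


def null_config(**overrides) -> SyntheticConfig:
    """Convenience: a config with no condition effect anywhere (null hypothesis)."""
    base = SyntheticConfig(effect_size=0.0, latent_effect_size=0.0)
    return replace(base, **overrides)
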