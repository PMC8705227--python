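"""On-disk representations and run-wide configuration.

Conventions used throughout the package:

* Volume (time) indices are 0-based measured-volume indices.
* Voxel linearization of a 4D grid ``(X, Y, Z, T)`` is Fortran order over the
  spatial axes (first axis fastest), i.e. voxel ``i`` maps to grid coordinates
  ``(i % X, (i // X) % Y, i // (X*Y))``.  The linearization is recorded in the
  returned object so selected-voxel sets are reproducible.
* HDF5 is the canonical store for network stacks (bit-exact round trip); TSV
  export of matrices is lossy (formatted floats) and only used for small tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("dynmesh")

VALID_LABELS = ("planning", "execution", "rest", "fixation")
TASK_LABELS = ("planning", "execution")


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


class ValidationError(ValueError):
    """Raised when a parsed artifact violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class StudyLayout:
    """Locations of every run of a study plus acquisition constants."""

    subjects: list[str]
    runs_per_subject: int
    tr: float  # seconds per measured volume
    paths: dict[tuple[str, int], tuple[Path, Path]]  # (subject, run) -> (volume, events)
    parcellation_path: Path | None = None

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValidationError(f"tr must be positive, got {self.tr}")
        for subject in self.subjects:
            for run in range(self.runs_per_subject):
                if (subject, run) not in self.paths:
                    raise ValidationError(f"no files registered for ({subject!r}, run {run})")


@dataclass
class Parcellation:
    """Per-voxel region labels plus the region table.

    ``region_ids`` are the atlas integer ids in canonical order; ``voxel_labels``
    maps each linearized voxel to a region id (0 = unassigned).  ``M`` counts
    the retained (non-cerebellar) regions; all region-level arrays downstream
    follow the retained-region ordering given by :meth:`retained_ids`.
    """

    region_ids: np.ndarray  # (n_regions,) int
    names: list[str]
    cerebellum_flags: np.ndarray  # (n_regions,) bool
    voxel_labels: np.ndarray  # (n_voxels,) int

    def __post_init__(self) -> None:
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        self.cerebellum_flags = np.asarray(self.cerebellum_flags, dtype=bool)
        self.voxel_labels = np.asarray(self.voxel_labels, dtype=int)
        if len(self.names) != self.region_ids.size or self.cerebellum_flags.size != self.region_ids.size:
            raise ValidationError("region table columns disagree in length")
        known = set(self.region_ids.tolist()) | {0}
        bad = set(np.unique(self.voxel_labels).tolist()) - known
        if bad:
            raise ValidationError(f"voxel labels reference unknown region ids {sorted(bad)}")

    @property
    def M(self) -> int:
        return int((~self.cerebellum_flags).sum())

    def retained_ids(self) -> np.ndarray:
        """Ids of non-cerebellar regions, in canonical order."""
        return self.region_ids[~self.cerebellum_flags]

    def retained_names(self) -> list[str]:
        return [n for n, c in zip(self.names, self.cerebellum_flags) if not c]


@dataclass
class EventTable:
    """Per-measured-volume condition labels with puzzle segmentation."""

    volume_index: np.ndarray  # (n,) int, 0-based, gap-free
    labels: np.ndarray  # (n,) str in VALID_LABELS
    puzzle_ids: np.ndarray  # (n,) int, -1 where null

    def __post_init__(self) -> None:
        self.volume_index = np.asarray(self.volume_index, dtype=int)
        self.labels = np.asarray(self.labels, dtype=object)
        self.puzzle_ids = np.asarray(self.puzzle_ids, dtype=int)
        n = self.volume_index.size
        if not np.array_equal(self.volume_index, np.arange(n)):
            raise ValidationError("volume_index must be 0-based, strictly increasing and gap-free")
        bad = {l for l in self.labels if l not in VALID_LABELS}
        if bad:
            raise ValidationError(f"unknown labels {sorted(bad)}; expected one of {VALID_LABELS}")
        task = np.isin(self.labels, TASK_LABELS)
        if np.any(self.puzzle_ids[task] < 0):
            raise ValidationError("every planning/execution volume needs a puzzle_id")
        for pid in np.unique(self.puzzle_ids[task]):
            rows = self.labels[self.puzzle_ids == pid]
            rows = rows[np.isin(rows, TASK_LABELS)]
            first_exec = next((i for i, l in enumerate(rows) if l == "execution"), len(rows))
            if any(l == "planning" for l in rows[first_exec:]):
                raise ValidationError(
                    f"puzzle {pid}: planning volumes must all precede execution volumes"
                )

    @property
    def n_volumes(self) -> int:
        return self.volume_index.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "volume_index": self.volume_index,
                "label": self.labels,
                "puzzle_id": [pid if pid >= 0 else "" for pid in self.puzzle_ids],
            }
        )

    def label_counts(self) -> dict[str, int]:
        vals, counts = np.unique(np.asarray(self.labels, dtype=str), return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass
class LabeledVoxelSeries:
    """Voxel x time matrix with (optionally attached) per-volume labels."""

    data: np.ndarray  # (n_voxels, n_volumes)
    grid_shape: tuple[int, int, int]
    inactive: np.ndarray = field(default=None)  # (n_voxels,) bool: NaN voxels
    labels: np.ndarray | None = None
    puzzle_ids: np.ndarray | None = None
    linearization: str = "fortran (first spatial axis fastest)"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("voxel series must be 2D (voxels x time)")
        if self.inactive is None:
            self.inactive = np.any(np.isnan(self.data), axis=1)

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def attach_events(self, events: EventTable) -> "LabeledVoxelSeries":
        if events.n_volumes != self.n_volumes:
            raise ValidationError(
                f"events cover {events.n_volumes} volumes, series has {self.n_volumes}"
            )
        self.labels = events.labels
        self.puzzle_ids = events.puzzle_ids
        return self


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def read_volume_run(path: str | Path) -> LabeledVoxelSeries:
    """Read one 4D NIfTI-1 run as a voxel x time matrix.

    NaN voxels are flagged in ``inactive`` and carried through untouched.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4D volume, got {data.ndim} dimensions")
    x, y, z, t = data.shape
    flat = data.reshape(x * y * z, t, order="F")
    series = LabeledVoxelSeries(data=flat, grid_shape=(x, y, z))
    if series.inactive.any():
        log.warning("%s: %d NaN voxels flagged inactive", path, int(series.inactive.sum()))
    return series


def write_volume_run(path: str | Path, data4d: np.ndarray, tr: float = 1.0) -> None:
    """Write a 4D array as NIfTI-1 (identity affine, TR recorded in the header)."""
    data4d = np.asarray(data4d)
    if data4d.ndim != 4:
        raise FormatError("expected a 4D array")
    img = nib.Nifti1Image(data4d.astype(np.float64), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, float(tr)))
    nib.save(img, str(path))


def voxel_series_to_volume(series: LabeledVoxelSeries) -> np.ndarray:
    """Invert the documented linearization back to a 4D grid."""
    x, y, z = series.grid_shape
    return series.data.reshape(x, y, z, series.n_volumes, order="F")


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

def read_events(path: str | Path, n_volumes: int) -> EventTable:
    """Read a BIDS-style events TSV (columns volume_index, label, puzzle_id)."""
    df = pd.read_csv(path, sep="\t", dtype={"volume_index": int, "label": str})
    required = {"volume_index", "label", "puzzle_id"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: events TSV needs columns {sorted(required)}")
    if len(df) != n_volumes:
        raise ValidationError(f"{path}: expected {n_volumes} rows, found {len(df)}")
    pid = pd.to_numeric(df["puzzle_id"], errors="coerce").fillna(-1).astype(int).to_numpy()
    return EventTable(
        volume_index=df["volume_index"].to_numpy(),
        labels=df["label"].to_numpy(dtype=object),
        puzzle_ids=pid,
    )


def write_events(path: str | Path, events: EventTable) -> None:
    events.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------

def read_parcellation(table_path: str | Path, labels_path: str | Path) -> Parcellation:
    """Read the region table (TSV: region_id, name, cerebellum) and per-voxel labels.

    ``labels_path`` may be a 3D NIfTI of region ids or a one-column TSV of
    already-linearized labels.
    """
    table = pd.read_csv(table_path, sep="\t")
    labels_path = Path(labels_path)
    if labels_path.suffix in {".nii", ".gz"}:
        img = nib.load(str(labels_path))
        lab = np.asanyarray(img.dataobj)
        if lab.ndim != 3:
            raise FormatError("parcellation volume must be 3D")
        voxel_labels = lab.reshape(-1, order="F").astype(int)
    else:
        voxel_labels = pd.read_csv(labels_path, sep="\t")["region_id"].to_numpy(dtype=int)
    return Parcellation(
        region_ids=table["region_id"].to_numpy(dtype=int),
        names=table["name"].astype(str).tolist(),
        cerebellum_flags=table["cerebellum"].astype(bool).to_numpy(),
        voxel_labels=voxel_labels,
    )


def write_parcellation(table_path: str | Path, labels_path: str | Path, parc: Parcellation) -> None:
    pd.DataFrame(
        {
            "region_id": parc.region_ids,
            "name": parc.names,
            "cerebellum": parc.cerebellum_flags.astype(int),
        }
    ).to_csv(table_path, sep="\t", index=False)
    pd.DataFrame({"region_id": parc.voxel_labels}).to_csv(labels_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Network stacks (HDF5 canonical store)
# ---------------------------------------------------------------------------

def write_network(
    path: str | Path,
    networks: list,
    subject: str = "sub-01",
    run: int = 0,
    region_ids: np.ndarray | None = None,
) -> None:
    """Persist a stack of per-instant networks for one (subject, run).

    Refuses non-finite weights.  Stores the full weight stack, the measured
    time index, the condition label and the active-node mask per instant, plus
    the canonical region-id ordering shared by every artifact of the run.
    """
    if not networks:
        raise ValidationError("nothing to write")
    W = np.stack([np.asarray(n.W, dtype=float) for n in networks])
    if not np.all(np.isfinite(W)):
        raise ValidationError("refusing to write non-finite network weights")
    m = W.shape[1]
    if region_ids is None:
        region_ids = np.arange(1, m + 1)
    region_ids = np.asarray(region_ids, dtype=int)
    if region_ids.size != m:
        raise ValidationError(f"region id list of length {region_ids.size} for {m}-node networks")
    with h5py.File(path, "a") as f:
        grp = f.require_group(f"{subject}/run-{run:02d}")
        for name in ("W", "t", "label", "active_nodes", "region_ids"):
            if name in grp:
                del grp[name]
        grp.create_dataset("W", data=W)
        grp.create_dataset("t", data=np.array([n.t for n in networks], dtype=int))
        grp.create_dataset(
            "label", data=np.array([n.label for n in networks], dtype=h5py.string_dtype())
        )
        grp.create_dataset(
            "active_nodes", data=np.stack([n.active_nodes for n in networks]).astype(bool)
        )
        grp.create_dataset("region_ids", data=region_ids)


def read_network(path: str | Path, subject: str = "sub-01", run: int = 0):
    """Read back a network stack written by :func:`write_network` (bit-exact)."""
    from .network_estimation import DynamicNetwork  # local import: avoids a module cycle

    with h5py.File(path, "r") as f:
        grp = f[f"{subject}/run-{run:02d}"]
        W = grp["W"][()]
        t = grp["t"][()]
        labels = [s.decode() if isinstance(s, bytes) else str(s) for s in grp["label"][()]]
        active = grp["active_nodes"][()]
        region_ids = grp["region_ids"][()]
    nets = [
        DynamicNetwork(W=W[i], t=int(t[i]), label=labels[i], active_nodes=active[i])
        for i in range(W.shape[0])
    ]
    return nets, region_ids


def export_network_tsv(path: str | Path, network, region_ids: np.ndarray | None = None) -> None:
    """Lossy TSV export (formatted floats) of a single network's weight matrix."""
    W = np.asarray(network.W)
    ids = region_ids if region_ids is not None else np.arange(1, W.shape[0] + 1)
    pd.DataFrame(W, index=ids, columns=ids).to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> Mapping:
    """Load a flat YAML config file of pipeline parameters."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError("config file must contain a mapping")
    return cfg
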