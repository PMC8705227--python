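"""Two-class decoding of planning vs execution.

Feature rows are either region activation vectors (one per task column of the
preprocessed series; fixed width M with zeros for inactive regions) or
flattened edge-weight matrices of the per-instant networks (width M*M; with
the 90-region atlas, 90 and 8,100 respectively).  Decoding runs per subject
with k-fold cross-validation (default k = 8) under one of two fold schemes:

* ``instance`` — plain shuffled row split, mirroring instance-level CV;
* ``grouped`` (default) — all rows of one puzzle share a fold, which prevents
  leakage between a measured instant and its own interpolated neighbors.

The supervised decoder is a linear maximum-margin classifier (SVM); the
unsupervised decoder is 2-means with the cluster-to-label mapping chosen on
the training rows (majority label per cluster), so held-out accuracy is
unbiased under label permutation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.model_selection import KFold
from sklearn.svm import SVC

from .io_core import TASK_LABELS, ValidationError
from .network_estimation import DynamicNetwork
from .preprocessing import RegionSeries

log = logging.getLogger("dynmesh")


@dataclass
class FeatureMatrix:
    X: np.ndarray  # (n_rows, n_features)
    labels: np.ndarray  # (n_rows,) str
    groups: np.ndarray  # (n_rows,) puzzle ids
    kind: str  # "region" | "edges"
    subject: str = ""

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


@dataclass
class DecodingResult:
    fold_accuracies: list[float]
    method: str
    scheme: str
    subject: str = ""
    degenerate: bool = False
    skipped_folds: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies)) if self.fold_accuracies else float("nan")

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_accuracies)) if self.fold_accuracies else float("nan")


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def build_features(
    source: RegionSeries | list[DynamicNetwork],
    kind: str,
    subject: str = "",
) -> FeatureMatrix:
    """Region features: one row per task column (measured and interpolated) of
    the series.  Edge features: one row per estimated network (measured task
    instants), the full M*M weight matrix flattened in canonical region order.
    Inactive regions contribute zeros, never removed columns."""
    if kind == "region":
        if not isinstance(source, RegionSeries):
            raise ValidationError("region features need a RegionSeries")
        rows = np.where(source.task_columns())[0]
        return FeatureMatrix(
            X=source.values[:, rows].T.copy(),
            labels=np.asarray(source.labels, dtype=object)[rows],
            groups=np.asarray(source.puzzle_ids)[rows],
            kind=kind,
            subject=subject,
        )
    if kind == "edges":
        nets = source
        if not nets or not isinstance(nets[0], DynamicNetwork):
            raise ValidationError("edge features need a list of DynamicNetwork")
        X = np.stack([n.W.reshape(-1) for n in nets])
        labels = np.array([n.label for n in nets], dtype=object)
        groups = np.array([n.t for n in nets])  # see puzzle_groups_for_networks
        return FeatureMatrix(X=X, labels=labels, groups=groups, kind=kind, subject=subject)
    raise ValidationError(f"unknown feature kind {kind!r}")


def balance_classes(fm: FeatureMatrix, seed: int = 0) -> FeatureMatrix:
    """Equalize class counts by subsampling the majority class (seeded).

    Chance-level assessments against a 0.5 baseline are only calibrated when
    the held-out rows are class-balanced; a majority-class learner otherwise
    scores the majority fraction under any label permutation.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(fm.labels, dtype=str)
    idx = []
    n_min = min(int((y == c).sum()) for c in TASK_LABELS)
    for c in TASK_LABELS:
        rows = np.where(y == c)[0]
        idx.append(rng.choice(rows, size=n_min, replace=False))
    keep = np.sort(np.concatenate(idx))
    return FeatureMatrix(
        X=fm.X[keep], labels=fm.labels[keep], groups=fm.groups[keep],
        kind=fm.kind, subject=fm.subject,
    )


def puzzle_groups_for_networks(nets: list[DynamicNetwork], series: RegionSeries) -> np.ndarray:
    """Map each network's measured instant back to its puzzle id (for grouped folds)."""
    measured_cols = np.where(series.measured_mask)[0]
    pid_of_measured = np.asarray(series.puzzle_ids)[measured_cols]
    return np.array([pid_of_measured[n.t] for n in nets])


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

def crossval_split(
    fm: FeatureMatrix, k: int = 8, scheme: str = "grouped", seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """k train/test index splits. ``instance``: shuffled row KFold.
    ``grouped``: puzzles are shuffled and dealt into k folds, so no puzzle id
    spans two folds."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    rng = np.random.default_rng(seed)
    if scheme == "instance":
        kf = KFold(n_splits=k, shuffle=True, random_state=int(rng.integers(2**31)))
        return [(tr, te) for tr, te in kf.split(fm.X)]
    if scheme == "grouped":
        puzzles = np.unique(fm.groups)
        if puzzles.size < k:
            raise ValidationError(f"{puzzles.size} puzzles cannot fill {k} grouped folds")
        perm = rng.permutation(puzzles)
        folds = [perm[i::k] for i in range(k)]
        out = []
        for fold_puzzles in folds:
            te = np.where(np.isin(fm.groups, fold_puzzles))[0]
            tr = np.where(~np.isin(fm.groups, fold_puzzles))[0]
            out.append((tr, te))
        return out
    raise ValidationError(f"unknown fold scheme {scheme!r}")


# ---------------------------------------------------------------------------
# Decoders
# ---------------------------------------------------------------------------

def decode_supervised(
    fm: FeatureMatrix,
    folds: list[tuple[np.ndarray, np.ndarray]],
    C: float = 1.0,
    scheme: str = "",
) -> DecodingResult:
    """Linear SVM per fold; folds whose training rows hold a single class are
    skipped with a warning."""
    accs: list[float] = []
    skipped = 0
    y = np.asarray(fm.labels, dtype=str)
    for tr, te in folds:
        if np.unique(y[tr]).size < 2:
            warnings.warn("skipping fold with single-class training data", stacklevel=2)
            skipped += 1
            continue
        clf = SVC(kernel="linear", C=C)
        clf.fit(fm.X[tr], y[tr])
        accs.append(float((clf.predict(fm.X[te]) == y[te]).mean()))
    return DecodingResult(
        fold_accuracies=accs, method="supervised-margin", scheme=scheme,
        subject=fm.subject, skipped_folds=skipped,
    )


def best_mapping_accuracy(cluster_ids: np.ndarray, labels: np.ndarray) -> float:
    """Accuracy under the better of the two cluster-to-label assignments."""
    cluster_ids = np.asarray(cluster_ids)
    labels = np.asarray(labels, dtype=str)
    classes = TASK_LABELS
    a = float(np.mean((cluster_ids == 0) == (labels == classes[0])))
    return max(a, 1.0 - a)


def _train_mapping(cluster_ids: np.ndarray, labels: np.ndarray) -> dict[int, str]:
    """Majority training label per cluster (the best-of-2 mapping on the
    training rows); degenerate clusters default to the overall majority."""
    labels = np.asarray(labels, dtype=str)
    overall = max(TASK_LABELS, key=lambda c: (labels == c).sum())
    mapping = {}
    for c in (0, 1):
        members = labels[cluster_ids == c]
        mapping[c] = (
            max(TASK_LABELS, key=lambda cl: (members == cl).sum()) if members.size else overall
        )
    return mapping


def decode_unsupervised(
    fm: FeatureMatrix,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
    mode: str = "heldout",
    seed: int = 0,
    scheme: str = "",
) -> DecodingResult:
    """2-means decoding.

    ``heldout``: per fold, fit on training rows, map clusters by majority
    training label, score held-out rows.  ``all``: fit and score on all rows
    under the best of the two mappings.  Identical feature rows (a degenerate
    clustering) are flagged.
    """
    y = np.asarray(fm.labels, dtype=str)
    degenerate = bool(np.all(fm.X == fm.X[0]))
    if degenerate:
        log.warning("identical feature rows: clustering is degenerate")
    if mode == "all":
        km = KMeans(n_clusters=2, n_init=10, random_state=seed)
        ids = km.fit_predict(fm.X)
        acc = best_mapping_accuracy(ids, y)
        return DecodingResult(
            fold_accuracies=[acc], method="unsupervised-centroid", scheme=scheme,
            subject=fm.subject, degenerate=degenerate,
        )
    if mode != "heldout":
        raise ValidationError(f"unknown mode {mode!r}")
    if folds is None:
        raise ValidationError("heldout mode needs folds")
    accs: list[float] = []
    for fold_i, (tr, te) in enumerate(folds):
        km = KMeans(n_clusters=2, n_init=10, random_state=seed + fold_i)
        km.fit(fm.X[tr])
        mapping = _train_mapping(km.labels_, y[tr])
        pred = np.array([mapping[c] for c in km.predict(fm.X[te])])
        accs.append(float((pred == y[te]).mean()))
    return DecodingResult(
        fold_accuracies=accs, method="unsupervised-centroid", scheme=scheme,
        subject=fm.subject, degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Study-level aggregation
# ---------------------------------------------------------------------------

def aggregate(results: list[DecodingResult]) -> pd.DataFrame:
    """Mean +/- SD across subjects of per-subject fold-mean accuracies,
    formatted one row per (method, scheme)."""
    if not results:
        raise ValidationError("no results to aggregate")
    df = pd.DataFrame(
        {
            "subject": [r.subject for r in results],
            "method": [r.method for r in results],
            "scheme": [r.scheme for r in results],
            "subject_mean": [r.mean for r in results],
            "subject_sd": [r.sd for r in results],
        }
    )
    out = (
        df.groupby(["method", "scheme"])["subject_mean"]
        .agg(mean="mean", sd=lambda s: float(np.std(s)), n_subjects="count")
        .reset_index()
    )
    return out
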