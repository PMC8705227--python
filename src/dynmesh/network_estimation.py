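"""Directed weighted networks at every measured time instant.

Around each measured task volume t a window of the interpolated series is
taken, ``win(t) = [t - floor(z/2), ..., t, ..., t + ceil(z/2)]`` (z+1 columns,
truncated at puzzle boundaries).  Within the window each region's functional
neighborhood is the set of its p highest-Pearson-correlation partners, and a
single-layer linear network with that connectivity is trained by full-batch
gradient descent so that every region's series is reconstructed as a weighted
sum of its neighbors' series.  The converged weights are the directed edge
weights of the instant's network, N(t) = (V, W(t)).

The training objective for output node i is

    Loss_i = mean_t (r_i,t - sum_j w_{t,j,i} r_j,t)^2 + lambda * ||w_i||^2

and the per-mesh closed-form ridge solution of the *same* objective,
``w_i = (X^T X + K*lambda*I)^-1 X^T y`` with K the window size, is provided as
a baseline and as the convergence oracle.  Pearson-correlation networks are
the second baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io_core import TASK_LABELS, ValidationError
from .preprocessing import RegionSeries

log = logging.getLogger("dynmesh")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Window:
    center_t: int  # measured-volume index
    center_col: int  # column in the interpolated series
    member_columns: np.ndarray  # contiguous column indices
    label: str

    @property
    def effective_size(self) -> int:
        return self.member_columns.size


@dataclass
class NeighborhoodMatrix:
    omega: np.ndarray  # (M, M) binary, zero diagonal
    p: int


@dataclass
class TrainingConfig:
    learning_rate: float | str = 1e-8  # a float, or "auto" for a safe per-window rate
    epochs: int = 10
    lam: float = 1.0
    init: str = "zeros"  # "zeros" | "random"
    include_l2_gradient: bool = True
    seed: int = 0
    tol: float = 0.0  # early stop when max |grad| falls below tol (0 = never)

    def __post_init__(self) -> None:
        if isinstance(self.learning_rate, str):
            if self.learning_rate != "auto":
                raise ValidationError("learning_rate must be a positive float or 'auto'")
        elif self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.epochs < 0 or self.lam < 0:
            raise ValidationError("epochs and lambda must be non-negative")
        if self.init not in ("zeros", "random"):
            raise ValidationError(f"unknown init {self.init!r}")


@dataclass
class DynamicNetwork:
    """W[j, i] is the weight of the directed edge from region j to region i."""

    W: np.ndarray  # (M, M), zero diagonal, zeros off the neighborhood support
    t: int  # measured-volume index
    active_nodes: np.ndarray
    label: str = ""


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def make_windows(series: RegionSeries, min_size: int = 3) -> list[Window]:
    """One window per measured task-labeled column, truncated to its puzzle
    segment.  Instants whose truncated window has fewer than ``min_size``
    columns are dropped (logged)."""
    z = series.z
    left, right = z // 2, math.ceil(z / 2)
    windows: list[Window] = []
    for seg in series.segments():
        lo, hi = int(seg[0]), int(seg[-1])
        for c in seg:
            if not series.measured_mask[c]:
                continue
            if series.labels[c] not in TASK_LABELS:
                continue
            a, b = max(lo, c - left), min(hi, c + right)
            cols = np.arange(a, b + 1)
            if cols.size < min_size:
                log.info("dropping instant %d: truncated window of %d columns", c, cols.size)
                continue
            windows.append(
                Window(
                    center_t=int(series.measured_index[c]),
                    center_col=int(c),
                    member_columns=cols,
                    label=str(series.labels[c]),
                )
            )
    return windows


# ---------------------------------------------------------------------------
# Functional neighborhoods
# ---------------------------------------------------------------------------

def _window_correlations(series: RegionSeries, window: Window) -> np.ndarray:
    """Pearson correlation matrix over the window; constant-in-window or
    inactive regions get correlation 0 with everything; zero diagonal."""
    R = series.values[:, window.member_columns]
    M = R.shape[0]
    sd = R.std(axis=1)
    ok = series.active_regions & (sd > 0)
    C = np.zeros((M, M))
    if ok.sum() >= 2:
        sub = np.corrcoef(R[ok])
        sub = np.atleast_2d(sub)
        C[np.ix_(ok, ok)] = sub
    np.fill_diagonal(C, 0.0)
    return C


def pearson_neighborhood(series: RegionSeries, window: Window, p: int) -> NeighborhoodMatrix:
    """Binary neighborhood: Omega[i, j] = 1 iff j is among the p regions most
    correlated with i in the window.  p is clamped to (active regions - 1)."""
    if window.effective_size < 3:
        raise ValidationError("neighborhood needs a window of >= 3 columns")
    C = _window_correlations(series, window)
    active = series.active_regions
    n_active = int(active.sum())
    if p >= n_active:
        log.warning("p=%d >= %d active regions; clamping to %d", p, n_active, n_active - 1)
        p = n_active - 1
    if p < 1:
        raise ValidationError("need at least one neighbor per region")
    M = C.shape[0]
    omega = np.zeros((M, M), dtype=int)
    Cm = C.copy()
    Cm[:, ~active] = -np.inf  # inactive regions can never be neighbors
    np.fill_diagonal(Cm, -np.inf)
    for i in np.where(active)[0]:
        nbrs = np.argpartition(-Cm[i], p - 1)[:p]
        omega[i, nbrs] = 1
    return NeighborhoodMatrix(omega=omega, p=p)


# ---------------------------------------------------------------------------
# Weight estimation
# ---------------------------------------------------------------------------

def _check_window_omega(series: RegionSeries, window: Window, omega: NeighborhoodMatrix) -> None:
    if window.effective_size < 3:
        raise ValidationError("estimation needs a window of >= 3 columns")
    om = omega.omega
    if om.shape != (series.M, series.M) or np.any(np.diag(om) != 0):
        raise ValidationError("invalid neighborhood matrix")


def auto_learning_rate(R: np.ndarray, lam: float) -> float:
    """1 / L for the largest per-mesh Lipschitz constant: L = 2*s/K + 2*lambda
    with s the top eigenvalue of R R^T over the window's K columns."""
    K = R.shape[1]
    s = float(np.linalg.norm(R, 2)) ** 2
    return 1.0 / (2.0 * s / K + 2.0 * lam + 1e-12)


def estimate_network(
    series: RegionSeries,
    window: Window,
    omega: NeighborhoodMatrix,
    cfg: TrainingConfig,
    return_loss: bool = False,
) -> DynamicNetwork:
    """Joint gradient-descent training of all meshes on the window.

    Every supported weight is updated full-batch:
    ``w <- w - lr * (mean_t -2 r_j (r_i - sum_h w_h r_h) [+ 2 lambda w])``.
    The support (neighborhood + zero diagonal) is enforced at every step.
    """
    _check_window_omega(series, window, omega)
    R = series.values[:, window.member_columns]
    M, K = R.shape
    mask = (omega.omega.T > 0).astype(float)  # mask[j, i]: edge j -> i exists
    out_active = omega.omega.sum(axis=1) > 0  # rows with at least one neighbor

    if cfg.init == "zeros":
        W = np.zeros((M, M))
    else:
        rng = np.random.default_rng(cfg.seed)
        W = rng.normal(scale=0.01, size=(M, M)) * mask
    lr = auto_learning_rate(R[series.active_regions], cfg.lam) if cfg.learning_rate == "auto" else float(cfg.learning_rate)

    losses: list[float] = []
    for _ in range(cfg.epochs):
        with np.errstate(over="ignore", invalid="ignore"):
            resid = R - W.T @ R  # resid[i, t] = r_i - sum_j W[j,i] r_j
            grad = (-2.0 / K) * (R @ resid.T) * mask
        if cfg.include_l2_gradient and cfg.lam > 0:
            grad += 2.0 * cfg.lam * W * mask
        if not np.all(np.isfinite(grad)):
            raise ValidationError(
                "non-finite loss during training; the learning rate is likely too high"
            )
        if return_loss:
            data_term = (resid[out_active] ** 2).mean(axis=1).sum()
            losses.append(float(data_term + cfg.lam * (W**2).sum()))
        with np.errstate(over="ignore", invalid="ignore"):
            W = W - lr * grad
        if cfg.tol > 0 and np.max(np.abs(grad)) < cfg.tol:
            break
    net = DynamicNetwork(
        W=W, t=window.center_t, active_nodes=series.active_regions.copy(), label=window.label
    )
    if return_loss:
        net.training_loss = np.array(losses)  # type: ignore[attr-defined]
    return net


def estimate_network_ridge(
    series: RegionSeries, window: Window, omega: NeighborhoodMatrix, lam: float = 1.0
) -> DynamicNetwork:
    """Per-mesh closed-form ridge solution of the training objective.

    For each region i with neighbor set from Omega: ``w_i = (X^T X +
    K*lambda*I)^-1 X^T y`` over the window's K columns (X = neighbor series,
    y = r_i), which minimizes mean squared residual + lambda*||w_i||^2 — the
    same objective the gradient-descent estimator minimizes.  A singular
    system at lambda = 0 falls back to the minimum-norm solution (flagged).
    """
    _check_window_omega(series, window, omega)
    R = series.values[:, window.member_columns]
    M, K = R.shape
    W = np.zeros((M, M))
    flagged = False
    for i in range(M):
        nbrs = np.where(omega.omega[i] > 0)[0]
        if nbrs.size == 0:
            continue
        X = R[nbrs].T  # (K, p)
        y = R[i]
        A = X.T @ X + K * lam * np.eye(nbrs.size)
        if lam == 0 and np.linalg.matrix_rank(A) < nbrs.size:
            w, *_ = np.linalg.lstsq(X, y, rcond=None)
            flagged = True
        else:
            w = np.linalg.solve(A, X.T @ y)
        W[nbrs, i] = w
    if flagged:
        log.warning("singular least squares at lambda=0; minimum-norm solution used")
    net = DynamicNetwork(
        W=W, t=window.center_t, active_nodes=series.active_regions.copy(), label=window.label
    )
    net.min_norm_fallback = flagged  # type: ignore[attr-defined]
    return net


def pearson_network(series: RegionSeries, window: Window) -> DynamicNetwork:
    """Baseline: symmetric network of window Pearson correlations, zero diagonal."""
    if window.effective_size < 3:
        raise ValidationError("needs a window of >= 3 columns")
    W = _window_correlations(series, window)
    return DynamicNetwork(
        W=W, t=window.center_t, active_nodes=series.active_regions.copy(), label=window.label
    )


# ---------------------------------------------------------------------------
# Per-run convenience
# ---------------------------------------------------------------------------

def estimate_run(
    series: RegionSeries,
    method: str = "ann",
    p: int | None = None,
    cfg: TrainingConfig | None = None,
    lam: float = 1.0,
) -> list[DynamicNetwork]:
    """Estimate one network per measured task instant of a preprocessed run.

    ``p`` defaults to M - 1 (full neighborhood minus self-connections).
    """
    if p is None:
        p = int(series.active_regions.sum()) - 1
    cfg = cfg or TrainingConfig()
    nets: list[DynamicNetwork] = []
    for window in make_windows(series):
        if method == "pearson":
            nets.append(pearson_network(series, window))
            continue
        omega = pearson_neighborhood(series, window, p)
        if method == "ann":
            nets.append(estimate_network(series, window, omega, cfg))
        elif method == "ridge":
            nets.append(estimate_network_ridge(series, window, omega, lam))
        else:
            raise ValidationError(f"unknown method {method!r}")
    return nets
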