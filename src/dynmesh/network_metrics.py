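"""Centrality and segregation measures on prepared directed weighted networks.

Estimated networks carry signed weights; before graph analysis every network
is shifted by the magnitude of its largest negative weight, normalized into
[0, 1], and pruned of inactive (flat-response) nodes.  Distances live on the
connection-length matrix L = 1/W (infinite where W = 0).

Per-node measures: degree (in/out/total), strength (in/out), betweenness
centrality (Brandes on L, normalized by (M-1)(M-2)), clustering coefficient,
per-node transitivity and local efficiency.  Per-network: global efficiency,
the mean inverse shortest path length over ordered node pairs.

Two clustering conventions are available: the ordered-pair geometric-mean
formula used by default ("printed"), and Fagiolo's direction-split variant
("fagiolo"); both are exercised against brute-force oracles in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .io_core import ValidationError
from .network_estimation import DynamicNetwork


@dataclass
class PreparedNetwork:
    W: np.ndarray  # (M', M') in [0, 1], zero diagonal
    node_ids: np.ndarray  # surviving indices into the original region order
    L: np.ndarray  # 1/W where W > 0, inf elsewhere

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]


@dataclass
class NetworkMetricsRecord:
    node_ids: np.ndarray
    degree: np.ndarray
    in_degree: np.ndarray
    out_degree: np.ndarray
    strength_in: np.ndarray
    strength_out: np.ndarray
    betweenness: np.ndarray
    clustering: np.ndarray
    transitivity: np.ndarray
    local_efficiency: np.ndarray
    global_efficiency: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "degree": self.degree,
                "in_degree": self.in_degree,
                "out_degree": self.out_degree,
                "strength_in": self.strength_in,
                "strength_out": self.strength_out,
                "betweenness": self.betweenness,
                "clustering": self.clustering,
                "transitivity": self.transitivity,
                "local_efficiency": self.local_efficiency,
            }
        )


# ---------------------------------------------------------------------------
# Preparation
# ---------------------------------------------------------------------------

def _length_matrix(W: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(L, 0.0)
    return L


def prepare_network(net: DynamicNetwork) -> PreparedNetwork:
    """Shift off the negative weights, normalize into [0, 1], prune inactive nodes."""
    W = np.asarray(net.W, dtype=float)
    if not np.all(np.isfinite(W)):
        raise ValidationError("network weights must be finite")
    keep = np.where(np.asarray(net.active_nodes, dtype=bool))[0]
    W = W[np.ix_(keep, keep)].copy()
    off = ~np.eye(W.shape[0], dtype=bool)
    wmin = W[off].min() if off.any() else 0.0
    shift = abs(wmin) if wmin < 0 else 0.0
    W[off] += shift
    wmax = W[off].max() if off.any() else 0.0
    if wmax <= 0:
        raise ValidationError("all-zero network: nothing to normalize")
    W[off] /= wmax
    np.fill_diagonal(W, 0.0)
    return PreparedNetwork(W=W, node_ids=keep, L=_length_matrix(W))


# ---------------------------------------------------------------------------
# Centrality
# ---------------------------------------------------------------------------

def degrees(net: PreparedNetwork) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(in, out, total) counts of nonzero edges per node (a_ij = 1 iff w_ij != 0)."""
    a = (net.W != 0).astype(int)
    d_in = a.sum(axis=0)
    d_out = a.sum(axis=1)
    return d_in, d_out, d_in + d_out


def strengths(net: PreparedNetwork) -> tuple[np.ndarray, np.ndarray]:
    """(in, out) sums of incident edge weights per node."""
    return net.W.sum(axis=0), net.W.sum(axis=1)


def betweenness(net: PreparedNetwork) -> np.ndarray:
    """Brandes betweenness on the length matrix, normalized by (M'-1)(M'-2);
    disconnected pairs contribute nothing."""
    m = net.n_nodes
    G = nx.DiGraph()
    G.add_nodes_from(range(m))
    rows, cols = np.where(net.W > 0)
    G.add_weighted_edges_from(
        ((int(i), int(j), float(net.L[i, j])) for i, j in zip(rows, cols)), weight="length"
    )
    if m < 3:
        return np.zeros(m)
    bc = nx.betweenness_centrality(G, weight="length", normalized=True)
    return np.array([bc[i] for i in range(m)])


# ---------------------------------------------------------------------------
# Segregation
# ---------------------------------------------------------------------------

def _triplet_denominators(W: np.ndarray) -> np.ndarray:
    a = (W != 0).astype(int)
    d_tot = a.sum(axis=0) + a.sum(axis=1)
    recip = (a * a.T).sum(axis=1)
    return d_tot * (d_tot - 1) - 2 * recip


def clustering_and_transitivity(
    net: PreparedNetwork, mode: str = "printed"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node clustering coefficient C_i and transitivity T_i.

    ``printed``: chi_i = 1/2 * sum_{j,h} (w_ij w_ih w_jh)^(1/3) over ordered
    pairs, divided by the triplet count (C_i) or its sum over all nodes (T_i).
    ``fagiolo``: the direction-split variant, C_i =
    [(W^(1/3) + (W^T)^(1/3))^3]_ii / (2 * triplets_i).
    Nodes with total degree <= 1 get C_i = 0 by convention.
    """
    W = net.W
    W13 = np.cbrt(W)
    if mode == "printed":
        chi = 0.5 * np.einsum("ij,ij->i", W13, W13 @ W13.T)
    elif mode == "fagiolo":
        S = W13 + W13.T
        chi = 0.5 * np.einsum("ij,jk,ki->i", S, S, S)
    else:
        raise ValidationError(f"unknown clustering mode {mode!r}")
    denom = _triplet_denominators(W).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(denom > 0, chi / np.where(denom > 0, denom, 1.0), 0.0)
    total = denom.sum()
    T = chi / total if total > 0 else np.zeros_like(chi)
    return C, T


def _global_efficiency_from_lengths(L: np.ndarray) -> float:
    m = L.shape[0]
    if m < 2:
        return 0.0
    D = dijkstra(L, directed=True)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / np.where(D > 0, D, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (m * (m - 1)))


def efficiencies(net: PreparedNetwork) -> tuple[np.ndarray, float]:
    """(local efficiency per node, global efficiency).

    Global efficiency is the mean inverse shortest path length over ordered
    node pairs (unreachable pairs contribute 0).  A node's local efficiency is
    the global efficiency of the subgraph induced by the union of its in- and
    out-neighbors; neighborhoods of fewer than two nodes score 0.
    """
    W = net.W
    m = net.n_nodes
    e_glob = _global_efficiency_from_lengths(net.L)
    local = np.zeros(m)
    a = W != 0
    for i in range(m):
        nbrs = np.where(a[i] | a[:, i])[0]
        nbrs = nbrs[nbrs != i]
        if nbrs.size < 2:
            continue
        local[i] = _global_efficiency_from_lengths(net.L[np.ix_(nbrs, nbrs)])
    return local, e_glob


# ---------------------------------------------------------------------------
# Full record and per-phase aggregation
# ---------------------------------------------------------------------------

def compute_metrics(net: PreparedNetwork, clustering_mode: str = "printed") -> NetworkMetricsRecord:
    d_in, d_out, d_tot = degrees(net)
    s_in, s_out = strengths(net)
    bc = betweenness(net)
    C, T = clustering_and_transitivity(net, mode=clustering_mode)
    local, e_glob = efficiencies(net)
    return NetworkMetricsRecord(
        node_ids=net.node_ids,
        degree=d_tot,
        in_degree=d_in,
        out_degree=d_out,
        strength_in=s_in,
        strength_out=s_out,
        betweenness=bc,
        clustering=C,
        transitivity=T,
        local_efficiency=local,
        global_efficiency=e_glob,
    )


def metrics_for_phase(
    networks: list[DynamicNetwork],
    phase: str,
    n_regions: int | None = None,
    clustering_mode: str = "printed",
) -> pd.DataFrame:
    """Per-region metrics averaged over all instants of one phase in a run.

    Returns a DataFrame indexed by region (original ordering); pruned regions
    hold NaN.  The across-instant mean global efficiency is stored in
    ``df.attrs['global_efficiency']``.
    """
    sel = [n for n in networks if n.label == phase]
    if not sel:
        raise ValidationError(f"no instants with phase {phase!r}")
    if n_regions is None:
        n_regions = sel[0].W.shape[0]
    cols = [
        "degree", "in_degree", "out_degree", "strength_in", "strength_out",
        "betweenness", "clustering", "transitivity", "local_efficiency",
    ]
    acc = np.full((len(sel), n_regions, len(cols)), np.nan)
    e_glob = np.zeros(len(sel))
    for k, net in enumerate(sel):
        rec = compute_metrics(prepare_network(net), clustering_mode=clustering_mode)
        for c, name in enumerate(cols):
            acc[k, rec.node_ids, c] = getattr(rec, name)
        e_glob[k] = rec.global_efficiency
    df = pd.DataFrame(np.nanmean(acc, axis=0), columns=cols)
    df.index.name = "region"
    df.attrs["global_efficiency"] = float(e_glob.mean())
    df.attrs["n_instants"] = len(sel)
    return df
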