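"""Independent brute-force oracles used only by the tests.

Every function here recomputes a quantity by direct enumeration (explicit
loops, Floyd-Warshall, closed forms) with no code shared with the package.
"""

import numpy as np


def bf_length_matrix(W):
    m = W.shape[0]
    L = np.full((m, m), np.inf)
    for i in range(m):
        for j in range(m):
            if i != j and W[i, j] > 0:
                L[i, j] = 1.0 / W[i, j]
        L[i, i] = 0.0
    return L


def bf_shortest_paths(W):
    """Floyd-Warshall distances and shortest-path counts on the length matrix."""
    m = W.shape[0]
    L = bf_length_matrix(W)
    d = L.copy()
    sigma = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            if i != j and np.isfinite(L[i, j]):
                sigma[i, j] = 1.0
    for k in range(m):
        for i in range(m):
            for j in range(m):
                if i == j:
                    continue
                alt = d[i, k] + d[k, j]
                if alt < d[i, j] - 1e-13:
                    d[i, j] = alt
                    sigma[i, j] = sigma[i, k] * sigma[k, j]
                elif np.isfinite(alt) and abs(alt - d[i, j]) <= 1e-13 and k not in (i, j):
                    sigma[i, j] += sigma[i, k] * sigma[k, j]
    return d, sigma


def bf_betweenness(W):
    """Normalized betweenness by exhaustive path counting."""
    m = W.shape[0]
    d, sigma = bf_shortest_paths(W)
    bc = np.zeros(m)
    for v in range(m):
        for j in range(m):
            for k in range(m):
                if len({v, j, k}) < 3 or sigma[j, k] == 0:
                    continue
                through = 0.0
                if np.isfinite(d[j, v] + d[v, k]) and abs(d[j, v] + d[v, k] - d[j, k]) <= 1e-12:
                    through = sigma[j, v] * sigma[v, k]
                bc[v] += through / sigma[j, k]
    if m > 2:
        bc /= (m - 1) * (m - 2)
    return bc


def bf_degrees(W):
    m = W.shape[0]
    d_in = np.array([sum(1 for j in range(m) if W[j, i] != 0) for i in range(m)])
    d_out = np.array([sum(1 for j in range(m) if W[i, j] != 0) for i in range(m)])
    return d_in, d_out, d_in + d_out


def bf_strengths(W):
    m = W.shape[0]
    s_in = np.array([sum(W[j, i] for j in range(m)) for i in range(m)])
    s_out = np.array([sum(W[i, j] for j in range(m)) for i in range(m)])
    return s_in, s_out


def _bf_triplets(W):
    m = W.shape[0]
    a = (W != 0).astype(int)
    out = np.zeros(m)
    for i in range(m):
        d_tot = sum(a[i, j] + a[j, i] for j in range(m))
        recip = sum(a[i, j] * a[j, i] for j in range(m))
        out[i] = d_tot * (d_tot - 1) - 2 * recip
    return out


def bf_clustering_printed(W):
    """Ordered-pair geometric-mean triangle formula, direct triple loop."""
    m = W.shape[0]
    chi = np.zeros(m)
    for i in range(m):
        for j in range(m):
            for h in range(m):
                chi[i] += (W[i, j] * W[i, h] * W[j, h]) ** (1.0 / 3.0)
    chi *= 0.5
    denom = _bf_triplets(W)
    C = np.where(denom > 0, chi / np.where(denom > 0, denom, 1), 0.0)
    T = chi / denom.sum() if denom.sum() > 0 else np.zeros(m)
    return C, T


def bf_clustering_fagiolo(W):
    """Direction-split variant: [(W^1/3 + (W^T)^1/3)^3]_ii / (2 * triplets_i)."""
    m = W.shape[0]
    S = np.cbrt(W) + np.cbrt(W.T)
    tri = np.zeros(m)
    for i in range(m):
        for j in range(m):
            for k in range(m):
                tri[i] += S[i, j] * S[j, k] * S[k, i]
    denom = _bf_triplets(W)
    return np.where(denom > 0, tri / (2 * np.where(denom > 0, denom, 1)), 0.0)


def bf_global_efficiency(W):
    m = W.shape[0]
    if m < 2:
        return 0.0
    d, _ = bf_shortest_paths(W)
    total = 0.0
    for i in range(m):
        for j in range(m):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (m * (m - 1))


def bf_local_efficiency(W):
    m = W.shape[0]
    a = W != 0
    out = np.zeros(m)
    for i in range(m):
        nbrs = [j for j in range(m) if j != i and (a[i, j] or a[j, i])]
        if len(nbrs) < 2:
            continue
        out[i] = bf_global_efficiency(W[np.ix_(nbrs, nbrs)])
    return out


def bf_pearson(x, y):
    """Covariance-formula Pearson correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return cov / (x.std() * y.std())


def random_prepared_digraph(rng, n_max=8, density=0.5):
    """A random nonnegative weighted digraph in [0,1] with zero diagonal."""
    m = int(rng.integers(3, n_max + 1))
    W = rng.random((m, m)) * (rng.random((m, m)) < density)
    np.fill_diagonal(W, 0.0)
    return W
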