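"""Independent brute-force implementations of the binary graph measures.

Everything here works directly on a dense 0/1 adjacency matrix with plain
numpy (plus scipy.linalg for matrix exponentials), deliberately avoiding
the graph library used by the feature engine.  Intended for exhaustive
cross-checks on small graphs only.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.linalg import expm

INF = np.inf


# -- basic structure ---------------------------------------------------------


def degrees(A):
    return A.sum(axis=0)


def floyd_warshall(A):
    n = len(A)
    D = np.where(A > 0, 1.0, INF)
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        D = np.minimum(D, D[:, k][:, None] + D[k, :][None, :])
    return D


def components(A):
    n = len(A)
    seen = np.zeros(n, dtype=bool)
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for u in np.flatnonzero(A[v]):
                if not seen[u]:
                    seen[u] = True
                    stack.append(u)
        comps.append(comp)
    return comps


def is_connected(A):
    return len(components(A)) == 1


# -- triangles / clustering --------------------------------------------------


def triangle_count(A):
    return np.trace(A @ A @ A) / 6.0


def transitivity(A):
    d = degrees(A)
    denom = (d * (d - 1)).sum()
    return float(np.trace(A @ A @ A) / denom) if denom > 0 else 0.0


def clustering(A):
    d = degrees(A)
    tri = np.diag(A @ A @ A)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(d > 1, tri / (d * (d - 1)), 0.0)
    return c


def average_clustering(A):
    return float(clustering(A).mean())


# -- cliques -----------------------------------------------------------------


def maximal_cliques(A):
    n = len(A)
    nodes = range(n)
    cliques = []
    for r in range(1, n + 1):
        for sub in combinations(nodes, r):
            if all(A[i, j] for i, j in combinations(sub, 2)):
                others = set(nodes) - set(sub)
                if not any(all(A[v, u] for u in sub) for v in others):
                    cliques.append(set(sub))
    return cliques


def clique_number(A):
    return max(len(c) for c in maximal_cliques(A))


# -- path-based --------------------------------------------------------------


def average_shortest_path(A):
    D = floyd_warshall(A)
    n = len(A)
    iu = np.triu_indices(n, 1)
    return float(D[iu].mean())


def wiener_index(A):
    D = floyd_warshall(A)
    return float(D[np.triu_indices(len(A), 1)].sum())


def eccentricities(A):
    return floyd_warshall(A).max(axis=1)


def global_efficiency(A):
    n = len(A)
    if n < 2:
        return 0.0
    D = floyd_warshall(A)
    iu = np.triu_indices(n, 1)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D[iu]) & (D[iu] > 0), 1.0 / D[iu], 0.0)
    return float(2 * inv.sum() / (n * (n - 1)))


def local_efficiency(A):
    n = len(A)
    effs = []
    for v in range(n):
        nb = np.flatnonzero(A[v])
        if len(nb) < 2:
            effs.append(0.0)
            continue
        effs.append(global_efficiency(A[np.ix_(nb, nb)]))
    return float(np.mean(effs))


def min_cut(A):
    """Global minimum edge cut by exhaustive bipartition."""
    n = len(A)
    best = INF
    for r in range(1, n // 2 + 1):
        for S in combinations(range(n), r):
            S = list(S)
            T = [v for v in range(n) if v not in S]
            best = min(best, A[np.ix_(S, T)].sum())
    return float(best)


# -- centralities ------------------------------------------------------------


def betweenness(A, normalized=True):
    n = len(A)
    D = floyd_warshall(A)
    # count shortest paths with matrix DP on path lengths
    sigma = np.zeros((n, n))
    np.fill_diagonal(sigma, 1.0)
    order = np.argsort(D, axis=None)
    for flat in order:
        s, t = divmod(flat, n)
        if s == t or not np.isfinite(D[s, t]):
            continue
        preds = [u for u in np.flatnonzero(A[:, t]) if D[s, u] + 1 == D[s, t]]
        sigma[s, t] = sum(sigma[s, u] for u in preds)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t or not np.isfinite(D[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if np.isfinite(D[s, v]) and np.isfinite(D[v, t]) \
                        and D[s, v] + D[v, t] == D[s, t]:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    bc /= 2.0  # undirected: each pair counted twice
    if normalized and n > 2:
        bc /= (n - 1) * (n - 2) / 2.0
    return bc


def closeness(A):
    """Wasserman-Faust-free convention: per-component scaling (as used by
    the common library default for possibly-disconnected graphs)."""
    n = len(A)
    D = floyd_warshall(A)
    out = np.zeros(n)
    for v in range(n):
        reach = np.isfinite(D[v]) & (np.arange(n) != v)
        r = reach.sum()
        if r == 0:
            continue
        tot = D[v][reach].sum()
        out[v] = (r / tot) * (r / (n - 1))
    return out


def harmonic(A):
    D = floyd_warshall(A)
    with np.errstate(divide="ignore"):
        H = np.where((D > 0) & np.isfinite(D), 1.0 / D, 0.0)
    return H.sum(axis=1)


def eigenvector(A, iters=10_000):
    """Perron vector by shifted power iteration (shift kills the +/-lambda
    oscillation on bipartite graphs)."""
    n = len(A)
    M = A + n * np.eye(n)
    x = np.ones(n) / np.sqrt(n)
    for _ in range(iters):
        y = M @ x
        y = y / np.linalg.norm(y)
        if np.allclose(y, x, atol=1e-14):
            break
        x = y
    return np.abs(y)


def pagerank(A, alpha=0.85):
    n = len(A)
    d = degrees(A)
    P = np.zeros((n, n))
    for v in range(n):
        if d[v] > 0:
            P[v] = A[v] / d[v]
        else:
            P[v] = 1.0 / n
    # solve p = alpha p P + (1-alpha)/n
    M = np.eye(n) - alpha * P.T
    p = np.linalg.solve(M, np.full(n, (1 - alpha) / n))
    return p / p.sum()


def katz(A, alpha, beta=1.0):
    n = len(A)
    x = np.linalg.solve(np.eye(n) - alpha * A, beta * np.ones(n))
    return x / np.linalg.norm(x)


def local_reaching(A):
    comps = components(A)
    n = len(A)
    out = np.zeros(n)
    for comp in comps:
        for v in comp:
            out[v] = (len(comp) - 1) / (n - 1) if n > 1 else 0.0
    return out


def global_reaching(A):
    lr = local_reaching(A)
    return float((lr.max() - lr).sum() / (len(A) - 1)) if len(A) > 1 else 0.0


def core_number(A):
    A = A.copy().astype(float)
    n = len(A)
    alive = np.ones(n, dtype=bool)
    core = np.zeros(n, dtype=int)
    k = 0
    while alive.any():
        while True:
            d = (A[alive][:, alive]).sum(axis=0)
            idx = np.flatnonzero(alive)
            weak = idx[d <= k]
            if len(weak) == 0:
                break
            for v in weak:
                core[v] = k
                alive[v] = False
                A[v, :] = 0
                A[:, v] = 0
        k += 1
    return core


def average_neighbor_degree(A):
    d = degrees(A)
    out = np.zeros(len(A))
    for v in range(len(A)):
        nb = np.flatnonzero(A[v])
        out[v] = d[nb].mean() if len(nb) else 0.0
    return out


def subgraph_centrality(A):
    return np.diag(expm(A)).copy()


def assortativity(A):
    d = degrees(A)
    xs, ys = [], []
    for i in range(len(A)):
        for j in range(len(A)):
            if A[i, j]:
                xs.append(d[i])
                ys.append(d[j])
    xs, ys = np.array(xs, float), np.array(ys, float)
    if len(xs) == 0 or xs.std() == 0 or ys.std() == 0:
        return np.nan
    return float(np.corrcoef(xs, ys)[0, 1])


def s_metric(A):
    d = degrees(A)
    tot = 0.0
    for i in range(len(A)):
        for j in range(i + 1, len(A)):
            if A[i, j]:
                tot += d[i] * d[j]
    return tot


def burt_constraint(A):
    n = len(A)
    d = degrees(A)
    P = np.zeros((n, n))
    for i in range(n):
        if d[i] > 0:
            P[i] = A[i] / d[i]
    out = np.zeros(n)
    for i in range(n):
        if d[i] == 0:
            out[i] = 0.0  # engine maps undefined to 0
            continue
        c = 0.0
        for j in np.flatnonzero(A[i]):
            indirect = sum(P[i, q] * P[q, j] for q in range(n) if q not in (i, j))
            c += (P[i, j] + indirect) ** 2
        out[i] = c
    return out


def articulation_points(A):
    n = len(A)
    base = len(components(A))
    out = np.zeros(n)
    for v in range(n):
        keep = [u for u in range(n) if u != v]
        sub = A[np.ix_(keep, keep)]
        out[v] = float(len(components(sub)) > base)
    return out


def current_flow_closeness(A):
    """Reciprocal of summed effective resistances, via Laplacian pseudoinverse."""
    L = np.diag(degrees(A)) - A
    Lp = np.linalg.pinv(L)
    R = np.diag(Lp)[:, None] + np.diag(Lp)[None, :] - 2 * Lp
    return 1.0 / R.sum(axis=1)


def degree_entropy(A):
    d = degrees(A).astype(int)
    n = len(A)
    counts = np.bincount(d)
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def modularity(A, communities):
    """Direct Newman modularity of a given node partition."""
    m = A.sum() / 2.0
    if m == 0:
        return 0.0
    d = degrees(A)
    q = 0.0
    for comm in communities:
        comm = list(comm)
        lc = A[np.ix_(comm, comm)].sum() / 2.0
        dc = d[comm].sum()
        q += lc / m - (dc / (2 * m)) ** 2
    return float(q)


def load_centrality(A, normalized=True):
    """Newman's load: unit packets split equally among shortest-path
    predecessors at every hop; endpoint loads excluded."""
    n = len(A)
    D = floyd_warshall(A)
    total = np.zeros(n)
    for s in range(n):
        load = np.ones(n)
        order = [v for v in np.argsort(-D[s]) if np.isfinite(D[s, v]) and v != s]
        for v in order:
            preds = [u for u in np.flatnonzero(A[v]) if D[s, u] + 1 == D[s, v]]
            if preds:
                share = load[v] / len(preds)
                for u in preds:
                    load[u] += share
        load[s] = 0.0
        contrib = load.copy()
        contrib[contrib > 0] -= 1.0  # subtract the packet delivered to v itself
        total += contrib
    if normalized and n > 2:
        total /= (n - 1) * (n - 2)
    return total


def node_clique_stats(A):
    """(size of largest maximal clique containing v, count containing v)."""
    n = len(A)
    cliques = maximal_cliques(A)
    size = np.ones(n)
    count = np.zeros(n)
    for c in cliques:
        for v in c:
            count[v] += 1
            size[v] = max(size[v], len(c))
    return size, count
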