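"""The 69-measure graph-feature engine.

Per subject the engine computes 36 global binary, 7 global weighted,
21 local binary and 5 local weighted graph measures (69 in total; the
26 local measures over 164 ROIs flatten to 4,264 per-subject features).
Binary measures are evaluated on the thresholded graph, weighted measures
on the rectified Fisher-z graph; path-based weighted measures use the
inverse weight as edge length.

Measures whose definition requires a connected graph (path lengths,
eccentricities, min cuts, ...) return NaN with a per-subject disconnection
flag instead of a component-wise approximation: thresholds that disconnect
graphs are excluded from model comparison rather than patched over.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path
from scipy.sparse import csr_matrix

from .connectome import binarize, to_networkx, to_networkx_weighted
from .datamodel import BinaryGraph, Cohort, ConnectivityMatrix, ConnectomlError

Category = Literal["global_binary", "global_weighted", "local_binary", "local_weighted"]

CATEGORY_SIZES = {
    "global_binary": 36,
    "global_weighted": 7,
    "local_binary": 21,
    "local_weighted": 5,
}
CATALOGUE_VERSION = "1.0"


@dataclass(frozen=True)
class MeasureDescriptor:
    name: str
    category: Category
    requires_connected: bool = False


_GLOBAL_BINARY = [
    ("number_of_edges", False),
    ("density", False),
    ("mean_degree", False),
    ("degree_std", False),
    ("max_degree", False),
    ("min_degree", False),
    ("number_of_isolates", False),
    ("connected_component_count", False),
    ("largest_component_fraction", False),
    ("transitivity", False),
    ("global_clustering", False),
    ("triangle_count", False),
    ("degree_assortativity", False),
    ("maximal_clique_count", False),
    ("clique_number", False),
    ("average_shortest_path_length", True),
    ("diameter", True),
    ("radius", True),
    ("wiener_index", True),
    ("global_efficiency", False),
    ("local_efficiency", False),
    ("average_eccentricity", True),
    ("global_reaching_centrality", False),
    ("stoer_wagner_cut", True),
    ("greedy_coloring_number", False),
    ("greedy_modularity", False),
    ("greedy_community_count", False),
    ("spectral_radius", False),
    ("spectral_gap", False),
    ("algebraic_connectivity", False),
    ("graph_energy", False),
    ("estrada_index", False),
    ("s_metric", False),
    ("mean_neighbor_degree", False),
    ("degeneracy", False),
    ("degree_entropy", False),
]

_GLOBAL_WEIGHTED = [
    ("total_edge_weight", False),
    ("mean_edge_weight", False),
    ("strength_std", False),
    ("weighted_global_clustering", False),
    ("dijkstra_path_length", True),
    ("weighted_wiener_index", True),
    ("conductance", False),
]

_LOCAL_BINARY = [
    ("degree_centrality", False),
    ("betweenness_centrality", False),
    ("closeness_centrality", False),
    ("load_centrality", False),
    ("eigenvector_centrality", False),
    ("pagerank_centrality", False),
    ("katz_centrality", False),
    ("harmonic_centrality", False),
    ("local_reaching_centrality", False),
    ("clustering_coefficient", False),
    ("triangles", False),
    ("core_number", False),
    ("eccentricity", True),
    ("average_neighbor_degree", False),
    ("node_clique_number", False),
    ("node_maximal_clique_count", False),
    ("greedy_color_index", False),
    ("subgraph_centrality", False),
    ("burt_constraint", False),
    ("articulation_point", False),
    ("current_flow_closeness", True),
]

_LOCAL_WEIGHTED = [
    ("weighted_degree", False),
    ("weighted_clustering_coefficient", False),
    ("weighted_pagerank", False),
    ("effective_size", False),
    ("closeness_vitality", True),
]


def catalogue() -> list[MeasureDescriptor]:
    """Fixed, versioned catalogue of all 69 measures (36/7/21/5)."""
    cat: list[MeasureDescriptor] = []
    for names, category in (
        (_GLOBAL_BINARY, "global_binary"),
        (_GLOBAL_WEIGHTED, "global_weighted"),
        (_LOCAL_BINARY, "local_binary"),
        (_LOCAL_WEIGHTED, "local_weighted"),
    ):
        for name, req in names:
            cat.append(MeasureDescriptor(name, category, req))
    counts = {c: sum(1 for d in cat if d.category == c) for c in CATEGORY_SIZES}
    assert counts == CATEGORY_SIZES, f"catalogue size drift: {counts}"
    assert len({d.name for d in cat}) == len(cat), "duplicate measure names"
    return cat


def measure_names(category: Category) -> list[str]:
    return [d.name for d in catalogue() if d.category == category]


def local_measure_names() -> list[str]:
    return measure_names("local_binary") + measure_names("local_weighted")


def global_measure_names() -> list[str]:
    return measure_names("global_binary") + measure_names("global_weighted")


# ---------------------------------------------------------------------------
# binary-graph computations


def _binary_context(gb: BinaryGraph) -> dict:
    A = np.asarray(gb.A, dtype=float)
    G = to_networkx(gb)
    n = A.shape[0]
    deg = A.sum(axis=0)
    dist = shortest_path(csr_matrix(A), method="D", unweighted=True)
    n_comp = nx.number_connected_components(G) if n else 0
    cliques = list(nx.find_cliques(G)) if G.number_of_edges() else [[v] for v in G]
    eig = np.linalg.eigvalsh(A)
    return {
        "A": A, "G": G, "n": n, "deg": deg, "dist": dist,
        "connected": n_comp == 1, "n_comp": n_comp, "cliques": cliques,
        "eig": eig,
    }


def _finite_or(x: float, default: float = 0.0) -> float:
    return float(x) if np.isfinite(x) else default


def _global_binary_values(ctx: dict) -> dict[str, float]:
    A, G, n, deg, dist = ctx["A"], ctx["G"], ctx["n"], ctx["deg"], ctx["dist"]
    eig = ctx["eig"]
    connected = ctx["connected"]
    m = G.number_of_edges()
    off = dist[np.triu_indices(n, k=1)]
    finite = off[np.isfinite(off)]
    comps = [len(c) for c in nx.connected_components(G)]
    vals: dict[str, float] = {}
    vals["number_of_edges"] = float(m)
    vals["density"] = nx.density(G)
    vals["mean_degree"] = float(deg.mean())
    vals["degree_std"] = float(deg.std())
    vals["max_degree"] = float(deg.max())
    vals["min_degree"] = float(deg.min())
    vals["number_of_isolates"] = float(np.sum(deg == 0))
    vals["connected_component_count"] = float(ctx["n_comp"])
    vals["largest_component_fraction"] = max(comps) / n
    vals["transitivity"] = nx.transitivity(G)
    vals["global_clustering"] = nx.average_clustering(G)
    vals["triangle_count"] = sum(nx.triangles(G).values()) / 3.0
    with np.errstate(invalid="ignore", divide="ignore"):
        assort = nx.degree_assortativity_coefficient(G) if m else np.nan
    vals["degree_assortativity"] = _finite_or(assort, 0.0)
    vals["maximal_clique_count"] = float(len(ctx["cliques"]))
    vals["clique_number"] = float(max(len(c) for c in ctx["cliques"]))
    if connected and n > 1:
        vals["average_shortest_path_length"] = float(off.mean())
        vals["diameter"] = float(off.max())
        ecc = dist.max(axis=1)
        vals["radius"] = float(ecc.min())
        vals["average_eccentricity"] = float(ecc.mean())
        vals["wiener_index"] = float(off.sum())
        vals["stoer_wagner_cut"] = float(nx.stoer_wagner(G)[0])
    elif connected:  # single node
        for k in ("average_shortest_path_length", "diameter", "radius",
                  "average_eccentricity", "wiener_index", "stoer_wagner_cut"):
            vals[k] = 0.0
    else:
        for k in ("average_shortest_path_length", "diameter", "radius",
                  "average_eccentricity", "wiener_index", "stoer_wagner_cut"):
            vals[k] = np.nan
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(off) & (off > 0), 1.0 / off, 0.0)
    vals["global_efficiency"] = float(2.0 * inv.sum() / (n * (n - 1))) if n > 1 else 0.0
    vals["local_efficiency"] = nx.local_efficiency(G)
    if n > 1:
        lr = (np.isfinite(dist).sum(axis=1) - 1) / (n - 1)
        vals["global_reaching_centrality"] = float((lr.max() - lr).sum() / (n - 1))
    else:
        vals["global_reaching_centrality"] = 0.0
    coloring = nx.greedy_color(G, strategy="largest_first")
    vals["greedy_coloring_number"] = float(max(coloring.values()) + 1)
    if m:
        communities = nx.community.greedy_modularity_communities(G)
        vals["greedy_modularity"] = nx.community.modularity(G, communities)
        vals["greedy_community_count"] = float(len(communities))
    else:
        vals["greedy_modularity"] = 0.0
        vals["greedy_community_count"] = float(n)
    vals["spectral_radius"] = float(eig[-1])
    vals["spectral_gap"] = float(eig[-1] - eig[-2]) if n > 1 else 0.0
    lap_eig = np.linalg.eigvalsh(np.diag(deg) - A)
    vals["algebraic_connectivity"] = float(lap_eig[1]) if n > 1 else 0.0
    vals["graph_energy"] = float(np.abs(eig).sum())
    vals["estrada_index"] = float(np.exp(eig).sum())
    rows, cols = np.nonzero(np.triu(A, k=1))
    vals["s_metric"] = float(np.sum(deg[rows] * deg[cols]))
    nbr = nx.average_neighbor_degree(G)
    vals["mean_neighbor_degree"] = float(np.mean(list(nbr.values()))) if nbr else 0.0
    vals["degeneracy"] = float(max(nx.core_number(G).values())) if n else 0.0
    counts = np.bincount(deg.astype(int))
    p = counts[counts > 0] / n
    vals["degree_entropy"] = float(-(p * np.log(p)).sum())
    return vals


def _local_binary_values(ctx: dict) -> pd.DataFrame:
    A, G, n, deg, dist = ctx["A"], ctx["G"], ctx["n"], ctx["deg"], ctx["dist"]
    connected = ctx["connected"]
    nodes = list(range(n))
    out: dict[str, np.ndarray] = {}

    def from_dict(d: dict) -> np.ndarray:
        return np.array([d[v] for v in nodes], dtype=float)

    out["degree_centrality"] = from_dict(nx.degree_centrality(G))
    out["betweenness_centrality"] = from_dict(nx.betweenness_centrality(G, normalized=True))
    out["closeness_centrality"] = from_dict(nx.closeness_centrality(G))
    out["load_centrality"] = from_dict(nx.load_centrality(G, normalized=True))
    # principal eigenvector of A, nonnegative by Perron-Frobenius (abs fixes sign)
    w, V = np.linalg.eigh(A)
    v1 = np.abs(V[:, -1])
    norm = np.linalg.norm(v1)
    out["eigenvector_centrality"] = v1 / norm if norm > 0 else np.full(n, 1 / np.sqrt(n))
    out["pagerank_centrality"] = from_dict(nx.pagerank(G, alpha=0.85))
    lam = ctx["eig"][-1]
    alpha = 0.85 / lam if lam > 0 else 0.1
    if n > 1:
        out["katz_centrality"] = from_dict(nx.katz_centrality_numpy(G, alpha=alpha))
    else:
        out["katz_centrality"] = np.ones(n)
    out["harmonic_centrality"] = from_dict(nx.harmonic_centrality(G))
    # fraction of other nodes reachable (undirected unweighted reading)
    if n > 1:
        out["local_reaching_centrality"] = (
            np.isfinite(dist).sum(axis=1) - 1) / (n - 1)
    else:
        out["local_reaching_centrality"] = np.zeros(n)
    out["clustering_coefficient"] = from_dict(nx.clustering(G))
    out["triangles"] = from_dict(nx.triangles(G))
    out["core_number"] = from_dict(nx.core_number(G))
    if connected:
        out["eccentricity"] = dist.max(axis=1)
    else:
        out["eccentricity"] = np.full(n, np.nan)
    out["average_neighbor_degree"] = from_dict(nx.average_neighbor_degree(G))
    ncn = np.ones(n)
    ncc = np.zeros(n)
    for c in ctx["cliques"]:
        for v in c:
            ncc[v] += 1
            ncn[v] = max(ncn[v], len(c))
    out["node_clique_number"] = ncn
    out["node_maximal_clique_count"] = ncc
    out["greedy_color_index"] = from_dict(nx.greedy_color(G, strategy="largest_first"))
    out["subgraph_centrality"] = from_dict(nx.subgraph_centrality(G)) if G.number_of_edges() else np.ones(n)
    constraint = nx.constraint(G)
    out["burt_constraint"] = np.array(
        [_finite_or(constraint[v], 0.0) for v in nodes]
    )
    art = set(nx.articulation_points(G))
    out["articulation_point"] = np.array([float(v in art) for v in nodes])
    if connected and n > 2:
        out["current_flow_closeness"] = from_dict(nx.current_flow_closeness_centrality(G))
    else:
        out["current_flow_closeness"] = np.full(n, np.nan)
    return pd.DataFrame(out, columns=[name for name, _ in _LOCAL_BINARY])


# ---------------------------------------------------------------------------
# weighted-graph computations


def _weighted_context(gw: ConnectivityMatrix) -> dict:
    W = gw.W
    n = W.shape[0]
    G = to_networkx_weighted(gw)
    with np.errstate(divide="ignore"):
        length = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), 0.0)
    dist = shortest_path(csr_matrix(length), method="D", directed=False)
    strength = W.sum(axis=0)
    connected = np.isfinite(dist).all()
    return {"W": W, "G": G, "n": n, "dist": dist, "strength": strength,
            "connected": connected, "length": length}


def _fiedler_partition(W: np.ndarray) -> np.ndarray | None:
    """Sign partition of the normalized-Laplacian Fiedler vector."""
    d = W.sum(axis=0)
    if np.all(d == 0):
        return None
    dinv = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    L = np.eye(len(d)) - (dinv[:, None] * W * dinv[None, :])
    w, V = np.linalg.eigh(L)
    f = V[:, 1]
    side = f > 0
    if side.all() or not side.any():
        side = f > np.median(f)
        if side.all() or not side.any():
            return None
    return side


def _global_weighted_values(ctx: dict) -> dict[str, float]:
    W, G, n, dist = ctx["W"], ctx["G"], ctx["n"], ctx["dist"]
    off = dist[np.triu_indices(n, k=1)]
    weights = W[np.triu_indices(n, k=1)]
    present = weights[weights > 0]
    vals: dict[str, float] = {}
    vals["total_edge_weight"] = float(present.sum())
    vals["mean_edge_weight"] = float(present.mean()) if present.size else 0.0
    vals["strength_std"] = float(ctx["strength"].std())
    vals["weighted_global_clustering"] = (
        nx.average_clustering(G, weight="weight") if G.number_of_edges() else 0.0
    )
    if ctx["connected"]:
        vals["dijkstra_path_length"] = float(off.mean())
        vals["weighted_wiener_index"] = float(off.sum())
    else:
        vals["dijkstra_path_length"] = np.nan
        vals["weighted_wiener_index"] = np.nan
    side = _fiedler_partition(W)
    strength = ctx["strength"]
    if side is None or strength[side].sum() == 0 or strength[~side].sum() == 0:
        vals["conductance"] = np.nan
    else:
        S = set(np.flatnonzero(side))
        vals["conductance"] = nx.conductance(G, S, weight="weight")
    return vals


def _closeness_vitality_weighted(ctx: dict) -> np.ndarray:
    """Change in weighted Wiener index when each node is removed.

    Removal that disconnects the remainder yields -inf in the usual
    convention; mapped to NaN here to keep the table numeric-or-missing.
    """
    n = ctx["n"]
    length = ctx["length"]
    base = ctx["dist"][np.triu_indices(n, k=1)].sum()
    out = np.empty(n)
    keep_all = np.arange(n)
    for v in range(n):
        keep = keep_all[keep_all != v]
        sub = length[np.ix_(keep, keep)]
        d = shortest_path(csr_matrix(sub), method="D", directed=False)
        s = d[np.triu_indices(n - 1, k=1)].sum()
        out[v] = base - s if np.isfinite(s) else np.nan
    return out


def _local_weighted_values(ctx: dict) -> pd.DataFrame:
    W, G, n = ctx["W"], ctx["G"], ctx["n"]
    nodes = list(range(n))

    def from_dict(d: dict, default: float = 0.0) -> np.ndarray:
        return np.array([_finite_or(d.get(v, default), default) for v in nodes])

    out: dict[str, np.ndarray] = {}
    out["weighted_degree"] = ctx["strength"]
    out["weighted_clustering_coefficient"] = from_dict(nx.clustering(G, weight="weight"))
    out["weighted_pagerank"] = from_dict(nx.pagerank(G, alpha=0.85, weight="weight"))
    out["effective_size"] = from_dict(nx.effective_size(G, weight="weight"))
    if ctx["connected"]:
        out["closeness_vitality"] = _closeness_vitality_weighted(ctx)
    else:
        out["closeness_vitality"] = np.full(n, np.nan)
    return pd.DataFrame(out, columns=[name for name, _ in _LOCAL_WEIGHTED])


# ---------------------------------------------------------------------------
# public API


def compute_global(gb: BinaryGraph, gw: ConnectivityMatrix) -> pd.Series:
    """All 43 global measures (36 binary on gb + 7 weighted on gw)."""
    vals = _global_binary_values(_binary_context(gb))
    vals.update(_global_weighted_values(_weighted_context(gw)))
    return pd.Series(vals, index=global_measure_names(), dtype=float)


def compute_local(gb: BinaryGraph, gw: ConnectivityMatrix) -> pd.DataFrame:
    """N x 26 local measures (21 binary + 5 weighted), one row per ROI."""
    left = _local_binary_values(_binary_context(gb))
    right = _local_weighted_values(_weighted_context(gw))
    df = pd.concat([left, right], axis=1)
    df.index.name = "roi_id"
    return df


@dataclass
class FeatureTables:
    """Tidy per-cohort feature tables at one binarization threshold."""

    tau: float
    global_df: pd.DataFrame          # subjects x 43
    local_df: pd.DataFrame           # subjects x (N*26), columns roiXXX__measure
    labels: np.ndarray
    connected: np.ndarray            # per-subject: no disconnection at this tau

    @property
    def global_binary_df(self) -> pd.DataFrame:
        return self.global_df[measure_names("global_binary")]


def local_column_names(n_roi: int) -> list[str]:
    return [f"roi{i:03d}__{m}" for i in range(n_roi) for m in local_measure_names()]


def feature_table(cohort: Cohort, tau: float, scope: str = "both") -> FeatureTables:
    """Binarize every subject at tau and compute the requested feature blocks."""
    if scope not in ("global", "local", "both"):
        raise ConnectomlError(f"unknown scope {scope!r}")
    g_rows, l_rows, ids, conn = [], [], [], []
    for s in cohort:
        gb = binarize(s.matrix, tau)
        ids.append(s.matrix.subject_id)
        conn.append(int(np.sum(gb.A.sum(axis=0) == 0)) == 0
                    and nx.number_connected_components(to_networkx(gb)) == 1)
        if scope in ("global", "both"):
            g_rows.append(compute_global(gb, s.matrix))
        if scope in ("local", "both"):
            l_rows.append(compute_local(gb, s.matrix).to_numpy().ravel())
    n_roi = cohort.n_roi
    global_df = (pd.DataFrame(g_rows, index=ids) if g_rows
                 else pd.DataFrame(index=ids))
    local_df = (pd.DataFrame(np.array(l_rows), index=ids,
                             columns=local_column_names(n_roi)) if l_rows
                else pd.DataFrame(index=ids))
    return FeatureTables(tau=tau, global_df=global_df, local_df=local_df,
                         labels=cohort.labels, connected=np.array(conn, dtype=bool))


def group_contrast(df: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Patient/control ratio of group means per feature column.

    Returns columns mean_control, mean_patient, ratio; a zero control mean
    is flagged with ratio NaN rather than inf.
    """
    labels = np.asarray(labels)
    if len(set(labels)) < 2:
        raise ConnectomlError("group_contrast needs both classes present")
    m0 = df[labels == 0].mean(axis=0)
    m1 = df[labels == 1].mean(axis=0)
    ratio = pd.Series(np.where(m0 != 0, m1 / m0.replace(0, np.nan), np.nan),
                      index=df.columns)
    return pd.DataFrame({"mean_control": m0, "mean_patient": m1, "ratio": ratio})
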