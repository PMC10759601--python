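"""Weighted brain-graph construction and binarization.

The chain is: sample Pearson correlation between every pair of ROI time
series, Fisher z-transform (artanh) the correlations, set negative weights
to zero (negative functional coupling has no agreed biological reading),
then threshold to obtain unweighted graphs.  Thresholding is strict
(edge iff W > tau) so that tau = 0 keeps exactly the positively correlated
pairs.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .datamodel import (
    BinaryGraph,
    ConnectivityMatrix,
    ConnectomlError,
    RoiTimeSeries,
)

DEFAULT_Z_MAX = 3.8002  # artanh(0.999); cap for |r| = 1


def pearson_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pairwise sample Pearson correlation of ROI columns, zero diagonal."""
    r = np.corrcoef(ts.data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(subject_id=ts.subject_id, W=r, stage="raw_pcc")


def fisher_transform(m: ConnectivityMatrix, z_max: float = DEFAULT_Z_MAX) -> ConnectivityMatrix:
    """Variance-stabilizing artanh of the correlations; |r| = 1 capped at z_max."""
    if m.stage != "raw_pcc":
        raise ConnectomlError(f"fisher_transform expects raw_pcc stage, got {m.stage}")
    r = m.W
    with np.errstate(divide="ignore"):
        Z = np.arctanh(np.clip(r, -1.0, 1.0))
    Z = np.where(np.isinf(Z), np.sign(r) * z_max, Z)
    Z = np.clip(Z, -z_max, z_max)
    np.fill_diagonal(Z, 0.0)
    return ConnectivityMatrix(subject_id=m.subject_id, W=Z, stage="fisher")


def rectify_negative(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Set negative Fisher-z weights to zero (idempotent)."""
    if m.stage not in ("fisher", "rectified"):
        raise ConnectomlError(f"rectify_negative expects fisher stage, got {m.stage}")
    return ConnectivityMatrix(subject_id=m.subject_id, W=np.maximum(m.W, 0.0),
                              stage="rectified")


def connectome_from_timeseries(ts: RoiTimeSeries, z_max: float = DEFAULT_Z_MAX) -> ConnectivityMatrix:
    """Full chain: Pearson -> Fisher z -> rectification."""
    return rectify_negative(fisher_transform(pearson_matrix(ts), z_max=z_max))


def binarize(m: ConnectivityMatrix, tau: float) -> BinaryGraph:
    """Threshold the rectified weights: edge present iff W > tau (strict)."""
    if m.stage != "rectified":
        raise ConnectomlError(f"binarize expects rectified stage, got {m.stage}")
    if not 0.0 <= tau < 1.0:
        raise ConnectomlError("tau must lie in [0, 1)")
    A = (m.W > tau).astype(np.int8)
    np.fill_diagonal(A, 0)
    return BinaryGraph(subject_id=m.subject_id, A=A, tau=tau)


def isolate_count(g: BinaryGraph) -> int:
    """Number of degree-zero nodes; > 0 flags the graph as disconnected for
    threshold bookkeeping (path-based measures become incomputable)."""
    return int(np.sum(g.A.sum(axis=0) == 0))


def to_networkx(g: BinaryGraph) -> nx.Graph:
    G = nx.from_numpy_array(np.asarray(g.A, dtype=int))
    for _, _, d in G.edges(data=True):
        d.pop("weight", None)
    return G


def to_networkx_weighted(m: ConnectivityMatrix) -> nx.Graph:
    """Weighted graph on strictly positive rectified weights."""
    G = nx.from_numpy_array(m.W)
    zero = [(u, v) for u, v, d in G.edges(data=True) if d["weight"] <= 0]
    G.remove_edges_from(zero)
    return G
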