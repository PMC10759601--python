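"""Biomarker discovery: RLF pair selection and SpeCo co-occurrence detection.

**RLF** treats every (ROI, local-feature) pair as an independent predictor
(164 x 26 = 4,264 columns), scores each column by a univariate two-class
ANOVA F statistic and/or by mean absolute Shapley attribution from a tree
ensemble, keeps the top 100 pairs, and ranks ROIs by how often they recur
among those pairs.

**SpeCo** spectrally clusters each subject's weighted connectome, counts
for each diagnostic group how often every ROI pair lands in the same
cluster, thresholds the counts by a statistical majority (90-95%), and
reports pairs that co-occur in exactly one group as discriminative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.cluster import KMeans
from sklearn.feature_selection import f_classif

from .datamodel import Cohort, ConnectivityMatrix, ConnectomlError, stage_seed


@dataclass(frozen=True)
class RlfPair:
    roi_id: int
    measure: str
    score: float


# ---------------------------------------------------------------------------
# Method 1: RLF


def _split_column(name: str) -> tuple[int, str]:
    roi, measure = name.split("__", 1)
    return int(roi.removeprefix("roi")), measure


def rlf_scores(local_df: pd.DataFrame, labels: np.ndarray,
               method: str = "univariate",
               attributor=None) -> list[RlfPair]:
    """Score every (ROI, measure) column; constant columns score 0.

    ``univariate`` uses the two-class ANOVA F statistic; ``shapley`` uses
    mean |attribution| from a fitted tree ensemble via ``attributor``
    (a callable (model, X) -> per-column scores, typically
    ``explain.feature_attribution`` wrapped with a fitted model).
    """
    labels = np.asarray(labels)
    if len(set(labels)) < 2:
        raise ConnectomlError("rlf_scores needs both classes")
    X = local_df.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ConnectomlError("RLF features must be finite")
    if method == "univariate":
        const = X.std(axis=0) == 0
        F = np.zeros(X.shape[1])
        if (~const).any():
            with np.errstate(divide="ignore", invalid="ignore"):
                fvals, _ = f_classif(X[:, ~const], labels)
            # a perfectly separating column has an infinite F statistic
            F[~const] = np.nan_to_num(fvals, nan=0.0, posinf=1e12)
    elif method == "shapley":
        if attributor is None:
            raise ConnectomlError("shapley scoring requires an attributor")
        F = np.asarray(attributor(X, labels), dtype=float)
        if F.shape != (X.shape[1],):
            raise ConnectomlError("attributor must return one score per column")
    else:
        raise ConnectomlError(f"unknown RLF method {method!r}")
    pairs = []
    for name, score in zip(local_df.columns, F):
        roi, measure = _split_column(name)
        pairs.append(RlfPair(roi_id=roi, measure=measure, score=float(max(score, 0.0))))
    return pairs


def rlf_select(pairs: list[RlfPair], top_m: int = 100) -> list[RlfPair]:
    """Exactly top_m highest-scoring pairs; ties by (roi_id, measure)."""
    if len(pairs) < top_m:
        raise ConnectomlError(f"only {len(pairs)} pairs available, need {top_m}")
    ordered = sorted(pairs, key=lambda p: (-p.score, p.roi_id, p.measure))
    return ordered[:top_m]


def roi_frequency(selected: list[RlfPair]) -> pd.Series:
    """Occurrences of each ROI among selected pairs, descending; sums to m."""
    if not selected:
        raise ConnectomlError("empty RLF selection")
    counts = pd.Series([p.roi_id for p in selected]).value_counts()
    counts.index.name = "roi_id"
    return counts


# ---------------------------------------------------------------------------
# Method 2: SpeCo


def spectral_partition(m: ConnectivityMatrix, k: int, seed: int = 0) -> np.ndarray:
    """Normalized-Laplacian spectral embedding + seeded k-means.

    Embeds ROIs in the k smallest eigenvectors of
    L_sym = I - D^{-1/2} W D^{-1/2} (rows normalized to unit length) and
    clusters with k-means.  Zero-strength ROIs embed at the origin.
    """
    W = m.W
    n = W.shape[0]
    if not 2 <= k <= n:
        raise ConnectomlError(f"need 2 <= k <= {n}, got {k}")
    d = W.sum(axis=0)
    if np.all(d == 0):
        raise ConnectomlError("all-zero connectivity: nothing to cluster")
    dinv = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    L = np.eye(n) - dinv[:, None] * W * dinv[None, :]
    _, V = eigh(L, subset_by_index=(0, k - 1))
    norms = np.linalg.norm(V, axis=1)
    U = V / np.where(norms > 0, norms, 1.0)[:, None]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(U)


@dataclass
class CooccurrenceMatrix:
    counts: np.ndarray
    group: int
    group_size: int
    k: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if not np.array_equal(c, c.T):
            raise ConnectomlError("co-occurrence counts must be symmetric")
        if np.any(np.diag(c) != self.group_size):
            raise ConnectomlError("co-occurrence diagonal must equal group size")
        if c.min() < 0 or c.max() > self.group_size:
            raise ConnectomlError("counts must lie in [0, group size]")


def cooccurrence(partitions: list[np.ndarray], group: int, k: int) -> CooccurrenceMatrix:
    """counts[i, j] = number of subjects placing ROIs i and j together."""
    if not partitions:
        raise ConnectomlError("no partitions given")
    n = len(partitions[0])
    counts = np.zeros((n, n), dtype=int)
    for p in partitions:
        p = np.asarray(p)
        if len(p) != n:
            raise ConnectomlError("partitions cover inconsistent ROI sets")
        counts += (p[:, None] == p[None, :]).astype(int)
    return CooccurrenceMatrix(counts=counts, group=group,
                              group_size=len(partitions), k=k)


def majority_pairs(cm: CooccurrenceMatrix, theta: float) -> set[tuple[int, int]]:
    """Pairs co-occurring in at least theta of the group (inclusive >=)."""
    if not 0 < theta <= 1:
        raise ConnectomlError("theta must lie in (0, 1]")
    frac = cm.counts / cm.group_size
    iu, ju = np.triu_indices(cm.counts.shape[0], k=1)
    hit = frac[iu, ju] >= theta
    return {(int(i), int(j)) for i, j in zip(iu[hit], ju[hit])}


def discriminative_pairs(
    patient: set[tuple[int, int]], control: set[tuple[int, int]]
) -> dict[tuple[int, int], str]:
    """Symmetric difference tagged by source group."""
    out: dict[tuple[int, int], str] = {}
    for p in patient - control:
        out[p] = "patient"
    for p in control - patient:
        out[p] = "control"
    return out


@dataclass
class SpecoSetting:
    k: int
    theta: float
    patient_cm: CooccurrenceMatrix
    control_cm: CooccurrenceMatrix
    patient_pairs: set[tuple[int, int]]
    control_pairs: set[tuple[int, int]]
    informative: dict[tuple[int, int], str]


def speco(
    cohort: Cohort,
    k_range: tuple[int, ...] = (2, 3, 4, 5),
    theta_range: tuple[float, ...] = (0.90, 0.95),
    seed: int = 0,
) -> list[SpecoSetting]:
    """Full (k, theta) sweep of the SpeCo procedure over a labelled cohort."""
    y = cohort.labels
    if len(set(y.tolist())) < 2:
        raise ConnectomlError("speco needs both groups")
    out = []
    for k in k_range:
        parts: dict[int, list[np.ndarray]] = {0: [], 1: []}
        for s in cohort:
            p = spectral_partition(s.matrix, k,
                                   seed=stage_seed(seed, f"speco-k{k}"))
            parts[s.label].append(p)
        cm1 = cooccurrence(parts[1], group=1, k=k)
        cm0 = cooccurrence(parts[0], group=0, k=k)
        for theta in theta_range:
            sp = majority_pairs(cm1, theta)
            sc = majority_pairs(cm0, theta)
            out.append(SpecoSetting(
                k=k, theta=theta, patient_cm=cm1, control_cm=cm0,
                patient_pairs=sp, control_pairs=sc,
                informative=discriminative_pairs(sp, sc),
            ))
    return out


@dataclass
class BiomarkerReport:
    """Ranked ROIs (RLF) and discriminative ROI pairs (SpeCo)."""

    rlf_top_pairs: list[RlfPair]
    roi_ranking: pd.Series
    speco_settings: list[SpecoSetting] = field(default_factory=list)

    def speco_informative_union(self) -> set[tuple[int, int]]:
        u: set[tuple[int, int]] = set()
        for s in self.speco_settings:
            u |= set(s.informative)
        return u
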