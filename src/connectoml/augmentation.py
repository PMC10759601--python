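"""Consensus-labelled cohort augmentation.

New minority-class subjects are minted by adding uniform noise from
(0.0, 0.3) to 5 randomly chosen off-diagonal ROI pairs of an existing
rectified matrix (10 of 164 x 164 entries — 0.037% — so the brain-graph
geometry is essentially preserved).  A Random Forest and an XGBoost model
trained on the original cohort's global binary features vote on the label;
ties are dropped, and only minority-class synthetics are retained until
the classes balance.
"""

from __future__ import annotations

import warnings

import numpy as np

from .connectome import binarize
from .datamodel import Cohort, ConnectivityMatrix, ConnectomlError, Subject
from .features import compute_global, measure_names
from .ml import LABELER_MODELS, make_pipeline

DROP = "DROP"


def perturb_matrix(
    m: ConnectivityMatrix,
    n_pairs: int = 5,
    noise_lo: float = 0.0,
    noise_hi: float = 0.3,
    seed: int = 0,
    subject_id: str | None = None,
) -> ConnectivityMatrix:
    """Perturb exactly n_pairs distinct unordered off-diagonal pairs.

    Each pair receives one delta drawn from U(noise_lo, noise_hi), applied
    to both (i, j) and (j, i), so 2*n_pairs entries change.  Fisher-z
    weights are unbounded above, so no clipping is applied.
    """
    n = m.n_roi
    iu, ju = np.triu_indices(n, k=1)
    if n_pairs > len(iu):
        raise ConnectomlError(f"n_pairs={n_pairs} exceeds {len(iu)} available pairs")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(iu), size=n_pairs, replace=False)
    deltas = rng.uniform(noise_lo, noise_hi, size=n_pairs)
    W = m.W.copy()
    W[iu[chosen], ju[chosen]] += deltas
    W[ju[chosen], iu[chosen]] += deltas
    return ConnectivityMatrix(
        subject_id=subject_id or f"{m.subject_id}+aug{seed}",
        W=W,
        stage=m.stage,
    )


class ConsensusLabeler:
    """Two-model consensus: unanimous vote labels, disagreement drops."""

    def __init__(self, tau: float, seed: int = 0,
                 model_names: tuple[str, str] = LABELER_MODELS):
        self.tau = tau
        self.seed = seed
        self.model_names = model_names
        self._models = None
        self._feature_names = measure_names("global_binary")

    def _features(self, m: ConnectivityMatrix) -> np.ndarray:
        row = compute_global(binarize(m, self.tau), m)
        return row[self._feature_names].to_numpy(dtype=float)

    def fit(self, cohort: Cohort) -> "ConsensusLabeler":
        orig = cohort.originals()
        X = np.array([self._features(s.matrix) for s in orig])
        y = orig.labels
        self._models = []
        for name in self.model_names:
            pipe = make_pipeline(name, self.seed)
            pipe.fit(X, y)
            self._models.append(pipe)
        return self

    def label(self, m: ConnectivityMatrix) -> int | str:
        if self._models is None:
            raise ConnectomlError("consensus labeler is not fitted")
        x = self._features(m)[None, :]
        votes = [int(mod.predict(x)[0]) for mod in self._models]
        return votes[0] if len(set(votes)) == 1 else DROP


def balance_cohort(
    cohort: Cohort,
    tau: float,
    n_pairs: int = 5,
    noise_lo: float = 0.0,
    noise_hi: float = 0.3,
    target_ratio: float = 1.0,
    seed: int = 0,
    max_attempts: int | None = None,
    labeler: ConsensusLabeler | None = None,
) -> Cohort:
    """Augment the minority class until class counts balance (or a cap hits).

    Original subjects are never modified; synthetics carry provenance
    ``augmented`` and are minted from randomly chosen minority-class
    sources, labelled by consensus, and kept only when the consensus label
    equals the minority class.
    """
    n0, n1 = cohort.counts()
    if n0 == 0 or n1 == 0:
        raise ConnectomlError("both classes must be present")
    minority = 1 if n1 < n0 else 0
    need = int(round(max(n0, n1) * target_ratio)) - min(n0, n1)
    if need <= 0:
        return cohort
    if labeler is None:
        labeler = ConsensusLabeler(tau=tau, seed=seed).fit(cohort)
    sources = [s for s in cohort if s.label == minority and s.provenance == "original"]
    rng = np.random.default_rng(seed)
    cap = max_attempts if max_attempts is not None else 20 * need
    new_subjects = list(cohort.subjects)
    made = 0
    attempts = 0
    while made < need and attempts < cap:
        attempts += 1
        src = sources[rng.integers(len(sources))]
        pert_seed = int(rng.integers(2**31 - 1))
        m = perturb_matrix(src.matrix, n_pairs, noise_lo, noise_hi,
                           seed=pert_seed,
                           subject_id=f"aug{made:03d}_{src.matrix.subject_id}")
        lab = labeler.label(m)
        if lab == minority:
            new_subjects.append(Subject(matrix=m, label=minority,
                                        provenance="augmented"))
            made += 1
    if made < need:
        warnings.warn(
            f"augmentation cap reached: produced {made}/{need} accepted "
            f"minority synthetics in {attempts} attempts",
            stacklevel=2,
        )
    return Cohort(new_subjects)
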