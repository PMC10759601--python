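"""Synthetic ROI-time-series cohorts with planted group structure.

The generator emulates the statistical structure the downstream analysis
assumes: block-structured ROI correlations (functional communities), class
imbalance, and planted patient/control differences.  Subject time series are
drawn from a zero-mean multivariate Gaussian whose correlation matrix encodes
the group structure — the Pearson/Fisher pipeline only consumes second-order
structure, so no hemodynamic model is needed.

Patient-group perturbations, all scaled by ``effect_strength``:

* a fraction of within-block ROI pairs is rewired to the between-block
  correlation level (and a smaller fraction of between-block pairs promoted),
  which after binarization lowers the clustering coefficient, raises the
  average shortest path length, and fragments the dense blocks into many
  overlapping maximal cliques — the three planted group contrasts;
* each *informative ROI* migrates: its ties to its home block are demoted
  and ties to a neighbouring block promoted, concentrating discriminative
  signal in that ROI's local features;
* for each *differing pair* (i, j), ROI j migrates into i's block, so the
  pair co-clusters in patients but not controls.

With ``effect_strength = 0`` the two groups are exchangeable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .connectome import connectome_from_timeseries
from .datamodel import Cohort, ConnectomlError, RoiTimeSeries, Subject, stage_seed

PD_EIG_FLOOR = 1e-6


@dataclass(frozen=True)
class SimSpec:
    """Study-design parameters of a synthetic cohort."""

    n_control: int = 122
    n_patient: int = 50
    n_roi: int = 164
    T: int = 150
    n_blocks: int = 8
    within_block_r: float = 0.45
    between_block_r: float = 0.10
    effect_strength: float = 1.0
    rewire_frac: float = 0.50
    promote_frac: float = 0.0
    informative_rois: tuple[int, ...] = ()
    differing_pairs: tuple[tuple[int, int], ...] = ()
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_patient < 2:
            raise ConnectomlError("need at least 2 subjects per group")
        if not self.within_block_r > self.between_block_r:
            raise ConnectomlError("within_block_r must exceed between_block_r")
        if not (0 <= self.between_block_r and self.within_block_r < 1):
            raise ConnectomlError("correlation targets must lie in [0, 1)")
        if any(not 0 <= i < self.n_roi for i in self.informative_rois):
            raise ConnectomlError("informative_rois outside atlas range")
        for i, j in self.differing_pairs:
            if i == j or not (0 <= i < self.n_roi and 0 <= j < self.n_roi):
                raise ConnectomlError(f"bad differing pair ({i}, {j})")

    def block_of(self) -> np.ndarray:
        """Block membership per ROI (contiguous, near-equal blocks)."""
        sizes = [len(b) for b in np.array_split(np.arange(self.n_roi), self.n_blocks)]
        return np.repeat(np.arange(self.n_blocks), sizes)


@dataclass
class CohortTruth:
    """Ground-truth record for recovery tests."""

    informative_rois: tuple[int, ...]
    differing_pairs: tuple[tuple[int, int], ...]
    effect_strength: float
    blocks: list[int]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CohortTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            informative_rois=tuple(d["informative_rois"]),
            differing_pairs=tuple(tuple(p) for p in d["differing_pairs"]),
            effect_strength=d["effect_strength"],
            blocks=list(d["blocks"]),
        )


def nearest_pd_correlation(C: np.ndarray, eig_floor: float = PD_EIG_FLOOR) -> np.ndarray:
    """Clip eigenvalues at eig_floor and renormalize to unit diagonal."""
    C = (C + C.T) / 2.0
    w, V = np.linalg.eigh(C)
    if w.min() >= eig_floor:
        return C
    w = np.clip(w, eig_floor, None)
    C = (V * w) @ V.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return (C + C.T) / 2.0


def _migrate(C: np.ndarray, roi: int, home: np.ndarray, target: np.ndarray,
             within: float, between: float, strength: float) -> None:
    """Move `roi`'s correlation profile from its home block toward `target`."""
    lo = between + (1 - strength) * (within - between)
    hi = between + strength * (within - between)
    for m in home:
        if m != roi:
            C[roi, m] = C[m, roi] = lo
    for m in target:
        if m != roi:
            C[roi, m] = C[m, roi] = hi


def block_covariance(spec: SimSpec, group: int) -> np.ndarray:
    """Group-level ROI correlation matrix (symmetric positive definite).

    Group 0 is the plain block model; group 1 additionally carries the
    planted perturbations described in the module docstring.
    """
    if group not in (0, 1):
        raise ConnectomlError("group must be 0 or 1")
    blocks = spec.block_of()
    same = blocks[:, None] == blocks[None, :]
    C = np.where(same, spec.within_block_r, spec.between_block_r).astype(float)
    np.fill_diagonal(C, 1.0)

    eff = spec.effect_strength
    if group == 1 and eff > 0:
        rng = np.random.default_rng(stage_seed(spec.seed, "patient-structure"))
        iu, ju = np.triu_indices(spec.n_roi, k=1)
        within_pairs = np.flatnonzero(same[iu, ju])
        between_pairs = np.flatnonzero(~same[iu, ju])
        n_demote = int(round(eff * spec.rewire_frac * len(within_pairs)))
        n_promote = int(round(eff * spec.promote_frac * len(within_pairs)))
        demote = rng.choice(within_pairs, size=min(n_demote, len(within_pairs)),
                            replace=False)
        promote = rng.choice(between_pairs, size=min(n_promote, len(between_pairs)),
                             replace=False)
        C[iu[demote], ju[demote]] = C[ju[demote], iu[demote]] = spec.between_block_r
        C[iu[promote], ju[promote]] = C[ju[promote], iu[promote]] = spec.within_block_r

        members = [np.flatnonzero(blocks == b) for b in range(spec.n_blocks)]
        for roi in spec.informative_rois:
            b = blocks[roi]
            target = members[(b + 1) % spec.n_blocks]
            _migrate(C, roi, members[b], target, spec.within_block_r,
                     spec.between_block_r, eff)
        for i, j in spec.differing_pairs:
            _migrate(C, j, members[blocks[j]], members[blocks[i]],
                     spec.within_block_r, spec.between_block_r, eff)

    C = nearest_pd_correlation(C)
    if np.linalg.eigvalsh(C).min() <= 0:
        raise ConnectomlError("correlation targets infeasible: matrix not PD")
    return C


def sample_timeseries(cov: np.ndarray, T: int, seed: int,
                      subject_id: str = "sim") -> RoiTimeSeries:
    """T i.i.d. draws from N(0, cov)."""
    n = cov.shape[0]
    if T < n:
        import warnings

        warnings.warn(f"T={T} < N={n}: correlation matrix will be rank deficient",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    X = rng.standard_normal((T, n)) @ L.T
    return RoiTimeSeries(subject_id=subject_id, data=X)


def _subject_cov(base: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd <= 0:
        return base
    J = rng.normal(0.0, noise_sd, size=base.shape)
    C = base + (J + J.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return nearest_pd_correlation(np.clip(C, -0.999, 0.999))


def generate_cohort(spec: SimSpec) -> tuple[Cohort, CohortTruth]:
    """Simulate the full labelled cohort of rectified connectivity matrices."""
    covs = {g: block_covariance(spec, g) for g in (0, 1)}
    subjects = []
    counts = {0: spec.n_control, 1: spec.n_patient}
    prefix = {0: "ctrl", 1: "pat"}
    for group in (0, 1):
        for k in range(counts[group]):
            sid = f"{prefix[group]}{k:03d}"
            s_seed = stage_seed(spec.seed, f"subject-{sid}")
            rng = np.random.default_rng(s_seed)
            cov = _subject_cov(covs[group], spec.noise_sd, rng)
            ts = sample_timeseries(cov, spec.T, seed=stage_seed(s_seed, "ts"),
                                   subject_id=sid)
            subjects.append(
                Subject(matrix=connectome_from_timeseries(ts), label=group)
            )
    truth = CohortTruth(
        informative_rois=spec.informative_rois,
        differing_pairs=spec.differing_pairs,
        effect_strength=spec.effect_strength,
        blocks=[int(b) for b in spec.block_of()],
    )
    return Cohort(subjects), truth
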