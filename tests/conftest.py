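"""Shared fixtures: small synthetic cohorts, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from connectoml.features import feature_table
from connectoml.synthetic import SimSpec, generate_cohort

PLANTED_ROIS = (3, 17, 28)
PLANTED_PAIRS = ((2, 12), (5, 25), (8, 33))


@pytest.fixture(scope="session")
def strong_spec() -> SimSpec:
    """Strong planted effect, informative ROIs and differing pairs."""
    return SimSpec(
        n_control=25, n_patient=25, n_roi=40, T=120, n_blocks=4, seed=7,
        informative_rois=PLANTED_ROIS, differing_pairs=PLANTED_PAIRS,
    )


@pytest.fixture(scope="session")
def strong_cohort(strong_spec):
    cohort, truth = generate_cohort(strong_spec)
    return cohort, truth


@pytest.fixture(scope="session")
def strong_tables(strong_cohort):
    cohort, _ = strong_cohort
    return feature_table(cohort, 0.20, scope="both")


@pytest.fixture(scope="session")
def effect_tables():
    """Strong rewiring effect, no planted biomarker migrations: the cohort
    on which the three group-contrast directions are defined."""
    spec = SimSpec(n_control=15, n_patient=15, n_roi=40, T=120, n_blocks=4,
                   seed=5)
    cohort, _ = generate_cohort(spec)
    return feature_table(cohort, 0.20, scope="global")


@pytest.fixture(scope="session")
def tiny_cohort():
    """12-ROI cohort for fast plumbing tests."""
    spec = SimSpec(n_control=5, n_patient=4, n_roi=12, T=80, n_blocks=3, seed=3)
    cohort, _ = generate_cohort(spec)
    return cohort


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def random_rectified(n: int, rng: np.random.Generator, density: float = 0.5):
    """Random rectified connectivity matrix for property tests."""
    from connectoml.datamodel import ConnectivityMatrix

    W = rng.uniform(0, 0.8, size=(n, n))
    W *= rng.random((n, n)) < density
    W = np.triu(W, 1)
    W = W + W.T
    return ConnectivityMatrix(subject_id="rand", W=W, stage="rectified")
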