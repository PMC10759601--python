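"""Core domain types for functional-connectome analysis.

The pipeline models a subject's brain as a weighted graph on a fixed set of
regions of interest (ROIs).  Edge weights are rectified Fisher-z transformed
Pearson correlations between ROI BOLD time series; binary graphs are obtained
by thresholding those weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

Stage = Literal["raw_pcc", "fisher", "rectified"]
Provenance = Literal["original", "augmented"]

DEFAULT_N_ROI = 164


class ConnectomlError(Exception):
    """Base class for domain validation errors."""


class AtlasMismatchError(ConnectomlError):
    """Input columns do not match the ROI atlas."""


class ZeroVarianceError(ConnectomlError):
    """A time-series column is constant, so its correlation is undefined."""


class ShapeError(ConnectomlError):
    """Input array has the wrong shape."""


@dataclass(frozen=True)
class RoiAtlas:
    """Ordered ROI parcellation: (0-based id, name, MNI coordinate in mm)."""

    names: tuple[str, ...]
    mni: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ConnectomlError("atlas ROI names must be unique")
        if len(self.mni) != len(self.names):
            raise ConnectomlError("atlas names and coordinates differ in length")

    @property
    def n_roi(self) -> int:
        return len(self.names)

    @classmethod
    def generic(cls, n_roi: int = DEFAULT_N_ROI) -> "RoiAtlas":
        """Placeholder atlas with synthetic names and zero coordinates."""
        return cls(
            names=tuple(f"roi{i:03d}" for i in range(n_roi)),
            mni=tuple((0.0, 0.0, 0.0) for _ in range(n_roi)),
        )


@dataclass
class RoiTimeSeries:
    """T x N matrix of ROI-averaged BOLD signal (rows = time points)."""

    subject_id: str
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ShapeError("time series must be a 2-D (T x N) array")
        if self.data.shape[0] < 3:
            raise ConnectomlError("need at least 3 time points for a correlation")
        var = self.data.var(axis=0)
        if np.any(var == 0):
            bad = int(np.flatnonzero(var == 0)[0])
            raise ZeroVarianceError(f"ROI column {bad} has zero variance")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_roi(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """N x N symmetric connectivity weights with a processing-stage tag.

    Stages: ``raw_pcc`` (Pearson r, in [-1, 1]), ``fisher`` (artanh r),
    ``rectified`` (negative Fisher weights set to 0).  The diagonal is 0
    at every stage; self-correlation carries no information for the graph.
    """

    subject_id: str
    W: np.ndarray
    stage: Stage = "rectified"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ShapeError(f"connectivity matrix must be square, got {self.W.shape}")
        if np.isnan(self.W).any():
            raise ConnectomlError("connectivity matrix contains NaN")
        if not np.allclose(self.W, self.W.T, atol=1e-8):
            raise ConnectomlError("connectivity matrix must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ConnectomlError("connectivity matrix diagonal must be zero")
        if self.stage == "raw_pcc" and (self.W.min() < -1 - 1e-12 or self.W.max() > 1 + 1e-12):
            raise ConnectomlError("raw Pearson entries must lie in [-1, 1]")
        if self.stage == "rectified" and self.W.min() < 0:
            raise ConnectomlError("rectified weights must be nonnegative")

    @property
    def n_roi(self) -> int:
        return self.W.shape[0]


@dataclass
class BinaryGraph:
    """Unweighted brain graph: 0/1 adjacency at binarization threshold tau."""

    subject_id: str
    A: np.ndarray
    tau: float

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ShapeError("adjacency must be square")
        if not np.array_equal(self.A, self.A.T):
            raise ConnectomlError("adjacency must be symmetric")
        if np.any(np.diag(self.A) != 0):
            raise ConnectomlError("adjacency diagonal must be zero")
        vals = np.unique(self.A)
        if not np.all(np.isin(vals, (0, 1))):
            raise ConnectomlError("adjacency entries must be 0/1")
        self.A = self.A.astype(np.int8)

    @property
    def n_roi(self) -> int:
        return self.A.shape[0]


@dataclass
class Subject:
    """One cohort member: rectified connectivity, diagnosis label, provenance."""

    matrix: ConnectivityMatrix
    label: int
    provenance: Provenance = "original"

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ConnectomlError("label must be 0 (control) or 1 (patient)")


@dataclass
class Cohort:
    """Labelled collection of subjects; label 1 = schizophrenic (positive)."""

    subjects: list[Subject] = field(default_factory=list)

    def __post_init__(self) -> None:
        sizes = {s.matrix.n_roi for s in self.subjects}
        if len(sizes) > 1:
            raise ConnectomlError(f"subjects disagree on ROI count: {sorted(sizes)}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n_roi(self) -> int:
        return self.subjects[0].matrix.n_roi

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects], dtype=int)

    @property
    def matrices(self) -> list[ConnectivityMatrix]:
        return [s.matrix for s in self.subjects]

    def originals(self) -> "Cohort":
        return Cohort([s for s in self.subjects if s.provenance == "original"])

    def counts(self) -> tuple[int, int]:
        """(n_control, n_patient)."""
        y = self.labels
        return int(np.sum(y == 0)), int(np.sum(y == 1))


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed from the master seed.

    Uses CRC32 of the stage name so that stages can be rerun in isolation
    without consuming a shared random stream.
    """
    import zlib

    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)
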