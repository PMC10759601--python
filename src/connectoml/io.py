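"""Readers and writers for the pipeline's tabular formats.

Conventions: N x N subject matrices are header-less CSV (language neutral);
time series and tables are TSV with a header row.  Readers validate against
the type invariants rather than silently coercing.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    AtlasMismatchError,
    Cohort,
    ConnectivityMatrix,
    ConnectomlError,
    RoiAtlas,
    RoiTimeSeries,
    ShapeError,
    Subject,
)

ASYMMETRY_TOL = 1e-8


def read_atlas(path: str | Path) -> RoiAtlas:
    """Read a TSV atlas table with columns: id, name, x, y, z.

    Published ids may be 1-based; rows are re-indexed 0..N-1 in file order.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"id", "name", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ConnectomlError(f"atlas table needs columns {sorted(required)}")
    return RoiAtlas(
        names=tuple(df["name"].astype(str)),
        mni=tuple(zip(df["x"].astype(float), df["y"].astype(float), df["z"].astype(float))),
    )


def write_atlas(atlas: RoiAtlas, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": range(atlas.n_roi),
            "name": atlas.names,
            "x": [c[0] for c in atlas.mni],
            "y": [c[1] for c in atlas.mni],
            "z": [c[2] for c in atlas.mni],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_timeseries(path: str | Path, atlas: RoiAtlas | None = None,
                    subject_id: str | None = None) -> RoiTimeSeries:
    """Read a T x N TSV of ROI time series with a header of ROI names.

    When an atlas is given the column set must equal the atlas names and is
    reordered to atlas order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if atlas is not None:
        if set(df.columns) != set(atlas.names):
            raise AtlasMismatchError(
                f"time-series columns do not match atlas ROI names in {path.name}"
            )
        df = df[list(atlas.names)]
    return RoiTimeSeries(subject_id=subject_id or path.stem, data=df.to_numpy(dtype=float))


def write_timeseries(ts: RoiTimeSeries, path: str | Path, atlas: RoiAtlas | None = None) -> None:
    names = atlas.names if atlas is not None else [f"roi{i:03d}" for i in range(ts.n_roi)]
    pd.DataFrame(ts.data, columns=list(names)).to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path, stage: str = "rectified",
                subject_id: str | None = None) -> ConnectivityMatrix:
    """Read a header-less N x N CSV connectivity matrix.

    Near-symmetric input (asymmetry above 1e-8) is symmetrized by averaging
    with a warning; NaN or non-square input is rejected.
    """
    path = Path(path)
    W = np.loadtxt(path, delimiter=",", ndmin=2)
    if W.shape[0] != W.shape[1]:
        raise ShapeError(f"matrix in {path.name} is {W.shape}, expected square")
    if np.isnan(W).any():
        raise ConnectomlError(f"matrix in {path.name} contains NaN")
    asym = np.abs(W - W.T).max()
    if asym > ASYMMETRY_TOL:
        warnings.warn(
            f"matrix in {path.name} asymmetric by {asym:.3g}; symmetrizing (W + W.T)/2",
            stacklevel=2,
        )
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return ConnectivityMatrix(subject_id=subject_id or path.stem, W=W, stage=stage)


def write_matrix(m: ConnectivityMatrix, path: str | Path) -> None:
    np.savetxt(path, m.W, delimiter=",", fmt="%.17g")


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"subject_id", "label"}.issubset(df.columns):
        raise ConnectomlError("label table needs columns subject_id, label")
    if not df["label"].isin([0, 1]).all():
        raise ConnectomlError("labels must be 0 or 1")
    return df


def write_labels(cohort: Cohort, path: str | Path) -> None:
    pd.DataFrame(
        {
            "subject_id": [s.matrix.subject_id for s in cohort],
            "label": [s.label for s in cohort],
            "provenance": [s.provenance for s in cohort],
        }
    ).to_csv(path, sep="\t", index=False)


def read_cohort(matrix_dir: str | Path, labels_path: str | Path,
                stage: str = "rectified") -> Cohort:
    """Load a cohort from per-subject matrix CSVs plus a label table.

    Matrix files are expected at ``<matrix_dir>/<subject_id>.csv``.
    """
    matrix_dir = Path(matrix_dir)
    labels = read_labels(labels_path)
    subjects = []
    for row in labels.itertuples(index=False):
        m = read_matrix(matrix_dir / f"{row.subject_id}.csv", stage=stage,
                        subject_id=str(row.subject_id))
        prov = getattr(row, "provenance", "original")
        subjects.append(Subject(matrix=m, label=int(row.label), provenance=prov))
    return Cohort(subjects)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in cohort:
        write_matrix(s.matrix, out_dir / f"{s.matrix.subject_id}.csv")
    write_labels(cohort, out_dir / "labels.tsv")
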