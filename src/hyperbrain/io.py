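"""Cohort I/O and time-series preparation.

Input to the package is already-extracted regional mean BOLD time series
(one T x R table per subject, timepoints by regions), plus a cohort manifest
assigning each subject to a group.  Voxel-level preprocessing (realignment,
normalisation, band-pass filtering, atlas application) is upstream and out
of scope.

Interchange format is TSV: subject tables carry a header row of ROI labels
and one row per timepoint; the manifest has columns ``subject_id``,
``group``, ``timeseries_path`` and optionally ``nuisance_path``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ROITimeSeries",
    "CohortDataset",
    "NuisanceRegressors",
    "read_cohort",
    "write_cohort",
    "residualize_nuisance",
    "standardize_columns",
]

GROUPS = ("control", "patient")


@dataclass
class ROITimeSeries:
    """Regional mean time series for one subject (T timepoints x R regions)."""

    subject_id: str
    data: np.ndarray
    roi_labels: list[str]
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D, got shape {self.data.shape}")
        t, r = self.data.shape
        if t < 2 or r < 2:
            raise ValueError(f"need T >= 2 and R >= 2, got T={t}, R={r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id!r}: non-finite values in time series")
        if len(self.roi_labels) != r:
            raise ValueError(
                f"subject {self.subject_id!r}: {len(self.roi_labels)} labels for {r} regions"
            )
        if len(set(self.roi_labels)) != r:
            raise ValueError(f"subject {self.subject_id!r}: ROI labels not unique")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class NuisanceRegressors:
    """Per-subject nuisance design (e.g. CSF mean, WM mean, 6 motion parameters)."""

    data: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.shape[1] != len(self.names):
            raise ValueError("number of names must match number of regressor columns")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in nuisance regressors")


@dataclass
class CohortDataset:
    """Multi-subject cohort: aligned ROI time series plus group labels."""

    subjects: list[ROITimeSeries]
    labels: list[str]
    nuisance: list[NuisanceRegressors | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.subjects):
            raise ValueError("labels length must equal subjects length")
        if not self.nuisance:
            self.nuisance = [None] * len(self.subjects)
        for lab in self.labels:
            if lab not in GROUPS:
                raise ValueError(f"unknown group label {lab!r}; expected one of {GROUPS}")
        if self.subjects:
            ref = self.subjects[0].roi_labels
            for s in self.subjects[1:]:
                if s.roi_labels != ref:
                    raise ValueError(
                        f"subject {s.subject_id!r} has inconsistent ROI labels/columns"
                    )

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_rois(self) -> int:
        return self.subjects[0].n_rois

    @property
    def roi_labels(self) -> list[str]:
        return self.subjects[0].roi_labels

    def group_indices(self, group: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels) == group)


def _read_table(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"referenced file does not exist: {path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")

    def _not_a_number(v) -> bool:
        try:
            float(v)
            return False
        except (TypeError, ValueError):
            return True

    bad = df.map(_not_a_number).to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric cell in {path} at row {i + 1}, column {df.columns[j]!r}"
        )
    return df


def read_cohort(manifest_path: str | Path) -> CohortDataset:
    """Read a cohort from a TSV manifest.

    The manifest must have columns ``subject_id``, ``group``,
    ``timeseries_path`` (paths resolved relative to the manifest's
    directory) and may have ``nuisance_path``.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest does not exist: {manifest_path}")
    man = pd.read_csv(manifest_path, sep="\t", dtype=str)
    required = {"subject_id", "group", "timeseries_path"}
    if not required.issubset(man.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    base = manifest_path.parent
    subjects: list[ROITimeSeries] = []
    labels: list[str] = []
    nuisance: list[NuisanceRegressors | None] = []
    for _, row in man.iterrows():
        ts_path = base / row["timeseries_path"]
        df = _read_table(ts_path)
        subjects.append(
            ROITimeSeries(
                subject_id=str(row["subject_id"]),
                data=df.to_numpy(dtype=float),
                roi_labels=[str(c) for c in df.columns],
            )
        )
        labels.append(str(row["group"]))
        if "nuisance_path" in man.columns and isinstance(row.get("nuisance_path"), str):
            ndf = _read_table(base / row["nuisance_path"])
            nuisance.append(
                NuisanceRegressors(ndf.to_numpy(dtype=float), [str(c) for c in ndf.columns])
            )
        else:
            nuisance.append(None)
    return CohortDataset(subjects=subjects, labels=labels, nuisance=nuisance)


def write_cohort(cohort: CohortDataset, out_dir: str | Path) -> Path:
    """Write one TSV per subject plus a manifest; returns the manifest path.

    Values are written at 17 significant digits so that
    ``read_cohort(write_cohort(x))`` reproduces ``x`` bit-compatibly.
    """
    if len(cohort) == 0:
        raise ValueError("refusing to write an empty cohort")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (ts, lab) in enumerate(zip(cohort.subjects, cohort.labels)):
        fname = f"{ts.subject_id}.tsv"
        df = pd.DataFrame(ts.data, columns=ts.roi_labels)
        df.to_csv(out_dir / fname, sep="\t", index=False, float_format="%.17g")
        row = {"subject_id": ts.subject_id, "group": lab, "timeseries_path": fname}
        nuis = cohort.nuisance[i]
        if nuis is not None:
            nname = f"{ts.subject_id}_nuisance.tsv"
            pd.DataFrame(nuis.data, columns=nuis.names).to_csv(
                out_dir / nname, sep="\t", index=False, float_format="%.17g"
            )
            row["nuisance_path"] = nname
        rows.append(row)
    manifest_path = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def _name_collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    # incremental rank check: a column that does not raise the rank is dependent
    dependent = []
    rank = 0
    kept = np.empty((design.shape[0], 0))
    for j in range(design.shape[1]):
        cand = np.hstack([kept, design[:, j : j + 1]])
        r = np.linalg.matrix_rank(cand)
        if r == rank:
            dependent.append(names[j])
        else:
            kept, rank = cand, r
    return dependent


def residualize_nuisance(ts: ROITimeSeries, nuis: NuisanceRegressors) -> ROITimeSeries:
    """Replace each ROI column by its OLS residual against [intercept | nuisance].

    The returned residuals are orthogonal to every nuisance column and have
    zero mean.  The residuals — not the raw series — are what the sparse
    regressions are fitted to.
    """
    if nuis.data.shape[0] != ts.n_timepoints:
        raise ValueError(
            f"nuisance rows ({nuis.data.shape[0]}) != timepoints ({ts.n_timepoints})"
        )
    design = np.column_stack([np.ones(ts.n_timepoints), nuis.data])
    names = ["intercept"] + list(nuis.names)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _name_collinear_columns(design, names)
        raise np.linalg.LinAlgError(
            f"nuisance design is rank deficient; collinear columns: {bad}"
        )
    coef, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    resid = ts.data - design @ coef
    return ROITimeSeries(ts.subject_id, resid, list(ts.roi_labels), ts.tr_seconds)


def standardize_columns(ts: ROITimeSeries) -> ROITimeSeries:
    """Z-score every ROI column (mean 0, unit sample sd with n-1 denominator)."""
    sd = ts.data.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        bad = [ts.roi_labels[j] for j in zero]
        raise ValueError(f"zero-variance ROI column(s): {bad}")
    z = (ts.data - ts.data.mean(axis=0)) / sd
    return ROITimeSeries(ts.subject_id, z, list(ts.roi_labels), ts.tr_seconds)
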