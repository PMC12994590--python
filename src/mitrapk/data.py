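"""Concentration-time dataset handling.

Observed data are study-mean concentrations: each record carries a time (h),
the mean concentration across subjects (ng/mL), the standard deviation of
that mean (ng/mL), and the analyte label (``parent`` for mitragynine,
``metabolite`` for 7-hydroxymitragynine).  The canonical interchange format
is a CSV with columns ``time_h, mean_ng_ml, sd_ng_ml, analyte``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ANALYTES",
    "COLUMNS",
    "DEFAULT_EXCLUSIONS",
    "ConcentrationDataset",
    "DatasetError",
    "load_dataset",
    "dataset_from_frame",
    "exclude_outliers",
    "compute_cv",
]

ANALYTES = ("parent", "metabolite")
COLUMNS = ("time_h", "mean_ng_ml", "sd_ng_ml", "analyte")

#: Exclusion rule applied by default: the metabolite observation at 35 h,
#: an outlier identified by visual inspection in the source study.
DEFAULT_EXCLUSIONS = (("metabolite", 35.0),)


class DatasetError(ValueError):
    """Raised for malformed concentration tables."""


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing column(s): {missing}")
    df = df.loc[:, list(COLUMNS)].copy()
    for col in ("time_h", "mean_ng_ml", "sd_ng_ml"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise DatasetError(
                f"unparseable number in column {col!r} at row(s) {list(bad)}"
            )
        df[col] = vals.astype(float)
    unknown = sorted(set(df["analyte"]) - set(ANALYTES))
    if unknown:
        raise DatasetError(f"unknown analyte label(s): {unknown}")
    if (df["time_h"] < 0).any():
        raise DatasetError("negative time")
    if (df["sd_ng_ml"] < 0).any():
        raise DatasetError("negative sd_ng_ml")
    dup = df.duplicated(subset=["analyte", "time_h"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["analyte", "time_h"]].drop_duplicates()
        raise DatasetError(
            "duplicate (analyte, time) pair(s): "
            + ", ".join(f"({a}, {t} h)" for a, t in pairs.itertuples(index=False))
        )
    return df.sort_values(["analyte", "time_h"], ignore_index=True)


@dataclass
class ConcentrationDataset:
    """Validated, sorted concentration records plus an exclusion audit trail.

    ``records`` is a DataFrame with the canonical columns, sorted by
    (analyte, time); ``exclusions`` holds removed records with a ``reason``
    column.
    """

    records: pd.DataFrame
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(COLUMNS) + ["reason"])
    )

    def __len__(self) -> int:
        return len(self.records)

    def analyte(self, name: str) -> pd.DataFrame:
        if name not in ANALYTES:
            raise KeyError(f"unknown analyte {name!r}")
        return self.records[self.records["analyte"] == name].reset_index(drop=True)

    def fittable(self) -> pd.DataFrame:
        """Records usable on the log-concentration scale (mean > 0)."""
        return self.records[self.records["mean_ng_ml"] > 0].reset_index(drop=True)

    def copy(self) -> "ConcentrationDataset":
        return ConcentrationDataset(self.records.copy(), self.exclusions.copy())

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def dataset_from_frame(df: pd.DataFrame) -> ConcentrationDataset:
    """Build a validated dataset from an in-memory table."""
    records = _validate_frame(df)
    nonpos = records["mean_ng_ml"] <= 0
    if nonpos.any():
        times = records.loc[nonpos, "time_h"].tolist()
        warnings.warn(
            f"{int(nonpos.sum())} record(s) with mean <= 0 (times {times}); "
            "they are retained but excluded from log-scale fitting",
            stacklevel=2,
        )
    return ConcentrationDataset(records)


def load_dataset(path) -> ConcentrationDataset:
    """Read a concentration-time CSV/TSV and validate it.

    Raises :class:`DatasetError` naming the offending row for missing
    columns, unparseable numbers, or duplicate (analyte, time) pairs.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    return dataset_from_frame(df)


def exclude_outliers(
    ds: ConcentrationDataset,
    rules=DEFAULT_EXCLUSIONS,
) -> ConcentrationDataset:
    """Move records matching (analyte, time) rules to the exclusion list.

    Idempotent; a rule with no matching record is a no-op with a warning.
    """
    records = ds.records.copy()
    excluded = [ds.exclusions]
    for analyte, time in rules:
        mask = (records["analyte"] == analyte) & np.isclose(records["time_h"], time)
        if not mask.any():
            warnings.warn(
                f"exclusion rule ({analyte}, {time} h) matched no record",
                stacklevel=2,
            )
            continue
        hit = records.loc[mask].copy()
        hit["reason"] = f"excluded by rule ({analyte}, {time} h): outlier"
        excluded.append(hit)
        records = records.loc[~mask]
    exclusions = pd.concat([e for e in excluded if len(e)], ignore_index=True) if any(
        len(e) for e in excluded
    ) else ds.exclusions.copy()
    return ConcentrationDataset(records.reset_index(drop=True), exclusions)


def compute_cv(ds: ConcentrationDataset, cv_floor: float = 0.05) -> pd.Series:
    """Per-record coefficient of variation, floored from below.

    CV_i = max(sd_i / mean_i, cv_floor); the floor (default 0.05) keeps
    near-zero reported SDs from producing unbounded fitting weights.
    Requires every record to have mean > 0.
    """
    if cv_floor <= 0:
        raise ValueError("cv_floor must be > 0")
    mean = ds.records["mean_ng_ml"]
    if (mean <= 0).any():
        times = ds.records.loc[mean <= 0, "time_h"].tolist()
        raise DatasetError(
            f"CV undefined for mean <= 0 at time(s) {times}; exclude these records first"
        )
    cv = (ds.records["sd_ng_ml"] / mean).clip(lower=cv_floor)
    cv.name = "cv"
    return cv
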