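"""Measurement-cleaning rules applied to raw longitudinal height records.

The pipeline order is fixed: treatment-window filter (0..54 months, and
subjects must keep at least two measurements), HSDS plausibility range
(strictly inside (-7, 2)), sequential height-decrease rule (a measurement
at least 2 cm below the running maximum of earlier retained heights is an
error, since measurement error is only ~0.3 cm), and finally residual
outliers against a broken-stick fit (|residual| >= 0.5 SDS, inclusive),
followed by a single refit.

All thresholds are configurable; the defaults implement the published
protocol.  A :class:`CleaningReport` records every removal with its reason
so counts are conserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import brokenstick
from .reference import GrowthReference, hsds_from_height

__all__ = [
    "CleaningConfig",
    "CleaningReport",
    "ensure_hsds",
    "filter_treatment_window",
    "filter_hsds_range",
    "flag_height_decreases",
    "remove_brokenstick_outliers",
    "clean_records",
]

RECORD_COLUMNS = ("subject_id", "months_on_treatment")


@dataclass(frozen=True)
class CleaningConfig:
    max_months: float = 54.0
    hsds_low: float = -7.0
    hsds_high: float = 2.0
    decrease_cm: float = 2.0
    outlier_bound: float = 0.5
    min_records: int = 2


@dataclass
class CleaningReport:
    """Audit trail of the cleaning pipeline."""

    n_input: int = 0
    n_removed_window: int = 0
    n_removed_short: int = 0      # subjects left with < min_records
    n_removed_range: int = 0
    n_removed_decrease: int = 0
    n_removed_outlier: int = 0
    removed: list = field(default_factory=list)  # (subject_id, record_id, reason)

    @property
    def n_removed(self) -> int:
        return (self.n_removed_window + self.n_removed_short + self.n_removed_range
                + self.n_removed_decrease + self.n_removed_outlier)

    def log(self, rows: pd.DataFrame, reason: str):
        counter = {
            "window": "n_removed_window", "short": "n_removed_short",
            "range": "n_removed_range", "decrease": "n_removed_decrease",
            "outlier": "n_removed_outlier",
        }[reason]
        setattr(self, counter, getattr(self, counter) + len(rows))
        for _, r in rows.iterrows():
            self.removed.append((r["subject_id"], r.get("record_id", None), reason))

    def to_json(self, path=None) -> str:
        payload = {
            "n_input": self.n_input,
            "n_removed_window": self.n_removed_window,
            "n_removed_short": self.n_removed_short,
            "n_removed_range": self.n_removed_range,
            "n_removed_decrease": self.n_removed_decrease,
            "n_removed_outlier": self.n_removed_outlier,
            "removed": [
                {"subject_id": str(s), "record_id": None if i is None else int(i),
                 "reason": why}
                for (s, i, why) in self.removed
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _check(records: pd.DataFrame):
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns: {missing}")
    if "height_cm" not in records.columns and "hsds" not in records.columns:
        raise ValueError("records need at least one of height_cm / hsds")


def ensure_hsds(records: pd.DataFrame, ref: GrowthReference) -> pd.DataFrame:
    """Fill missing ``hsds`` from ``height_cm`` via the reference (and the
    ``sex`` and ``age_years`` columns)."""
    _check(records)
    out = records.copy()
    if "hsds" not in out.columns:
        out["hsds"] = np.nan
    need = out["hsds"].isna()
    if need.any():
        sub = out.loc[need]
        z = [
            hsds_from_height(h, a, s, ref)
            for h, a, s in zip(sub["height_cm"], sub["age_years"], sub["sex"])
        ]
        out.loc[need, "hsds"] = z
    return out


def _drop_short_subjects(records: pd.DataFrame, min_records: int,
                         report: CleaningReport | None) -> pd.DataFrame:
    counts = records.groupby("subject_id")["months_on_treatment"].transform("size")
    bad = counts < min_records
    if report is not None and bad.any():
        report.log(records.loc[bad], "short")
    return records.loc[~bad]


def filter_treatment_window(records: pd.DataFrame, max_months: float = 54.0,
                            min_records: int = 2,
                            report: CleaningReport | None = None) -> pd.DataFrame:
    """Keep measurements with 0 <= months_on_treatment <= max_months and
    drop subjects left with fewer than ``min_records`` measurements."""
    _check(records)
    if max_months <= 0:
        raise ValueError("max_months must be positive")
    m = records["months_on_treatment"].to_numpy(dtype=float)
    keep = (m >= 0) & (m <= max_months)
    if report is not None and (~keep).any():
        report.log(records.loc[~keep], "window")
    return _drop_short_subjects(records.loc[keep], min_records, report)


def filter_hsds_range(records: pd.DataFrame, low: float = -7.0, high: float = 2.0,
                      report: CleaningReport | None = None) -> pd.DataFrame:
    """Keep records with low < hsds < high (strict on both sides)."""
    if low >= high:
        raise ValueError("low must be below high")
    if "hsds" not in records.columns:
        raise ValueError("hsds column required (convert heights first)")
    z = records["hsds"].to_numpy(dtype=float)
    keep = (z > low) & (z < high)
    if report is not None and (~keep).any():
        report.log(records.loc[~keep], "range")
    return records.loc[keep]


def flag_height_decreases(records: pd.DataFrame, threshold: float = 2.0,
                          report: CleaningReport | None = None) -> pd.DataFrame:
    """Drop measurements >= ``threshold`` cm below the running maximum.

    Children on growth-hormone therapy do not shrink; a decrease beyond
    measurement error marks a recording mistake.  Records are scanned in
    time order per subject and compared against the running maximum of the
    *retained* earlier heights, so the first record is never removed and the
    rule is idempotent.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if "height_cm" not in records.columns or records["height_cm"].isna().any():
        raise ValueError("height_cm required for the decrease rule "
                         "(convert from hsds via the reference first)")
    drop_idx = []
    for _, sub in records.groupby("subject_id", sort=False):
        sub = sub.sort_values("months_on_treatment", kind="stable")
        run_max = -np.inf
        for idx, h in zip(sub.index, sub["height_cm"].to_numpy(dtype=float)):
            if run_max - h >= threshold:
                drop_idx.append(idx)
            else:
                run_max = max(run_max, h)
    if report is not None and drop_idx:
        report.log(records.loc[drop_idx], "decrease")
    return records.drop(index=drop_idx)


def remove_brokenstick_outliers(records: pd.DataFrame,
                                model: "brokenstick.BrokenStickModel",
                                bound: float = 0.5,
                                report: CleaningReport | None = None) -> pd.DataFrame:
    """Drop records whose broken-stick residual satisfies |r| >= bound.

    The bound is inclusive on both sides.  ``model`` must have been fitted
    on these records (residuals are observed minus the subject's fitted
    value at the observation time).
    """
    resid = brokenstick.residuals(model, records)
    keep = resid.abs() < bound
    if report is not None and (~keep).any():
        report.log(records.loc[~keep], "outlier")
    return records.loc[keep]


def clean_records(records: pd.DataFrame, ref: GrowthReference | None = None,
                  config: CleaningConfig | None = None,
                  grid: "brokenstick.KnotGrid | None" = None,
                  fit_config: "brokenstick.FitConfig | None" = None):
    """Full cleaning pipeline; returns (clean records, final model, report).

    Applies, in order: treatment window, HSDS range, height-decrease rule,
    broken-stick residual outliers (with exactly one refit afterwards).
    ``ref`` is only needed when records lack an ``hsds`` column.
    """
    config = config or CleaningConfig()
    report = CleaningReport(n_input=len(records))
    out = records.copy()
    if "record_id" not in out.columns:
        out["record_id"] = np.arange(len(out))
    if ref is not None:
        out = ensure_hsds(out, ref)

    out = filter_treatment_window(out, config.max_months, config.min_records, report)
    out = filter_hsds_range(out, config.hsds_low, config.hsds_high, report)
    out = _drop_short_subjects(out, config.min_records, report)
    if "height_cm" in out.columns and not out["height_cm"].isna().any():
        out = flag_height_decreases(out, config.decrease_cm, report)
        out = _drop_short_subjects(out, config.min_records, report)

    model = brokenstick.fit(out, grid=grid, config=fit_config)
    out = remove_brokenstick_outliers(out, model, config.outlier_bound, report)
    out = _drop_short_subjects(out, config.min_records, report)
    model = brokenstick.fit(out, grid=grid, config=fit_config)  # single refit
    return out, model, report
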