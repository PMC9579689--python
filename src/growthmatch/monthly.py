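"""Monthly HSDS grids: interpolate knot estimates and align raw visits.

The matching machinery works on HSDS at integer months 0..48 on treatment.
Database curves come from linear interpolation of the 3-monthly broken-stick
knot estimates; a new patient's visit history is aligned to the grid by
rounding each observation's treatment time to the nearest month (half away
from zero) and averaging collisions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MONTHS", "MonthlyCurve", "VisitVector", "interpolate_monthly",
           "to_visit_vector", "round_months"]

MONTHS = np.arange(0, 49)


@dataclass
class MonthlyCurve:
    """A subject's HSDS at integer months 0..48 on treatment."""

    subject_id: object
    values: np.ndarray                 # length 49
    provenance: str = "broken_stick"   # or "observed"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(MONTHS),):
            raise ValueError(f"monthly curve must have {len(MONTHS)} values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("monthly curve contains non-finite values")


@dataclass
class VisitVector:
    """Observed HSDS of one subject at distinct rounded months <= 48."""

    months: np.ndarray
    values: np.ndarray
    subject_id: object = None

    def __post_init__(self):
        self.months = np.asarray(self.months, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.months.shape != self.values.shape:
            raise ValueError("months and values must have equal length")
        if len(self.months) and (
            np.any(np.diff(self.months) <= 0)
            or self.months[0] < 0 or self.months[-1] > 48
        ):
            raise ValueError("months must be strictly increasing within 0..48")

    def __len__(self):
        return len(self.months)

    def up_to(self, month: int) -> "VisitVector":
        keep = self.months <= month
        return VisitVector(self.months[keep], self.values[keep], self.subject_id)


def interpolate_monthly(estimates) -> MonthlyCurve:
    """Linear interpolation of 3-monthly knot estimates to months 0..48."""
    knots = np.asarray(estimates.knots, dtype=float)
    values = np.asarray(estimates.values, dtype=float)
    if knots[0] != 0 or knots[-1] < MONTHS[-1]:
        raise ValueError("knot estimates must span months 0..48")
    if not np.all(np.isfinite(values)):
        raise ValueError("missing knot estimate")
    return MonthlyCurve(
        subject_id=getattr(estimates, "subject_id", None),
        values=np.interp(MONTHS, knots, values),
        provenance="broken_stick",
    )


def round_months(months) -> np.ndarray:
    """Round decimal months to the nearest integer, halves away from zero."""
    m = np.asarray(months, dtype=float)
    return np.floor(m + 0.5).astype(int)


def to_visit_vector(records: pd.DataFrame, up_to_month: int = 48,
                    subject_id=None) -> VisitVector:
    """Collapse one subject's records to HSDS at rounded integer months.

    Duplicate rounded months are averaged; only months <= ``up_to_month``
    (and <= 48) are retained.  An empty result is returned, not raised, when
    no record falls in range.
    """
    if subject_id is None and "subject_id" in records.columns and len(records):
        subject_id = records["subject_id"].iloc[0]
    m = round_months(records["months_on_treatment"].to_numpy(dtype=float))
    y = records["hsds"].to_numpy(dtype=float)
    keep = (m >= 0) & (m <= min(up_to_month, 48))
    m, y = m[keep], y[keep]
    if len(m) == 0:
        return VisitVector(np.array([], dtype=int), np.array([]), subject_id)
    agg = pd.Series(y).groupby(m).mean()
    return VisitVector(agg.index.to_numpy(), agg.to_numpy(), subject_id)
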