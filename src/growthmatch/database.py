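"""The Matching Database: curated complete monthly HSDS trajectories.

Curves enter the database only when (1) HSDS at treatment start lies in
[-4, -1) SDS, (2) every treatment year 0-12, 12-24, 24-36, 36-48 shows a
strictly positive HSDS increase, and (3) age at treatment start lies in
[3, 16) years.  Growth-hormone deficiency (GHD) and small-for-gestational-
age (SGA) patients are pooled; an indication filter is available for
subgroup databases.

Each curve carries a *weighing score*: the number of database curves whose
full 0-48-month trajectory lies within residual SD < 0.03 of it, plus one
for the curve itself, divided by the database size.  Common trajectories
thus weigh more in downstream weighted-mean predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .monthly import MONTHS, MonthlyCurve

__all__ = [
    "SelectionCriteria",
    "MatchingDatabase",
    "apply_selection",
    "curve_distance",
    "compute_weighing_scores",
    "GOOD_MATCH_THRESHOLD",
]

GOOD_MATCH_THRESHOLD = 0.03  # SDS; "good match" cut-off for weighing scores

META_COLUMNS = ("sex", "indication", "age_at_start")


@dataclass(frozen=True)
class SelectionCriteria:
    """Inclusion rules for the Matching Database.

    ``baseline_hsds_range`` is inclusive at the lower and exclusive at the
    upper bound; likewise ``age_at_start_range``.
    """

    baseline_hsds_range: tuple = (-4.0, -1.0)
    require_yearly_increase: bool = True
    age_at_start_range: tuple = (3.0, 16.0)

    def __post_init__(self):
        if (self.baseline_hsds_range[0] >= self.baseline_hsds_range[1]
                or self.age_at_start_range[0] >= self.age_at_start_range[1]):
            raise ValueError("criteria ranges must be non-empty")


def curve_distance(a, b) -> float:
    """Residual standard error between two HSDS vectors on shared months.

    sqrt(sum((a-b)^2) / (n-1)) for n >= 3 shared points, with divisor n
    instead when fewer than 3 points are shared (which also keeps a single
    shared point well defined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors over the same months")
    n = a.size
    if n < 1:
        raise ValueError("need at least one shared month")
    denom = n - 1 if n >= 3 else n
    return float(np.sqrt(np.sum((a - b) ** 2) / denom))


def _distance_denominator(n: int) -> int:
    return n - 1 if n >= 3 else n


def apply_selection(curves: pd.DataFrame, metadata: pd.DataFrame,
                    criteria: SelectionCriteria | None = None) -> pd.Index:
    """Return the subject ids (index entries) passing the selection rules.

    ``curves`` is the wide monthly matrix (rows = subjects, 49 columns for
    months 0..48); ``metadata`` must carry ``age_at_start`` per subject.
    """
    criteria = criteria or SelectionCriteria()
    if curves.shape[1] != len(MONTHS):
        raise ValueError(f"curves must have {len(MONTHS)} monthly columns")
    missing = curves.index.difference(metadata.index)
    if len(missing):
        raise ValueError(f"metadata missing for subjects: {list(missing[:5])}")

    vals = curves.to_numpy(dtype=float)
    lo, hi = criteria.baseline_hsds_range
    ok = (vals[:, 0] >= lo) & (vals[:, 0] < hi)
    if criteria.require_yearly_increase:
        for k in range(4):
            ok &= (vals[:, 12 * (k + 1)] - vals[:, 12 * k]) > 0
    age = metadata.loc[curves.index, "age_at_start"].to_numpy(dtype=float)
    alo, ahi = criteria.age_at_start_range
    ok &= (age >= alo) & (age < ahi)
    return curves.index[ok]


def compute_weighing_scores(curves: pd.DataFrame,
                            good_threshold: float = GOOD_MATCH_THRESHOLD) -> pd.Series:
    """Weighing score per curve: (good matches + 1 for itself) / N.

    A pair is a good match when the full-curve residual SD is strictly
    below ``good_threshold``.  Computed with the Gram-matrix identity
    ||a-b||^2 = ||a||^2 + ||b||^2 - 2 a.b, so it scales to thousands of
    curves without materialising an N x N x 49 array.
    """
    X = curves.to_numpy(dtype=float)
    n_pts = X.shape[1]
    denom = _distance_denominator(n_pts)
    sq = np.einsum("ij,ij->i", X, X)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    good = d2 / denom < good_threshold**2
    np.fill_diagonal(good, False)
    counts = good.sum(axis=1)
    return pd.Series((counts + 1) / len(X), index=curves.index, name="weight")


@dataclass
class MatchingDatabase:
    """Complete monthly curves, per-subject metadata and weighing scores."""

    curves: pd.DataFrame     # wide: index subject_id, columns month_0..month_48
    meta: pd.DataFrame       # index subject_id; sex, indication, age_at_start
    weights: pd.Series       # index subject_id, values in (0, 1]
    criteria: SelectionCriteria = SelectionCriteria()
    good_threshold: float = GOOD_MATCH_THRESHOLD

    def __post_init__(self):
        if not self.curves.index.equals(self.weights.index):
            raise ValueError("curves and weights must share the same subjects")
        if self.curves.shape[1] != len(MONTHS):
            raise ValueError(f"curves must have {len(MONTHS)} monthly columns")
        w = self.weights.to_numpy(dtype=float)
        if np.any(w <= 0) or np.any(w > 1):
            raise ValueError("weights must lie in (0, 1]")

    def __len__(self):
        return len(self.curves)

    @property
    def subject_ids(self) -> pd.Index:
        return self.curves.index

    @classmethod
    def build(cls, monthly_curves: list[MonthlyCurve] | pd.DataFrame,
              metadata: pd.DataFrame,
              criteria: SelectionCriteria | None = None,
              good_threshold: float = GOOD_MATCH_THRESHOLD,
              indication: str | None = None) -> "MatchingDatabase":
        """Apply selection to candidate curves and compute weighing scores.

        ``indication`` optionally restricts the database to "GHD" or "SGA"
        (the default pools both).
        """
        criteria = criteria or SelectionCriteria()
        if isinstance(monthly_curves, pd.DataFrame):
            wide = monthly_curves.copy()
        else:
            wide = pd.DataFrame(
                {c.subject_id: c.values for c in monthly_curves}
            ).T
        wide.columns = [f"month_{m}" for m in MONTHS]
        meta = metadata.loc[wide.index]
        if indication is not None:
            keep = meta["indication"] == indication
            wide, meta = wide.loc[keep], meta.loc[keep]
        selected = apply_selection(wide, meta, criteria)
        wide = wide.loc[selected]
        if len(wide) == 0:
            raise ValueError("no curves pass the selection criteria")
        weights = compute_weighing_scores(wide, good_threshold)
        return cls(curves=wide, meta=meta.loc[selected], weights=weights,
                   criteria=criteria, good_threshold=good_threshold)

    # -- persistence ---------------------------------------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.curves.rename_axis("subject_id").to_csv(d / "curves.csv")
        self.meta.rename_axis("subject_id").to_csv(d / "meta.csv")
        self.weights.rename_axis("subject_id").to_csv(d / "weights.csv")
        manifest = {
            "n_curves": len(self),
            "good_threshold": self.good_threshold,
            "criteria": {
                "baseline_hsds_range": list(self.criteria.baseline_hsds_range),
                "require_yearly_increase": self.criteria.require_yearly_increase,
                "age_at_start_range": list(self.criteria.age_at_start_range),
            },
            "format_version": 1,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory) -> "MatchingDatabase":
        d = Path(directory)
        curves = pd.read_csv(d / "curves.csv", index_col="subject_id")
        meta = pd.read_csv(d / "meta.csv", index_col="subject_id")
        weights = pd.read_csv(d / "weights.csv", index_col="subject_id")["weight"]
        manifest = json.loads((d / "manifest.json").read_text())
        crit = manifest["criteria"]
        return cls(
            curves=curves, meta=meta, weights=weights,
            criteria=SelectionCriteria(
                tuple(crit["baseline_hsds_range"]),
                crit["require_yearly_increase"],
                tuple(crit["age_at_start_range"]),
            ),
            good_threshold=manifest["good_threshold"],
        )
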