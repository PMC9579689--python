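"""Curve matching: nearest-trajectory search and weighted-mean prediction.

A new patient's visit vector (observed HSDS at rounded months up to the
current visit) is compared with every database curve restricted to the
same months, using the residual standard error as the distance.  The 25
closest curves are retained (the patient's own curve is excluded first if
present) and the future trajectory is predicted as the weighing-score-
weighted mean of the matched curves after the visit; the weighted SD over
the matched curves quantifies how predictable the patient is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .database import MatchingDatabase, _distance_denominator
from .monthly import MONTHS, VisitVector
from .reference import GrowthReference, height_from_hsds

__all__ = ["MatchResult", "PredictionResult", "find_matches",
           "predict_from_matches", "predict_height_curve", "match_and_predict"]

DEFAULT_K = 25


class NoCandidatesError(ValueError):
    """Raised when the database is empty after self-exclusion."""


@dataclass
class MatchResult:
    """The k closest database curves, in ascending distance order."""

    matched_ids: list
    distances: np.ndarray
    weights: np.ndarray
    n_visit_months: int = 0

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(np.diff(self.distances) < -1e-12):
            raise ValueError("distances must be non-decreasing")

    def __len__(self):
        return len(self.matched_ids)


@dataclass
class PredictionResult:
    """Weighted-mean predicted HSDS per month after the matching visit."""

    months: np.ndarray
    predicted: np.ndarray
    spread: np.ndarray            # weighted SD across matched curves
    quantiles: pd.DataFrame = field(default=None, repr=False)  # q10/q25/q50/q75/q90
    matched: MatchResult = None
    after_month: int = 0


def find_matches(visit: VisitVector, db: MatchingDatabase, k: int = DEFAULT_K,
                 exclude_id=None) -> MatchResult:
    """Select the ``k`` database curves closest to the visit vector.

    Distance is the residual standard error over the visit's months; ties
    are broken by ascending subject id so matching is deterministic.  When
    fewer than ``k`` candidates exist all are returned with a warning.
    """
    if len(visit) == 0:
        raise ValueError("visit vector is empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    cols = [f"month_{m}" for m in visit.months]
    X = db.curves[cols].to_numpy(dtype=float)
    ids = db.curves.index.to_numpy()
    if exclude_id is not None:
        keep = ids != exclude_id
        X, ids = X[keep], ids[keep]
    if len(ids) == 0:
        raise NoCandidatesError("matching database empty after self-exclusion")

    n = len(visit)
    d2 = np.sum((X - visit.values[None, :]) ** 2, axis=1)
    dist = np.sqrt(d2 / _distance_denominator(n))
    order = np.lexsort((ids.astype(str), dist))[: min(k, len(ids))]
    if len(order) < k:
        warnings.warn(
            f"only {len(order)} candidate curves available (requested {k})",
            RuntimeWarning,
        )
    matched = ids[order]
    return MatchResult(
        matched_ids=list(matched),
        distances=dist[order],
        weights=db.weights.loc[matched].to_numpy(dtype=float),
        n_visit_months=n,
    )


def predict_from_matches(match: MatchResult, db: MatchingDatabase,
                         after_month: int) -> PredictionResult:
    """Weighted mean (and spread) of the matched curves after a month.

    Weights are the database weighing scores, normalised here; the
    prediction covers months ``after_month + 1 .. 48`` and is empty (not an
    error) when ``after_month >= 48``.  Weighted per-month quantiles of the
    matched curves are included as an alternative spread display.
    """
    if len(match) == 0:
        raise ValueError("no matches to predict from")
    months = MONTHS[MONTHS > after_month]
    if len(months) == 0:
        empty = np.array([])
        return PredictionResult(months=months, predicted=empty, spread=empty,
                                quantiles=pd.DataFrame(), matched=match,
                                after_month=after_month)
    cols = [f"month_{m}" for m in months]
    C = db.curves.loc[match.matched_ids, cols].to_numpy(dtype=float)
    w = match.weights / match.weights.sum()
    pred = w @ C
    spread = np.sqrt(np.maximum(w @ (C - pred[None, :]) ** 2, 0.0))
    qs = {}
    for q in (0.10, 0.25, 0.50, 0.75, 0.90):
        qs[f"q{int(q * 100)}"] = _weighted_quantile(C, w, q)
    return PredictionResult(
        months=months, predicted=pred, spread=spread,
        quantiles=pd.DataFrame(qs, index=months), matched=match,
        after_month=after_month,
    )


def _weighted_quantile(C: np.ndarray, w: np.ndarray, q: float) -> np.ndarray:
    """Per-column weighted quantile (linear interpolation on the CDF)."""
    out = np.empty(C.shape[1])
    for j in range(C.shape[1]):
        order = np.argsort(C[:, j])
        x, ww = C[order, j], w[order]
        cdf = np.cumsum(ww) - 0.5 * ww
        cdf /= ww.sum()
        out[j] = np.interp(q, cdf, x)
    return out


def predict_height_curve(pred: PredictionResult, age_at_start: float, sex: str,
                         ref: GrowthReference) -> np.ndarray:
    """Convert a predicted HSDS curve to height in cm for one patient.

    Each month's HSDS is converted at age ``age_at_start + month / 12``
    with the patient's sex.
    """
    ages = age_at_start + pred.months / 12.0
    return np.array([
        height_from_hsds(z, a, sex, ref) for z, a in zip(pred.predicted, ages)
    ])


def match_and_predict(visit: VisitVector, db: MatchingDatabase,
                      k: int = DEFAULT_K, exclude_id=None) -> PredictionResult:
    """Convenience wrapper: match on the visit vector, then predict after
    its last month."""
    match = find_matches(visit, db, k=k, exclude_id=exclude_id)
    return predict_from_matches(match, db, after_month=int(visit.months[-1]))
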