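"""Validation harness: visit-history groups and prediction-error summaries.

Prediction accuracy is assessed on observed (not model-smoothed) records.
Five nested visit-history groups mimic how much information a clinician
has at prediction time:

1. HSDS known at treatment start only;
2. start plus >= 1 measurement at months 1-3 (history fed up to month 3);
3. start plus >= 1 measurement at months 4-6 (history to month 6);
4. start plus >= 1 measurement at months 9-12 (history to month 12);
5. start plus >= 1 at months 7-12 and >= 1 at months 13-24 (history to 24).

For every subject x group, the visit vector up to the group's history
cutoff is matched against the database (with the subject's own curve
excluded), the weighted-mean prediction is computed, and errors
(observed - predicted HSDS) are recorded at every later observed month.
Errors are summarised by months-on-treatment bins 4-9, 10-14, 15-20,
21-27, 28-32, 33-39 and 40-48; months 1-3 fall in no bin and are excluded
from summaries.  The error SD per bin is the headline accuracy metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .database import MatchingDatabase
from .matching import DEFAULT_K, NoCandidatesError, find_matches, predict_from_matches
from .monthly import to_visit_vector

__all__ = ["ValidationGroupSpec", "GROUP_SPECS", "MONTH_BINS", "bin_label",
           "build_groups", "run_validation", "summarize_bins"]

log = logging.getLogger(__name__)

MONTH_BINS = ((4, 9), (10, 14), (15, 20), (21, 27), (28, 32), (33, 39), (40, 48))


@dataclass(frozen=True)
class ValidationGroupSpec:
    """Membership and history rules for one validation group."""

    group_id: int
    required_windows: tuple    # inclusive month intervals needing >= 1 visit
    history_cutoff: int        # months fed to the matcher
    evaluation_after: int      # errors scored at months strictly beyond this

    def __post_init__(self):
        if self.evaluation_after < self.history_cutoff:
            raise ValueError("evaluation_after must be >= history_cutoff")


GROUP_SPECS = (
    ValidationGroupSpec(1, (), 0, 0),
    ValidationGroupSpec(2, ((1, 3),), 3, 3),
    ValidationGroupSpec(3, ((4, 6),), 6, 6),
    ValidationGroupSpec(4, ((9, 12),), 12, 12),
    ValidationGroupSpec(5, ((7, 12), (13, 24)), 24, 24),
)


def bin_label(month: int) -> str | None:
    """Months-on-treatment bin for an evaluation month, or None if < 4."""
    for lo, hi in MONTH_BINS:
        if lo <= month <= hi:
            return f"{lo}-{hi}"
    return None


def build_groups(records: pd.DataFrame,
                 specs=GROUP_SPECS) -> dict:
    """Map subject_id -> set of group ids the subject qualifies for.

    Works on rounded integer months (0..48).  A subject qualifies for a
    group when month 0 is observed, every required window holds at least
    one visit, and at least one visit falls after the evaluation cutoff.
    """
    membership: dict = {}
    for sid, sub in records.groupby("subject_id", sort=True):
        vv = to_visit_vector(sub, up_to_month=48, subject_id=sid)
        months = set(vv.months.tolist())
        groups = set()
        for spec in specs:
            if 0 not in months:
                continue
            if any(not any(lo <= m <= hi for m in months)
                   for lo, hi in spec.required_windows):
                continue
            if not any(m > spec.evaluation_after for m in months):
                continue
            groups.add(spec.group_id)
        membership[sid] = groups
    return membership


def run_validation(records: pd.DataFrame, db: MatchingDatabase,
                   specs=GROUP_SPECS, k: int = DEFAULT_K,
                   self_exclude: bool = True) -> pd.DataFrame:
    """Observed-minus-predicted errors for every subject x group x month.

    Returns the error table with columns subject_id, group_id, month,
    observed, predicted, error and bin.  Subjects whose history finds no
    candidates are skipped with a log entry.  ``self_exclude`` removes the
    subject's own curve from the database before matching; switching it
    off is only useful as a leakage check.
    """
    membership = build_groups(records, specs)
    spec_by_id = {s.group_id: s for s in specs}
    db_ids = set(db.subject_ids)
    rows = []
    for sid, sub in records.groupby("subject_id", sort=True):
        groups = membership.get(sid, set())
        if not groups:
            continue
        vv = to_visit_vector(sub, up_to_month=48, subject_id=sid)
        for gid in sorted(groups):
            spec = spec_by_id[gid]
            history = vv.up_to(spec.history_cutoff)
            if len(history) == 0:
                continue
            exclude = sid if (self_exclude and sid in db_ids) else None
            try:
                match = find_matches(history, db, k=k, exclude_id=exclude)
            except NoCandidatesError:
                log.warning("no candidates for subject %s in group %d", sid, gid)
                continue
            pred = predict_from_matches(match, db, int(history.months[-1]))
            pred_by_month = dict(zip(pred.months.tolist(), pred.predicted))
            for m, obs in zip(vv.months, vv.values):
                if m <= spec.evaluation_after or m not in pred_by_month:
                    continue
                p = pred_by_month[m]
                rows.append({
                    "subject_id": sid, "group_id": gid, "month": int(m),
                    "observed": float(obs), "predicted": float(p),
                    "error": float(obs - p), "bin": bin_label(int(m)),
                })
    return pd.DataFrame(
        rows, columns=["subject_id", "group_id", "month", "observed",
                       "predicted", "error", "bin"],
    )


def summarize_bins(errors: pd.DataFrame, stratify: str | None = None) -> pd.DataFrame:
    """Per group x month-bin error statistics.

    Reports n, mean, SD (sample, n-1), median, quartiles (linear
    interpolation between order statistics) and min/max -- the boxplot
    statistics plus the error SD.  Empty bins are emitted with n = 0 and
    null statistics.  ``stratify`` optionally adds a metadata column of
    ``errors`` (e.g. indication or an age band) to the grouping.
    """
    if errors.empty:
        raise ValueError("error table is empty")
    keys = ["group_id"] + ([stratify] if stratify else [])
    scored = errors.dropna(subset=["bin"])
    out = []
    strata = scored.groupby(keys) if stratify else scored.groupby("group_id")
    for key, sub in strata:
        key = key if isinstance(key, tuple) else (key,)
        for lo, hi in MONTH_BINS:
            label = f"{lo}-{hi}"
            e = sub.loc[sub["bin"] == label, "error"].to_numpy(dtype=float)
            row = dict(zip(keys, key))
            row["bin"] = label
            row["n"] = len(e)
            if len(e):
                row.update({
                    "mean": float(np.mean(e)),
                    "sd": float(np.std(e, ddof=1)) if len(e) > 1 else 0.0,
                    "median": float(np.median(e)),
                    "q1": float(np.quantile(e, 0.25)),
                    "q3": float(np.quantile(e, 0.75)),
                    "min": float(np.min(e)),
                    "max": float(np.max(e)),
                })
            else:
                row.update({k: np.nan for k in
                            ("mean", "sd", "median", "q1", "q3", "min", "max")})
            out.append(row)
    return pd.DataFrame(out)
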