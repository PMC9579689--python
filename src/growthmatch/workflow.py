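"""End-to-end pipeline: raw records -> cleaned data -> Matching Database.

Chains the cleaning rules, the broken-stick fit, monthly interpolation,
database selection and weighing scores, which is the preparation a new
deployment runs once before serving match requests.
"""

from __future__ import annotations

import pandas as pd

from . import brokenstick
from .cleaning import CleaningConfig, clean_records
from .database import (GOOD_MATCH_THRESHOLD, MatchingDatabase, SelectionCriteria)
from .monthly import interpolate_monthly
from .reference import GrowthReference

__all__ = ["build_matching_database", "subject_metadata"]


def subject_metadata(records: pd.DataFrame) -> pd.DataFrame:
    """Per-subject sex / indication / age-at-start table from long records.

    ``age_at_start`` is taken from the column when present, otherwise
    derived as ``age_years - months_on_treatment / 12`` of the earliest
    record.
    """
    firsts = (records.sort_values("months_on_treatment", kind="stable")
              .groupby("subject_id").first())
    meta = pd.DataFrame(index=firsts.index)
    for col in ("sex", "indication"):
        if col in firsts.columns:
            meta[col] = firsts[col]
    if "age_at_start" in firsts.columns:
        meta["age_at_start"] = firsts["age_at_start"].astype(float)
    else:
        meta["age_at_start"] = (firsts["age_years"].astype(float)
                                - firsts["months_on_treatment"].astype(float) / 12.0)
    return meta


def build_matching_database(records: pd.DataFrame,
                            ref: GrowthReference | None = None,
                            criteria: SelectionCriteria | None = None,
                            cleaning: CleaningConfig | None = None,
                            grid: "brokenstick.KnotGrid | None" = None,
                            fit_config: "brokenstick.FitConfig | None" = None,
                            good_threshold: float = GOOD_MATCH_THRESHOLD,
                            indication: str | None = None):
    """Run the full preparation pipeline.

    Returns ``(db, clean, model, report)``: the Matching Database, the
    cleaned record table, the final broken-stick model and the cleaning
    report.
    """
    clean, model, report = clean_records(records, ref=ref, config=cleaning,
                                         grid=grid, fit_config=fit_config)
    estimates = brokenstick.predict_all(model, clean)
    curves = [interpolate_monthly(e) for e in estimates]
    meta = subject_metadata(clean)
    db = MatchingDatabase.build(curves, meta, criteria=criteria,
                                good_threshold=good_threshold,
                                indication=indication)
    return db, clean, model, report
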