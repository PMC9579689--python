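"""Charts: matched-curve growth charts and validation boxplots.

The match chart overlays the matched database curves on the patient's
observed visits; line width encodes the weighing score (common
trajectories drawn heavier, unique ones fainter) and the weighted-mean
prediction is drawn in red.  Axes can show HSDS or height in cm.
"""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .database import MatchingDatabase
from .matching import PredictionResult, predict_height_curve
from .monthly import MONTHS, VisitVector
from .reference import GrowthReference, height_from_hsds
from .validation import MONTH_BINS

__all__ = ["render_match_chart", "render_boxplots", "match_linewidths"]


def match_linewidths(weights, lw_min: float = 0.4, lw_max: float = 2.2) -> np.ndarray:
    """Line width per matched curve, increasing with the weighing score."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        return w
    span = w.max() - w.min()
    if span <= 0:
        return np.full_like(w, 0.5 * (lw_min + lw_max))
    return lw_min + (w - w.min()) / span * (lw_max - lw_min)


def render_match_chart(pred: PredictionResult, db: MatchingDatabase,
                       path=None, visit: VisitVector | None = None,
                       axis: str = "hsds", age_at_start: float | None = None,
                       sex: str | None = None, ref: GrowthReference | None = None):
    """Draw matched curves, the weighted-mean prediction and the visits.

    ``axis="cm"`` converts everything to height via the reference (requires
    ``age_at_start``, ``sex`` and ``ref``).  Returns the figure; writes it
    to ``path`` when given.
    """
    if axis not in ("hsds", "cm"):
        raise ValueError("axis must be 'hsds' or 'cm'")
    use_cm = axis == "cm"
    if use_cm and (age_at_start is None or sex is None or ref is None):
        raise ValueError("cm axis requires age_at_start, sex and ref")

    def to_axis(months, values):
        if not use_cm:
            return np.asarray(values, dtype=float)
        ages = age_at_start + np.asarray(months, dtype=float) / 12.0
        return np.array([height_from_hsds(z, a, sex, ref)
                         for z, a in zip(values, ages)])

    fig, ax = plt.subplots(figsize=(7, 5))
    widths = match_linewidths(pred.matched.weights)
    for sid, lw in zip(pred.matched.matched_ids, widths):
        curve = db.curves.loc[sid].to_numpy(dtype=float)
        line, = ax.plot(MONTHS, to_axis(MONTHS, curve), color="steelblue",
                        alpha=0.55, lw=lw)
        line.set_gid(f"match:{sid}")
    if len(pred.months):
        mean_line, = ax.plot(pred.months, to_axis(pred.months, pred.predicted),
                             color="red", lw=2.8, label="weighted mean prediction")
        mean_line.set_gid("weighted_mean")
        if use_cm:
            pass  # spread band is an SDS-scale construct; omit on the cm axis
        else:
            ax.fill_between(pred.months, pred.predicted - pred.spread,
                            pred.predicted + pred.spread, color="red", alpha=0.12,
                            label="+/- 1 weighted SD")
    if visit is not None and len(visit):
        ax.plot(visit.months, to_axis(visit.months, visit.values), "o",
                color="black", ms=6, zorder=5, label="observed visits")
    ax.set_xlabel("months on treatment")
    ax.set_ylabel("height (cm)" if use_cm else "HSDS")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def render_boxplots(summaries, path=None):
    """Boxplots of prediction error per month bin, one panel per group.

    ``summaries`` is the output of :func:`validation.summarize_bins`: the
    boxes are drawn from the precomputed quartile statistics (whiskers run
    to min and max).  Empty bins are skipped.  Returns the figure.
    """
    groups = sorted(summaries["group_id"].unique())
    fig, axes = plt.subplots(1, len(groups), figsize=(3.0 * len(groups), 4),
                             sharey=True, squeeze=False)
    order = [f"{lo}-{hi}" for lo, hi in MONTH_BINS]
    for ax, gid in zip(axes[0], groups):
        sub = summaries[summaries["group_id"] == gid].set_index("bin")
        stats, positions = [], []
        for i, label in enumerate(order):
            if label not in sub.index or not sub.loc[label, "n"]:
                continue
            row = sub.loc[label]
            stats.append({
                "med": row["median"], "q1": row["q1"], "q3": row["q3"],
                "whislo": row["min"], "whishi": row["max"], "label": label,
            })
            positions.append(i)
        if stats:
            ax.bxp(stats, positions=positions, showfliers=False)
        ax.axhline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_title(f"Group {gid}")
        ax.set_xticks(range(len(order)))
        ax.set_xticklabels(order, rotation=45, fontsize=7)
        ax.set_xlabel("months on treatment")
    axes[0][0].set_ylabel("observed - predicted HSDS")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
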