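"""Synthetic cohorts with the longitudinal structure of r-hGH registries.

Real treatment-registry growth records are proprietary; this generator emulates
their statistical shape so every pipeline stage is testable offline.  Each
child follows a smooth catch-up trajectory in HSDS,

    h(t) = h_inf - (h_inf - h0) * exp(-t / tau),

with baseline ``h0 ~ N(-2.4, 0.7)``, plateau ``h_inf ~ N(-1.0, 0.8)``
truncated to exceed ``h0`` (catch-up), and a subject-specific timescale
``tau`` lognormal around 18 months.  A configurable minority of
non-responders declines slowly instead.  Visits follow registry practice:
a baseline visit at month 0 and 1-4 visits per year at uniformly jittered
times up to 54 months.  Observed HSDS adds N(0, 0.05) measurement noise
(about 0.3 cm) and heights are derived through the growth reference at the
child's age and sex.

``inject_artifacts`` plants the three error types the cleaning rules are
designed to catch -- out-of-range HSDS, >= 2 cm height drops and isolated
+/- 0.6 SDS spikes -- with ground-truth labels, enabling recall checks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .reference import GrowthReference, height_from_hsds, load_who_style_reference

__all__ = ["CohortConfig", "ArtifactConfig", "TrueTrajectory",
           "simulate_cohort", "inject_artifacts", "true_monthly_curves"]


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults mirror the published cohort moments."""

    n_subjects: int = 500
    seed: int = 0
    baseline_hsds_mean: float = -2.4
    baseline_hsds_sd: float = 0.7
    final_hsds_mean: float = -1.0
    final_hsds_sd: float = 0.8
    catchup_timescale_months: float = 18.0   # lognormal median of tau
    catchup_timescale_log_sd: float = 0.35
    visits_per_year: tuple = (1, 4)          # inclusive integer range
    measurement_error_sd: float = 0.05       # SDS, ~0.3 cm
    frac_sga: float = 0.23
    frac_nonresponder: float = 0.05
    age_at_start_range: tuple = (3.0, 16.0)
    sex_ratio_male: float = 0.64
    months_max: float = 54.0

    def __post_init__(self):
        if (self.baseline_hsds_sd <= 0 or self.final_hsds_sd <= 0
                or self.measurement_error_sd < 0):
            raise ValueError("standard deviations must be positive")
        for frac in (self.frac_sga, self.frac_nonresponder, self.sex_ratio_male):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.visits_per_year[0] < 1 or self.visits_per_year[1] < self.visits_per_year[0]:
            raise ValueError("visits_per_year must be a valid integer range")


@dataclass(frozen=True)
class ArtifactConfig:
    """Per-subject injection probabilities (at most one artifact each)."""

    p_out_of_range: float = 0.03
    p_height_drop: float = 0.03
    p_spike: float = 0.10
    spike_sds: float = 0.6
    drop_extra_cm: tuple = (0.0, 1.5)   # uniform extra beyond the 2 cm rule

    def __post_init__(self):
        total = self.p_out_of_range + self.p_height_drop + self.p_spike
        if total > 1:
            raise ValueError("artifact probabilities must sum to <= 1")


@dataclass(frozen=True)
class TrueTrajectory:
    """Latent exponential-approach catch-up curve of one subject."""

    subject_id: str
    h0: float
    h_inf: float
    tau: float

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def curve(self, t):
        t = np.asarray(t, dtype=float)
        h = self.h_inf - (self.h_inf - self.h0) * np.exp(-t / self.tau)
        return float(h) if h.ndim == 0 else h


def _subject_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(n)]


def simulate_cohort(config: CohortConfig | None = None,
                    ref: GrowthReference | None = None):
    """Draw a cohort; returns (trajectories DataFrame, records DataFrame).

    The trajectory table holds one row per subject (latent curve parameters
    and metadata); the record table is long format with one row per
    measurement, carrying both observed HSDS and the derived height in cm.
    Deterministic given ``config.seed``.
    """
    config = config or CohortConfig()
    ref = ref or load_who_style_reference()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    ids = _subject_ids(n)

    h0 = rng.normal(config.baseline_hsds_mean, config.baseline_hsds_sd, n)
    nonresp = rng.random(n) < config.frac_nonresponder
    h_inf = np.empty(n)
    for i in range(n):
        if nonresp[i]:
            h_inf[i] = h0[i] - abs(rng.normal(0.0, 0.3))
        else:
            # truncated draw: plateau must exceed baseline for catch-up
            while True:
                draw = rng.normal(config.final_hsds_mean, config.final_hsds_sd)
                if draw > h0[i]:
                    h_inf[i] = draw
                    break
    tau = np.exp(rng.normal(np.log(config.catchup_timescale_months),
                            config.catchup_timescale_log_sd, n))
    sex = np.where(rng.random(n) < config.sex_ratio_male, "M", "F")
    indication = np.where(rng.random(n) < config.frac_sga, "SGA", "GHD")
    age_start = rng.uniform(*config.age_at_start_range, n)

    traj_rows, rec_rows = [], []
    for i, sid in enumerate(ids):
        traj = TrueTrajectory(sid, float(h0[i]), float(h_inf[i]), float(tau[i]))
        traj_rows.append({
            "subject_id": sid, "h0": traj.h0, "h_inf": traj.h_inf,
            "tau": traj.tau, "sex": sex[i], "indication": indication[i],
            "age_at_start": float(age_start[i]),
            "nonresponder": bool(nonresp[i]),
        })
        times = [0.0]
        n_years = int(np.ceil(config.months_max / 12.0))
        for year in range(n_years):
            n_vis = rng.integers(config.visits_per_year[0],
                                 config.visits_per_year[1] + 1)
            t = year * 12.0 + np.sort(rng.uniform(0.0, 12.0, n_vis))
            times.extend(t[(t > 0) & (t <= config.months_max)].tolist())
        times = np.asarray(sorted(times))
        noise = rng.normal(0.0, config.measurement_error_sd, len(times))
        z_obs = traj.curve(times) + noise
        ages = age_start[i] + times / 12.0
        heights = [height_from_hsds(z, a, sex[i], ref)
                   for z, a in zip(z_obs, ages)]
        for t, z, a, h in zip(times, z_obs, ages, heights):
            rec_rows.append({
                "subject_id": sid, "sex": sex[i], "indication": indication[i],
                "age_at_start": float(age_start[i]), "age_years": float(a),
                "months_on_treatment": float(t), "height_cm": float(h),
                "hsds": float(z),
            })

    trajectories = pd.DataFrame(traj_rows).set_index("subject_id", drop=False)
    records = pd.DataFrame(rec_rows)
    records["record_id"] = np.arange(len(records))
    return trajectories, records


def true_monthly_curves(trajectories: pd.DataFrame,
                        months=np.arange(0, 49)) -> pd.DataFrame:
    """Latent trajectories sampled on the monthly grid (wide matrix)."""
    vals = {
        row.subject_id: TrueTrajectory(row.subject_id, row.h0, row.h_inf,
                                       row.tau).curve(months)
        for row in trajectories.itertuples()
    }
    wide = pd.DataFrame(vals).T
    wide.columns = [f"month_{int(m)}" for m in months]
    wide.index.name = "subject_id"
    return wide


def inject_artifacts(records: pd.DataFrame,
                     config: ArtifactConfig | None = None,
                     ref: GrowthReference | None = None,
                     seed: int = 0):
    """Plant labelled measurement errors; returns (records, labels).

    Per subject, at most one artifact is injected (probabilities per
    :class:`ArtifactConfig`), keeping artifact types independent so that
    per-rule recall is attributable:

    - ``out_of_range``: HSDS pushed beyond the (-7, 2) plausibility band;
    - ``height_drop``: height set >= 2 cm below the subject's running
      maximum (heights and HSDS stay mutually consistent);
    - ``spike``: an isolated +/- 0.6 SDS shift of a single measurement.
    """
    config = config or ArtifactConfig()
    ref = ref or load_who_style_reference()
    rng = np.random.default_rng(seed)
    out = records.copy().reset_index(drop=True)
    if "record_id" not in out.columns:
        out["record_id"] = np.arange(len(out))
    labels = []

    for sid, sub in out.groupby("subject_id", sort=True):
        if len(sub) < 3:
            continue
        u = rng.random()
        if u < config.p_out_of_range:
            kind = "out_of_range"
        elif u < config.p_out_of_range + config.p_height_drop:
            kind = "height_drop"
        elif u < config.p_out_of_range + config.p_height_drop + config.p_spike:
            kind = "spike"
        else:
            continue
        sub = sub.sort_values("months_on_treatment")
        if kind == "height_drop":
            pos = int(rng.integers(1, len(sub)))     # never the first record
        else:
            pos = int(rng.integers(0, len(sub)))
        idx = sub.index[pos]
        age = out.at[idx, "age_years"]
        sex = out.at[idx, "sex"]
        if kind == "out_of_range":
            z = (2.0 + abs(rng.normal(0.0, 0.5)) if rng.random() < 0.5
                 else -7.0 - abs(rng.normal(0.0, 0.5)))
            out.at[idx, "hsds"] = z
            out.at[idx, "height_cm"] = height_from_hsds(z, age, sex, ref)
        elif kind == "height_drop":
            run_max = sub["height_cm"].iloc[:pos].max()
            new_h = run_max - 2.0 - rng.uniform(*config.drop_extra_cm)
            out.at[idx, "height_cm"] = new_h
            from .reference import hsds_from_height
            out.at[idx, "hsds"] = hsds_from_height(new_h, age, sex, ref)
        else:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            z = out.at[idx, "hsds"] + sign * config.spike_sds
            out.at[idx, "hsds"] = z
            out.at[idx, "height_cm"] = height_from_hsds(z, age, sex, ref)
        labels.append({"subject_id": sid, "record_id": int(out.at[idx, "record_id"]),
                       "kind": kind})

    return out, pd.DataFrame(labels, columns=["subject_id", "record_id", "kind"])
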