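import numpy as np
import pandas as pd
import pytest

import growthmatch as gm
from growthmatch.database import MatchingDatabase, curve_distance
from growthmatch.matching import (NoCandidatesError, find_matches,
                                  match_and_predict, predict_from_matches,
                                  predict_height_curve)
from growthmatch.monthly import MONTHS, VisitVector
from growthmatch.plots import match_linewidths, render_match_chart


def _random_db(n, seed, spread=0.3):
    rng = np.random.default_rng(seed)
    m = np.asarray(MONTHS, float)
    curves = {}
    for i in range(n):
        h0 = rng.uniform(-3.9, -1.1)
        gain = rng.uniform(0.3, 2.0)
        curves[f"d{i:03d}"] = (h0 + gain * (1 - np.exp(-m / 18.0))
                               + rng.normal(0, spread * 0.05, 49))
    wide = pd.DataFrame(curves).T
    wide.columns = [f"month_{mm}" for mm in MONTHS]
    wide.index.name = "subject_id"
    meta = pd.DataFrame({"sex": "M", "indication": "GHD", "age_at_start": 8.0},
                        index=wide.index)
    weights = pd.Series(rng.uniform(0.1, 1.0, n), index=wide.index, name="weight")
    return MatchingDatabase(curves=wide, meta=meta, weights=weights)


def brute_force_matches(visit, db, k, exclude_id=None):
    """Plain-python reference scan: distances, sort by (distance, id)."""
    scored = []
    for sid, row in db.curves.iterrows():
        if sid == exclude_id:
            continue
        vals = row[[f"month_{m}" for m in visit.months]].to_numpy(dtype=float)
        scored.append((curve_distance(visit.values, vals), str(sid), sid))
    scored.sort(key=lambda x: (x[0], x[1]))
    return [s[2] for s in scored[:k]]


class TestFindMatches:
    def test_identical_restriction_ranks_first(self):
        db = _random_db(30, 1)
        sid = db.subject_ids[7]
        months = np.array([0, 3, 6])
        visit = VisitVector(months, db.curves.loc[
            sid, [f"month_{m}" for m in months]].to_numpy(dtype=float))
        res = find_matches(visit, db, k=5)
        assert res.matched_ids[0] == sid
        assert res.distances[0] == pytest.approx(0.0, abs=1e-12)

    def test_k_larger_than_db_returns_all_sorted(self):
        db = _random_db(8, 2)
        visit = VisitVector([0, 6], [-2.0, -1.8])
        with pytest.warns(RuntimeWarning, match="candidate"):
            res = find_matches(visit, db, k=25)
        assert len(res) == 8
        assert np.all(np.diff(res.distances) >= 0)

    def test_exclusion_removes_self(self):
        db = _random_db(20, 3)
        sid = db.subject_ids[0]
        visit = VisitVector([0], [float(db.curves.loc[sid, "month_0"])])
        res = find_matches(visit, db, k=20, exclude_id=sid)
        assert sid not in res.matched_ids

    def test_empty_db_after_exclusion(self):
        db = _random_db(1, 4)
        visit = VisitVector([0], [-2.0])
        with pytest.raises(NoCandidatesError):
            find_matches(visit, db, k=5, exclude_id=db.subject_ids[0])

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        db = _random_db(int(rng.integers(20, 200)), seed + 10)
        n_months = int(rng.integers(1, 20))
        months = np.sort(rng.choice(49, size=n_months, replace=False))
        visit = VisitVector(months, rng.uniform(-4, 0, n_months))
        k = int(rng.integers(1, 30))
        res = find_matches(visit, db, k=k)
        assert res.matched_ids == brute_force_matches(visit, db, k)


class TestPrediction:
    def test_identical_matches_predict_themselves(self):
        db = _random_db(5, 5)
        base = db.curves.iloc[0].to_numpy(dtype=float)
        db.curves.iloc[:] = np.tile(base, (5, 1))
        visit = VisitVector([0, 3], base[[0, 3]])
        pred = match_and_predict(visit, db, k=5)
        np.testing.assert_allclose(pred.predicted, base[4:], atol=1e-12)
        np.testing.assert_allclose(pred.spread, 0.0, atol=1e-12)

    def test_hand_weighted_mean(self):
        db = _random_db(2, 6)
        db.curves.iloc[0] = -2.0
        db.curves.iloc[1] = -1.0
        db.weights.iloc[:] = [0.75, 0.25]
        visit = VisitVector([0], [-2.0])
        res = find_matches(visit, db, k=2)
        pred = predict_from_matches(res, db, after_month=0)
        np.testing.assert_allclose(pred.predicted, -1.75)

    def test_equal_weights_match_plain_mean(self):
        db = _random_db(10, 7)
        db.weights.iloc[:] = 0.4
        visit = VisitVector([0, 6, 12], [-2.5, -2.2, -2.0])
        pred = match_and_predict(visit, db, k=10)
        cols = [f"month_{m}" for m in pred.months]
        expected = db.curves.loc[pred.matched.matched_ids, cols].mean(axis=0)
        np.testing.assert_allclose(pred.predicted, expected)

    def test_prediction_within_matched_envelope(self):
        db = _random_db(40, 8)
        visit = VisitVector([0, 3, 9], [-2.6, -2.4, -2.1])
        pred = match_and_predict(visit, db, k=25)
        cols = [f"month_{m}" for m in pred.months]
        matched = db.curves.loc[pred.matched.matched_ids, cols].to_numpy()
        assert np.all(pred.predicted >= matched.min(axis=0) - 1e-12)
        assert np.all(pred.predicted <= matched.max(axis=0) + 1e-12)

    def test_after_month_48_empty(self):
        db = _random_db(5, 9)
        res = find_matches(VisitVector([48], [-1.0]), db, k=3)
        pred = predict_from_matches(res, db, after_month=48)
        assert len(pred.months) == 0

    def test_more_history_no_worse_at_month_24(self, true_curve_db, small_cohort):
        # noiseless patients drawn from the same generating process: the
        # month-24 error of the prediction must not get worse as visits
        # accumulate (averaged over replicates)
        cfg, _, _ = small_cohort
        patients, _ = gm.simulate_cohort(
            gm.CohortConfig(n_subjects=250, seed=777, measurement_error_sd=0.0))
        maes = []
        for upto in (0, 3, 6, 9):
            errs = []
            for row in patients.itertuples():
                traj = gm.TrueTrajectory(row.subject_id, row.h0, row.h_inf, row.tau)
                months = np.array([m for m in (0, 3, 6, 9) if m <= upto])
                visit = VisitVector(months, traj.curve(months.astype(float)))
                pred = match_and_predict(visit, true_curve_db, k=25)
                errs.append(abs(pred.predicted[pred.months == 24][0]
                                - traj.curve(24.0)))
            maes.append(np.mean(errs))
        assert all(maes[i + 1] <= maes[i] + 1e-9 for i in range(len(maes) - 1))


class TestHeightConversion:
    def test_hand_value(self):
        ref = gm.synthetic_reference(ages=range(0, 22), m0=130.0, slope=0.0, s=0.05)
        db = _random_db(3, 11)
        res = find_matches(VisitVector([0], [-2.0]), db, k=3)
        pred = predict_from_matches(res, db, after_month=47)
        pred.predicted[:] = -2.0
        heights = predict_height_curve(pred, age_at_start=6.0, sex="M", ref=ref)
        assert heights[0] == pytest.approx(117.0)   # 130 * (1 - 0.05*2)

    def test_round_trip(self, who_ref):
        db = _random_db(10, 12)
        visit = VisitVector([0, 6], [-2.5, -2.3])
        pred = match_and_predict(visit, db, k=10)
        heights = predict_height_curve(pred, 7.0, "F", who_ref)
        back = [gm.hsds_from_height(h, 7.0 + m / 12.0, "F", who_ref)
                for h, m in zip(heights, pred.months)]
        np.testing.assert_allclose(back, pred.predicted, atol=1e-9)


class TestChart:
    def test_chart_written_and_linewidths_track_weights(self, tmp_path):
        db = _random_db(40, 13)
        visit = VisitVector([0, 3, 6], [-2.6, -2.4, -2.2])
        pred = match_and_predict(visit, db, k=25)
        path = tmp_path / "chart.png"
        fig = render_match_chart(pred, db, path, visit=visit)
        assert path.exists() and path.stat().st_size > 0
        lines = {ln.get_gid(): ln for ln in fig.axes[0].lines
                 if ln.get_gid() and ln.get_gid().startswith("match:")}
        widths = [lines[f"match:{sid}"].get_linewidth()
                  for sid in pred.matched.matched_ids]
        order_w = np.argsort(pred.matched.weights)
        assert np.all(np.diff(np.asarray(widths)[order_w]) >= -1e-12)
        assert any(ln.get_gid() == "weighted_mean" for ln in fig.axes[0].lines)

    def test_cm_axis_uses_height_conversion(self, tmp_path, who_ref):
        db = _random_db(10, 14)
        visit = VisitVector([0], [-2.4])
        pred = match_and_predict(visit, db, k=5)
        fig = render_match_chart(pred, db, tmp_path / "cm.png", visit=visit,
                                 axis="cm", age_at_start=8.0, sex="M",
                                 ref=who_ref)
        mean_line = next(ln for ln in fig.axes[0].lines
                         if ln.get_gid() == "weighted_mean")
        expected = predict_height_curve(pred, 8.0, "M", who_ref)
        np.testing.assert_allclose(mean_line.get_ydata(), expected)

    def test_constant_weights_constant_width(self):
        w = match_linewidths(np.full(5, 0.3))
        assert np.ptp(w) == 0
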