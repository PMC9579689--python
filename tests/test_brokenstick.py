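import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import growthmatch as gm
from growthmatch import brokenstick as bs

from conftest import gls_beta_se, simulate_from_mixed_model

SMALL_GRID = gm.KnotGrid(knots=(0.0, 3.0, 6.0, 9.0, 12.0), boundary=None)
TWO_KNOTS = gm.KnotGrid(knots=(0.0, 3.0), boundary=None)


def _model(grid, beta, omega, sigma2):
    return bs.BrokenStickModel(
        grid=grid, beta=np.asarray(beta, float), omega=np.asarray(omega, float),
        sigma2=sigma2, converged=True, n_subjects=1, n_observations=1,
        log_likelihood=0.0)


class TestBasis:
    def test_knot_values_are_indicators(self):
        grid = gm.KnotGrid()
        for i, k in enumerate(grid.all_knots):
            b = bs.bspline_basis(k, grid)
            expected = np.zeros(grid.n_basis)
            expected[i] = 1.0
            np.testing.assert_allclose(b, expected)

    def test_interior_tent_weights(self):
        b = bs.bspline_basis(1.0, TWO_KNOTS)
        np.testing.assert_allclose(b, [2 / 3, 1 / 3])

    @given(t=st.floats(0, 54))
    def test_partition_of_unity(self, t):
        b = bs.bspline_basis(t, gm.KnotGrid())
        assert np.all(b >= 0)
        assert np.count_nonzero(b) <= 2
        assert b.sum() == pytest.approx(1.0)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            bs.bspline_basis(55.0, gm.KnotGrid())
        with pytest.raises(ValueError):
            bs.bspline_basis(-1.0, gm.KnotGrid())


class TestFit:
    def test_parameter_recovery(self):
        knots = SMALL_GRID.all_knots
        beta = -2.4 + 0.08 * knots
        D = np.abs(knots[:, None] - knots[None, :])
        omega = 0.45 * np.exp(-D / 12.0)
        sigma2 = 0.01
        rec = simulate_from_mixed_model(150, SMALL_GRID, beta, omega, sigma2,
                                        seed=21, visits=(3, 8))
        model = bs.fit(rec, SMALL_GRID)
        assert model.converged
        se = gls_beta_se(model, rec)
        assert np.all(np.abs(model.beta - beta) < 3 * se)
        assert abs(model.sigma2 - sigma2) / sigma2 < 0.2

    def test_loglik_never_decreases(self):
        rec = simulate_from_mixed_model(
            60, SMALL_GRID, np.full(5, -2.0), 0.3 * np.eye(5), 0.02, seed=3)
        model = bs.fit(rec, SMALL_GRID)
        assert np.all(np.diff(model.loglik_path) > -1e-6)

    def test_noiseless_interpolation_limit(self):
        # exact piecewise-linear data observed at every knot
        rng = np.random.default_rng(4)
        knots = SMALL_GRID.all_knots
        rows, truth = [], {}
        for i in range(80):
            vals = -2.5 + rng.normal(0, 0.6) + 0.07 * knots + rng.normal(0, 0.05, 5)
            truth[f"S{i:03d}"] = vals
            for t, v in zip(knots, vals):
                rows.append({"subject_id": f"S{i:03d}",
                             "months_on_treatment": t, "hsds": v})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = bs.fit(pd.DataFrame(rows), SMALL_GRID)
        assert model.sigma2 <= 1e-4
        for sid, sub in pd.DataFrame(rows).groupby("subject_id"):
            est = bs.predict_subject(model, sub)
            np.testing.assert_allclose(est.values, truth[sid], atol=1e-2)

    def test_shared_curve_gives_zero_omega(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(30):
            t = np.sort(rng.uniform(0, 12, 5))
            for tt in t:
                rows.append({"subject_id": i, "months_on_treatment": tt,
                             "hsds": -2.4 + 0.08 * tt})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = bs.fit(pd.DataFrame(rows), SMALL_GRID)
        assert np.abs(model.omega).max() < 1e-6
        np.testing.assert_allclose(model.beta, -2.4 + 0.08 * SMALL_GRID.all_knots,
                                   atol=1e-6)

    def test_rejects_single_observation_subjects(self):
        rec = pd.DataFrame({"subject_id": ["a", "a", "b"],
                            "months_on_treatment": [0.0, 6.0, 3.0],
                            "hsds": [-2.0, -1.9, -2.2]})
        with pytest.raises(ValueError, match="fewer than 2"):
            bs.fit(rec, SMALL_GRID)

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.api as sm

        rec = simulate_from_mixed_model(
            80, TWO_KNOTS, np.array([-2.4, -1.6]),
            np.array([[0.5, 0.3], [0.3, 0.45]]), 0.01, seed=42, visits=(3, 6),
            t_max=3.0)
        mine = bs.fit(rec, TWO_KNOTS)
        Z = bs.bspline_basis(rec["months_on_treatment"].to_numpy(), TWO_KNOTS)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(rec["hsds"].to_numpy(), Z,
                             groups=rec["subject_id"].to_numpy(),
                             exog_re=Z).fit(reml=False)
        np.testing.assert_allclose(mine.beta, res.fe_params, atol=1e-4)
        assert mine.sigma2 == pytest.approx(res.scale, rel=1e-2)
        np.testing.assert_allclose(mine.omega, np.asarray(res.cov_re), atol=1e-3)
        assert mine.log_likelihood == pytest.approx(res.llf, abs=1e-2)


class TestBlup:
    def test_closed_form_single_observation(self):
        # hand-computed: z=(2/3,1/3), V = z'Omega z + sigma2 = 0.2955556,
        # u = Omega z (y - z beta)/V
        model = _model(TWO_KNOTS, [-2.0, -1.5],
                       [[0.4, 0.1], [0.1, 0.3]], 0.04)
        rec = pd.DataFrame({"subject_id": ["a"], "months_on_treatment": [1.0],
                            "hsds": [-1.5]})
        est = bs.predict_subject(model, rec)
        np.testing.assert_allclose(est.values, [-1.66165414, -1.31203008],
                                   atol=1e-7)

    def test_no_observations_returns_population_mean(self):
        model = _model(TWO_KNOTS, [-2.0, -1.5], [[0.4, 0.1], [0.1, 0.3]], 0.04)
        rec = pd.DataFrame({"subject_id": [], "months_on_treatment": [],
                            "hsds": []})
        est = bs.predict_subject(model, rec, subject_id="ghost")
        np.testing.assert_allclose(est.values, model.beta)

    def test_interpolation_limit_small_sigma(self):
        model = _model(TWO_KNOTS, [-2.0, -1.5], [[0.4, 0.1], [0.1, 0.3]], 1e-12)
        rec = pd.DataFrame({"subject_id": ["a", "a"],
                            "months_on_treatment": [0.0, 3.0],
                            "hsds": [-2.7, -1.2]})
        est = bs.predict_subject(model, rec)
        np.testing.assert_allclose(est.values, [-2.7, -1.2], atol=1e-4)

    def test_shrinkage_toward_beta_as_sigma2_grows(self):
        rec = pd.DataFrame({"subject_id": ["a", "a"],
                            "months_on_treatment": [0.0, 3.0],
                            "hsds": [-2.7, -1.2]})
        beta = np.array([-2.0, -1.5])
        omega = np.array([[0.4, 0.1], [0.1, 0.3]])
        prev_gap = np.inf
        for sigma2 in (1e-6, 0.01, 0.1, 1.0, 10.0):
            est = bs.predict_subject(_model(TWO_KNOTS, beta, omega, sigma2), rec)
            gap = np.abs(est.values - beta).sum()
            assert gap < prev_gap + 1e-12
            prev_gap = gap


class TestResiduals:
    def test_zero_residuals_in_noiseless_limit(self):
        # with negligible residual variance the subject curve interpolates
        # the observations, so observed minus fitted vanishes
        model = _model(TWO_KNOTS, [-2.0, -1.5], [[0.4, 0.1], [0.1, 0.3]], 1e-12)
        rec = pd.DataFrame({"subject_id": ["a", "a"],
                            "months_on_treatment": [0.5, 2.0],
                            "hsds": [-1.8, -1.6]})
        np.testing.assert_allclose(bs.residuals(model, rec), 0.0, atol=1e-9)

    def test_perturbation_shifts_residual_by_one_minus_leverage(self):
        # oracle: explicit V and hat-matrix algebra, independent of the
        # package's BLUP code path
        model = _model(TWO_KNOTS, [-2.0, -1.5], [[0.4, 0.1], [0.1, 0.3]], 0.04)
        t = np.array([0.0, 1.0, 3.0])
        y = np.array([-2.1, -1.7, -1.4])
        rec = pd.DataFrame({"subject_id": ["a"] * 3, "months_on_treatment": t,
                            "hsds": y})
        r0 = bs.residuals(model, rec).to_numpy()
        delta = 0.4
        rec2 = rec.copy()
        rec2.loc[1, "hsds"] += delta
        r1 = bs.residuals(model, rec2).to_numpy()
        Z = bs.bspline_basis(t, TWO_KNOTS)
        W = Z @ model.omega @ Z.T
        H = W @ np.linalg.inv(W + model.sigma2 * np.eye(3))
        expected_shift = delta * (1.0 - H[1, 1])
        assert r1[1] - r0[1] == pytest.approx(expected_shift, abs=1e-9)


def test_model_json_round_trip(tmp_path):
    model = _model(gm.KnotGrid(), -2.0 - 0.01 * gm.KnotGrid().all_knots,
                   np.eye(18) * 0.4, 0.0025)
    path = tmp_path / "model.json"
    model.to_json(path)
    again = bs.BrokenStickModel.from_json(path)
    np.testing.assert_allclose(again.beta, model.beta)
    np.testing.assert_allclose(again.omega, model.omega)
    assert again.grid.knots == model.grid.knots
    assert again.sigma2 == model.sigma2
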