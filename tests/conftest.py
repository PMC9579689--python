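import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import growthmatch as gm
from growthmatch import brokenstick as bs

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_ref():
    """Constant-L synthetic reference: 1 SDS = M(age) * 0.045 cm exactly."""
    return gm.synthetic_reference()


@pytest.fixture(scope="session")
def who_ref():
    return gm.load_who_style_reference()


@pytest.fixture(scope="session")
def small_cohort():
    """200-subject synthetic cohort shared by pipeline-level tests."""
    cfg = gm.CohortConfig(n_subjects=200, seed=123)
    traj, rec = gm.simulate_cohort(cfg)
    return cfg, traj, rec


@pytest.fixture(scope="session")
def true_curve_db(small_cohort):
    """Matching database built from the latent (noise-free) monthly curves."""
    _, traj, _ = small_cohort
    curves = gm.true_monthly_curves(traj)
    meta = traj[["sex", "indication", "age_at_start"]]
    return gm.MatchingDatabase.build(curves, meta)


def simulate_from_mixed_model(n_subjects, grid, beta, omega, sigma2, seed,
                              visits=(4, 10), t_max=None):
    """Draw records straight from the broken-stick generative model."""
    rng = np.random.default_rng(seed)
    t_max = t_max if t_max is not None else grid.max_time
    L = np.linalg.cholesky(omega + 1e-10 * np.eye(len(beta)))
    rows = []
    for i in range(n_subjects):
        u = L @ rng.standard_normal(len(beta))
        n = int(rng.integers(visits[0], visits[1] + 1))
        t = np.sort(rng.uniform(0, t_max, n))
        Z = bs.bspline_basis(t, grid)
        y = Z @ (beta + u) + rng.normal(0, np.sqrt(sigma2), n)
        for tt, yy in zip(t, y):
            rows.append({"subject_id": f"S{i:04d}",
                         "months_on_treatment": tt, "hsds": yy})
    return pd.DataFrame(rows)


def gls_beta_se(model, records):
    """Model-based standard errors of the fixed effects (GLS information)."""
    K = model.grid.n_basis
    A = np.zeros((K, K))
    for _, sub in records.groupby("subject_id"):
        Z = bs.bspline_basis(sub["months_on_treatment"].to_numpy(), model.grid)
        V = Z @ model.omega @ Z.T + model.sigma2 * np.eye(len(sub))
        A += Z.T @ np.linalg.solve(V, Z)
    return np.sqrt(np.diag(np.linalg.inv(A)))
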