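"""Broken-stick model: a linear mixed model on a first-degree B-spline basis.

Irregularly timed HSDS observations of many children are summarised as
values on a common grid of breakpoints (every 3 months from 0 to 48 months
of treatment, with an optional right boundary knot at 54 months so that
late observations still inform the fit).  For subject ``i`` with
observation times ``t_ij``:

    y_ij = sum_k b_k(t_ij) * (beta_k + u_ik) + eps_ij
    u_i ~ MVN(0, Omega),   eps_ij ~ N(0, sigma2)

where ``b_k`` is the tent (linear B-spline) basis function peaking at knot
``k``.  Because the basis interpolates linearly, ``beta_k + u_ik`` is the
subject's HSDS at knot ``k`` and the fitted trajectory is a series of
connected straight lines.

Estimation is deterministic maximum likelihood via an ECM-type algorithm:
an EM update for the between-subject covariance ``Omega``, a profile
(1-D numerical) maximisation for the residual variance ``sigma2`` and a
GLS update for the fixed effects ``beta``.  Each step is monotone in the
marginal log-likelihood.  Subject-level curves are best linear unbiased
predictions (BLUP),

    u_hat_i = Omega Z_i' V_i^{-1} (y_i - Z_i beta),
    V_i = Z_i Omega Z_i' + sigma2 I,

which shrink sparsely observed subjects toward the population mean curve.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KnotGrid",
    "FitConfig",
    "BrokenStickModel",
    "SubjectKnotEstimates",
    "bspline_basis",
    "fit",
    "predict_subject",
    "predict_all",
    "residuals",
]


@dataclass(frozen=True)
class KnotGrid:
    """Breakpoint grid in months on treatment.

    ``knots`` are the reporting knots (default 0, 3, ..., 48); ``boundary``
    is an optional extra right knot (default 54) that extends the basis so
    observations beyond the last reporting knot are usable, without being
    part of the reported trajectory.
    """

    knots: tuple = tuple(float(k) for k in range(0, 49, 3))
    boundary: float | None = 54.0

    def __post_init__(self):
        ks = tuple(float(k) for k in self.knots)
        object.__setattr__(self, "knots", ks)
        if len(ks) < 2:
            raise ValueError("need at least two knots")
        if ks[0] != 0.0:
            raise ValueError("first knot must be 0")
        if not np.all(np.diff(ks) > 0):
            raise ValueError("knots must be strictly increasing")
        if self.boundary is not None and self.boundary <= ks[-1]:
            raise ValueError("boundary knot must exceed the last knot")

    @property
    def all_knots(self) -> np.ndarray:
        """Reporting knots plus the boundary knot, as an array."""
        ks = list(self.knots)
        if self.boundary is not None:
            ks.append(self.boundary)
        return np.asarray(ks, dtype=float)

    @property
    def n_basis(self) -> int:
        return len(self.all_knots)

    @property
    def max_time(self) -> float:
        return float(self.all_knots[-1])


def bspline_basis(t, grid: KnotGrid) -> np.ndarray:
    """Evaluate the linear B-spline (tent) basis at times ``t``.

    Returns an array of shape ``(len(t), n_basis)`` (or ``(n_basis,)`` for
    scalar ``t``).  Each row is non-negative, has at most two non-zero
    entries and sums to one (partition of unity on the grid range).
    """
    knots = grid.all_knots
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < knots[0] - 1e-9) or np.any(t_arr > knots[-1] + 1e-9):
        raise ValueError(
            f"time outside knot range [{knots[0]}, {knots[-1]}]: {t_arr}"
        )
    t_arr = np.clip(t_arr, knots[0], knots[-1])
    idx = np.clip(np.searchsorted(knots, t_arr, side="right") - 1, 0, len(knots) - 2)
    left, right = knots[idx], knots[idx + 1]
    frac = (t_arr - left) / (right - left)
    B = np.zeros((t_arr.size, len(knots)))
    rows = np.arange(t_arr.size)
    B[rows, idx] = 1.0 - frac
    B[rows, idx + 1] += frac
    return B[0] if np.isscalar(t) or np.ndim(t) == 0 else B


@dataclass(frozen=True)
class FitConfig:
    """Convergence and regularisation settings for the ECM fit."""

    max_iter: int = 500
    rel_tol: float = 1e-6          # relative log-likelihood change
    ridge: float = 1e-8            # added to diagonals before inversion
    sigma2_floor: float = 1e-10    # lower bound of the profile search
    sigma2_init_frac: float = 0.25  # initial sigma2 as fraction of var(y)
    profile_every: int = 10        # 1-D profile refresh of sigma2 (EM can
                                   # stall near the sigma2 -> 0 boundary)


@dataclass
class SubjectKnotEstimates:
    """A subject's HSDS at the reporting knots (BLUP: beta + u_hat)."""

    subject_id: object
    knots: np.ndarray
    values: np.ndarray
    n_observations: int


@dataclass
class BrokenStickModel:
    """Fitted broken-stick model parameters over the knot grid."""

    grid: KnotGrid
    beta: np.ndarray          # fixed effects, one per basis knot
    omega: np.ndarray         # between-subject covariance (n_basis x n_basis)
    sigma2: float             # residual variance (SDS^2)
    converged: bool
    n_subjects: int
    n_observations: int
    log_likelihood: float
    n_iter: int = 0
    loglik_path: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        k = self.grid.n_basis
        if self.beta.shape != (k,) or self.omega.shape != (k, k):
            raise ValueError("beta/omega shape inconsistent with knot grid")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    # -- persistence ---------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "knots": list(self.grid.knots),
            "boundary": self.grid.boundary,
            "beta": self.beta.tolist(),
            "omega": self.omega.tolist(),
            "sigma2": self.sigma2,
            "converged": bool(self.converged),
            "n_subjects": int(self.n_subjects),
            "n_observations": int(self.n_observations),
            "log_likelihood": float(self.log_likelihood),
            "n_iter": int(self.n_iter),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "BrokenStickModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        grid = KnotGrid(tuple(payload["knots"]), payload["boundary"])
        return cls(
            grid=grid,
            beta=np.array(payload["beta"]),
            omega=np.array(payload["omega"]),
            sigma2=payload["sigma2"],
            converged=payload["converged"],
            n_subjects=payload["n_subjects"],
            n_observations=payload["n_observations"],
            log_likelihood=payload["log_likelihood"],
            n_iter=payload.get("n_iter", 0),
        )


# ---------------------------------------------------------------------------
# fitting


def _group_by_size(records: pd.DataFrame, grid: KnotGrid):
    """Bucket subjects by number of observations for batched linear algebra.

    Returns a list of (subject_ids, Z, y) with Z of shape (m, n, K) and y of
    shape (m, n) for each distinct per-subject observation count n.
    """
    buckets: dict[int, list] = {}
    for sid, sub in records.groupby("subject_id", sort=True):
        t = sub["months_on_treatment"].to_numpy(dtype=float)
        y = sub["hsds"].to_numpy(dtype=float)
        order = np.argsort(t, kind="stable")
        t, y = t[order], y[order]
        Z = bspline_basis(t, grid)
        buckets.setdefault(len(t), []).append((sid, Z, y))
    out = []
    for n, items in sorted(buckets.items()):
        ids = [it[0] for it in items]
        Z = np.stack([it[1] for it in items])
        Y = np.stack([it[2] for it in items])
        out.append((ids, Z, Y))
    return out


def _loglik_terms(buckets, beta, omega, sigma2, ridge):
    """Marginal log-likelihood plus per-bucket V^{-1} and residuals."""
    ll = 0.0
    cache = []
    for ids, Z, Y in buckets:
        m, n, _ = Z.shape
        V = np.einsum("ank,kl,aml->anm", Z, omega, Z)
        V[:, np.arange(n), np.arange(n)] += sigma2 + ridge
        Vinv = np.linalg.inv(V)
        sign, logdet = np.linalg.slogdet(V)
        R = Y - Z @ beta
        quad = np.einsum("an,anm,am->a", R, Vinv, R)
        ll += -0.5 * float(np.sum(n * np.log(2 * np.pi) + logdet + quad))
        cache.append((ids, Z, Y, R, Vinv))
    return ll, cache


def _loglik_only(buckets, beta, omega, sigma2, ridge):
    ll = 0.0
    for _, Z, Y in buckets:
        m, n, _ = Z.shape
        V = np.einsum("ank,kl,aml->anm", Z, omega, Z)
        V[:, np.arange(n), np.arange(n)] += sigma2 + ridge
        sign, logdet = np.linalg.slogdet(V)
        R = Y - Z @ beta
        quad = np.einsum("an,anm,am->a", R, np.linalg.inv(V), R)
        ll += -0.5 * float(np.sum(n * np.log(2 * np.pi) + logdet + quad))
    return ll


def _gls_beta(buckets, omega, sigma2, ridge, K):
    A = np.zeros((K, K))
    b = np.zeros(K)
    for _, Z, Y in buckets:
        n = Z.shape[1]
        V = np.einsum("ank,kl,aml->anm", Z, omega, Z)
        V[:, np.arange(n), np.arange(n)] += sigma2 + ridge
        Vinv = np.linalg.inv(V)
        ZtVinv = np.einsum("ank,anm->akm", Z, Vinv)
        A += np.einsum("akm,amj->kj", ZtVinv, Z)
        b += np.einsum("akm,am->k", ZtVinv, Y)
    return np.linalg.solve(A + ridge * np.eye(K), b), A


def fit(records: pd.DataFrame, grid: KnotGrid | None = None,
        config: FitConfig | None = None) -> BrokenStickModel:
    """Fit the broken-stick model to long-format records.

    ``records`` needs columns ``subject_id``, ``months_on_treatment`` and
    ``hsds``; every subject must have at least two observations inside the
    grid range (sparse subjects stay in deliberately -- dropping them would
    bias the population estimates).
    """
    grid = grid or KnotGrid()
    config = config or FitConfig()
    counts = records.groupby("subject_id")["hsds"].size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"subjects with fewer than 2 observations: {bad[:5]}")

    buckets = _group_by_size(records, grid)
    K = grid.n_basis
    m_subjects = int(counts.size)
    n_obs = int(counts.sum())
    var_y = float(np.var(records["hsds"].to_numpy(dtype=float)))
    var_y = max(var_y, 1e-4)

    omega = np.eye(K) * var_y
    sigma2 = config.sigma2_init_frac * var_y
    beta, _ = _gls_beta(buckets, omega, sigma2, config.ridge, K)

    from scipy.optimize import minimize_scalar

    ll_path = []
    ll_old = -np.inf
    converged = False
    prev = None
    alpha = 1.0
    it = 0
    for it in range(1, config.max_iter + 1):
        # E-step at current (beta, omega, sigma2); joint EM M-step for
        # (omega, sigma2) -- monotone in the marginal likelihood
        _, cache = _loglik_terms(buckets, beta, omega, sigma2, config.ridge)
        S_uu = np.zeros((K, K))
        sse = 0.0
        for ids, Z, Y, R, Vinv in cache:
            OZt = np.einsum("kl,anl->akn", omega, Z)          # (m, K, n)
            # conditional covariance: Omega - OZt Vinv (OZt)'
            C = omega[None, :, :] - np.einsum("akn,anm,ajm->akj", OZt, Vinv, OZt)
            U = np.einsum("akn,anm,am->ak", OZt, Vinv, R)     # u_hat
            S_uu += np.einsum("ak,aj->kj", U, U) + C.sum(axis=0)
            eps = R - np.einsum("ank,ak->an", Z, U)
            sse += float(np.einsum("an,an->", eps, eps))
            sse += float(np.einsum("ank,akj,anj->", Z, C, Z))
        omega = S_uu / m_subjects
        omega = 0.5 * (omega + omega.T)
        sigma2 = max(sse / n_obs, config.sigma2_floor)

        # periodic 1-D profile of sigma2 given (beta, omega)
        if it % config.profile_every == 0 or it == 1:
            lo, hi = np.log(config.sigma2_floor), np.log(4.0 * var_y)
            res = minimize_scalar(
                lambda ls: -_loglik_only(buckets, beta, omega, np.exp(ls),
                                         config.ridge),
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-3},
            )
            cand = float(np.exp(res.x))
            if (_loglik_only(buckets, beta, omega, cand, config.ridge)
                    >= _loglik_only(buckets, beta, omega, sigma2, config.ridge)):
                sigma2 = cand

        # GLS update of beta given (omega, sigma2)
        beta, _ = _gls_beta(buckets, omega, sigma2, config.ridge, K)

        ll = _loglik_only(buckets, beta, omega, sigma2, config.ridge)

        # over-relaxation: extrapolate along the last EM step, keep only if
        # the likelihood improves (EM alone creeps on flat directions)
        if prev is not None and alpha >= 1.0:
            beta_t = beta + alpha * (beta - prev[0])
            omega_t = omega + alpha * (omega - prev[1])
            omega_t = 0.5 * (omega_t + omega_t.T)
            sigma2_t = float(np.exp(
                np.log(sigma2) + alpha * (np.log(sigma2) - np.log(prev[2]))))
            ok = sigma2_t >= config.sigma2_floor
            if ok:
                try:
                    np.linalg.cholesky(omega_t + config.ridge * np.eye(K))
                except np.linalg.LinAlgError:
                    ok = False
            if ok:
                ll_t = _loglik_only(buckets, beta_t, omega_t, sigma2_t, config.ridge)
                if ll_t > ll:
                    beta, omega, sigma2, ll = beta_t, omega_t, sigma2_t, ll_t
                    alpha = min(alpha * 2.0, 512.0)
                else:
                    alpha = 1.0
        prev = (beta.copy(), omega.copy(), sigma2)

        ll_path.append(ll)
        if np.isfinite(ll_old) and abs(ll - ll_old) < config.rel_tol * (abs(ll_old) + 1.0):
            converged = True
            ll_old = ll
            break
        ll_old = ll

    if not converged:
        warnings.warn(
            f"broken-stick fit did not converge in {config.max_iter} iterations",
            RuntimeWarning,
        )

    return BrokenStickModel(
        grid=grid, beta=beta, omega=omega, sigma2=sigma2,
        converged=converged, n_subjects=m_subjects, n_observations=n_obs,
        log_likelihood=float(ll_old), n_iter=it,
        loglik_path=np.asarray(ll_path),
    )


# ---------------------------------------------------------------------------
# prediction


def _blup(model: BrokenStickModel, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """BLUP of the subject's knot values given observations (t, y)."""
    if len(t) == 0:
        return model.beta.copy()
    Z = np.atleast_2d(bspline_basis(t, model.grid))
    V = Z @ model.omega @ Z.T + model.sigma2 * np.eye(len(t))
    V[np.diag_indices_from(V)] += 1e-10
    r = y - Z @ model.beta
    u = model.omega @ Z.T @ np.linalg.solve(V, r)
    return model.beta + u


def predict_subject(model: BrokenStickModel, records: pd.DataFrame,
                    subject_id=None) -> SubjectKnotEstimates:
    """Estimate one subject's HSDS at the reporting knots.

    ``records`` holds that subject's observations (columns
    ``months_on_treatment`` and ``hsds``).  With no observations the
    estimate is the population mean curve ``beta``.
    """
    t = records["months_on_treatment"].to_numpy(dtype=float)
    y = records["hsds"].to_numpy(dtype=float)
    est = _blup(model, t, y)
    n_report = len(model.grid.knots)
    if subject_id is None and "subject_id" in records.columns and len(records):
        subject_id = records["subject_id"].iloc[0]
    return SubjectKnotEstimates(
        subject_id=subject_id,
        knots=np.asarray(model.grid.knots),
        values=est[:n_report],
        n_observations=len(t),
    )


def predict_all(model: BrokenStickModel, records: pd.DataFrame) -> list[SubjectKnotEstimates]:
    """Per-subject knot estimates for every subject in ``records``."""
    return [
        predict_subject(model, sub, subject_id=sid)
        for sid, sub in records.groupby("subject_id", sort=True)
    ]


def residuals(model: BrokenStickModel, records: pd.DataFrame) -> pd.Series:
    """Observed minus subject-level fitted HSDS, aligned to ``records``.

    The fitted value at an observation time interpolates the subject's
    BLUP knot values with the same linear basis used in the fit.
    """
    out = pd.Series(index=records.index, dtype=float)
    for sid, sub in records.groupby("subject_id", sort=False):
        t = sub["months_on_treatment"].to_numpy(dtype=float)
        y = sub["hsds"].to_numpy(dtype=float)
        est = _blup(model, t, y)
        Z = np.atleast_2d(bspline_basis(t, model.grid))
        out.loc[sub.index] = y - Z @ est
    return out
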