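"""Height <-> HSDS conversion through LMS growth-reference tables.

The LMS method summarises an age- and sex-specific reference distribution of
height by three parameters: the Box-Cox power ``L`` (skewness), the median
``M`` (cm) and the coefficient of variation ``S``.  A measurement ``x`` at a
tabulated age converts to a standard deviation score (SDS, z-score) via

    z = ((x / M)**L - 1) / (L * S)        (L != 0)
    z = ln(x / M) / S                     (L == 0)

and back via the inverse transform.  Between tabulated ages L, M and S are
interpolated linearly; no extrapolation beyond the table is performed.

Two bundled tables are provided: a synthetic WHO-style height-for-age table
(realistic medians and SDs for ages 2-21 y, built from standard growth-chart
anchor values because the genuine reference tables are not redistributed
here) and a tiny constant-parameter table for exercising the arithmetic in
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "LMSRecord",
    "GrowthReference",
    "ReferenceRangeError",
    "hsds_from_height",
    "height_from_hsds",
    "cm_per_sds",
    "load_reference_csv",
    "load_who_style_reference",
    "synthetic_reference",
]

_SEX_ALIASES = {
    "f": "F", "female": "F", "girl": "F", "girls": "F",
    "m": "M", "male": "M", "boy": "M", "boys": "M",
}


class ReferenceRangeError(ValueError):
    """Raised when an age falls outside the tabulated reference range."""


def _norm_sex(sex: str) -> str:
    try:
        return _SEX_ALIASES[str(sex).strip().lower()]
    except KeyError:
        raise ValueError(f"unknown sex code: {sex!r} (expected F/M)") from None


@dataclass(frozen=True)
class LMSRecord:
    """One row of an LMS table: sex, decimal age and the L, M, S triple."""

    sex: str
    age: float
    L: float
    M: float
    S: float

    def __post_init__(self):
        object.__setattr__(self, "sex", _norm_sex(self.sex))
        if self.M <= 0 or self.S <= 0:
            raise ValueError("LMS record requires M > 0 and S > 0")
        if self.age < 0:
            raise ValueError("LMS record requires age >= 0")


@dataclass
class GrowthReference:
    """An LMS table for both sexes with linear age interpolation.

    Parameters
    ----------
    table
        DataFrame with columns ``sex`` ("F"/"M"), ``age_years``, ``L``,
        ``M``, ``S``.  Within each sex, ages must be strictly increasing
        with no gap larger than one year.
    name
        Free-text label identifying the reference edition.
    """

    table: pd.DataFrame
    name: str = "unnamed"
    _by_sex: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        required = {"sex", "age_years", "L", "M", "S"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"reference table missing columns: {sorted(missing)}")
        tab = self.table.copy()
        tab["sex"] = tab["sex"].map(_norm_sex)
        for sex, sub in tab.groupby("sex"):
            ages = sub["age_years"].to_numpy(dtype=float)
            if not np.all(np.diff(ages) > 0):
                raise ValueError(f"ages for sex {sex} must be strictly increasing")
            if np.any(np.diff(ages) > 1.0 + 1e-9):
                raise ValueError(f"age gaps for sex {sex} exceed one year")
            if np.any(sub["M"].to_numpy() <= 0) or np.any(sub["S"].to_numpy() <= 0):
                raise ValueError("M and S must be positive")
            self._by_sex[sex] = {
                "age": ages,
                "L": sub["L"].to_numpy(dtype=float),
                "M": sub["M"].to_numpy(dtype=float),
                "S": sub["S"].to_numpy(dtype=float),
            }
        self.table = tab

    @property
    def age_range(self) -> tuple[float, float]:
        lo = max(v["age"][0] for v in self._by_sex.values())
        hi = min(v["age"][-1] for v in self._by_sex.values())
        return (lo, hi)

    def lms(self, age, sex: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Interpolated (L, M, S) at decimal ``age`` for ``sex``."""
        sex = _norm_sex(sex)
        if sex not in self._by_sex:
            raise ValueError(f"reference {self.name!r} has no table for sex {sex}")
        cols = self._by_sex[sex]
        age = np.asarray(age, dtype=float)
        if np.any(age < cols["age"][0] - 1e-9) or np.any(age > cols["age"][-1] + 1e-9):
            raise ReferenceRangeError(
                f"age {age} outside reference range "
                f"[{cols['age'][0]}, {cols['age'][-1]}] for sex {sex}"
            )
        L = np.interp(age, cols["age"], cols["L"])
        M = np.interp(age, cols["age"], cols["M"])
        S = np.interp(age, cols["age"], cols["S"])
        return L, M, S


def _lms_z(x, L, M, S):
    x, L, M, S = np.broadcast_arrays(x, L, M, S)
    z = np.empty_like(x, dtype=float)
    nz = np.abs(L) > 1e-12
    z[nz] = ((x[nz] / M[nz]) ** L[nz] - 1.0) / (L[nz] * S[nz])
    z[~nz] = np.log(x[~nz] / M[~nz]) / S[~nz]
    return z


def _lms_x(z, L, M, S):
    z, L, M, S = np.broadcast_arrays(np.asarray(z, float), L, M, S)
    x = np.empty_like(z, dtype=float)
    nz = np.abs(L) > 1e-12
    base = 1.0 + L[nz] * S[nz] * z[nz]
    if np.any(base <= 0):
        raise ValueError("1 + L*S*z must be positive to invert the LMS transform")
    x[nz] = M[nz] * base ** (1.0 / L[nz])
    x[~nz] = M[~nz] * np.exp(S[~nz] * z[~nz])
    return x


def hsds_from_height(height, age, sex: str, ref: GrowthReference):
    """Height (cm) at decimal ``age`` -> height SDS against ``ref``.

    Accepts scalars or broadcastable arrays; returns a float for scalar
    input.
    """
    height = np.asarray(height, dtype=float)
    if np.any(height <= 0):
        raise ValueError("height must be positive")
    L, M, S = ref.lms(age, sex)
    z = _lms_z(height, L, M, S)
    return float(z) if z.ndim == 0 else z


def height_from_hsds(z, age, sex: str, ref: GrowthReference):
    """Height SDS -> height in cm (inverse LMS transform)."""
    L, M, S = ref.lms(age, sex)
    x = _lms_x(z, L, M, S)
    return float(x) if x.ndim == 0 else x


def cm_per_sds(age, sex_mode: str, ref: GrowthReference):
    """Local height scale of the reference: cm corresponding to 1 SDS.

    Evaluated as the derivative of the SDS->height transform at the median
    (z = 0), which equals ``M * S`` for every ``L``.  ``sex_mode`` is
    ``"female"``, ``"male"`` or ``"averaged"`` (mean of the two sexes).
    """
    mode = str(sex_mode).strip().lower()
    if mode in ("averaged", "average", "mean"):
        vals = []
        for sex in ("F", "M"):
            _, M, S = ref.lms(age, sex)
            vals.append(M * S)
        out = np.mean(vals, axis=0)
    else:
        _, M, S = ref.lms(age, _norm_sex(mode))
        out = M * S
    out = np.asarray(out, dtype=float)
    return float(out) if out.ndim == 0 else out


def load_reference_csv(path, name: str | None = None) -> GrowthReference:
    """Read an LMS table from CSV (columns sex, age_years, L, M, S)."""
    tab = pd.read_csv(path)
    return GrowthReference(tab, name=name or str(path))


def load_who_style_reference() -> GrowthReference:
    """Bundled synthetic WHO-style height-for-age reference, ages 2-21 y.

    The table reproduces the familiar shape of the WHO height-for-age
    charts (L = 1 throughout, smooth medians, SD rising from ~3.5 cm at
    age 2 to ~7-8 cm in puberty); it is generated from anchor values, not
    copied from the published reference, and is intended for realistic
    simulation and examples.
    """
    src = resources.files("growthmatch.data") / "lms_height_synthetic_who_style.csv"
    with resources.as_file(src) as p:
        return load_reference_csv(p, name="synthetic-who-style")


def synthetic_reference(
    ages=tuple(range(0, 22)), m0: float = 85.0, slope: float = 5.0, s: float = 0.045
) -> GrowthReference:
    """Tiny constant-L synthetic table (L=1, M linear in age, constant S).

    Useful in unit tests where closed-form expectations are wanted:
    1 SDS corresponds to exactly ``M(age) * s`` cm.
    """
    rows = []
    for sex in ("F", "M"):
        for a in ages:
            rows.append({"sex": sex, "age_years": float(a), "L": 1.0,
                         "M": m0 + slope * a, "S": s})
    return GrowthReference(pd.DataFrame(rows), name="synthetic-linear")
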