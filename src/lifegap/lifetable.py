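"""Period life tables: reading, old-age extrapolation, and life expectancy.

Official abbreviated period life tables stop at age 90.  Life
expectancy requires a complete table, so one-year death probabilities
``qx`` are extrapolated from the observed old-age pattern up to a
closure age of 112, at which death is certain (``q(112) = 1``).

The default extrapolation fits a Gompertz (log-linear) hazard over ages
75-90 by least squares; a Kannisto logistic hazard, which levels off at
very old ages, is available as an alternative.  Death probabilities and
hazards are linked by ``m(x) = -ln(1 - q(x))`` on single-year age
intervals ``[x, x+1)``.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable

import numpy as np
import pandas as pd

CLOSURE_AGE = 112
MAX_ABBREV_AGE = 90
DEFAULT_FIT_AGES = range(75, 91)

LIFETABLE_COLUMNS = ["period_start", "period_end", "sex", "age", "qx"]
SEXES = ("female", "male")


class LifeTableError(ValueError):
    """Malformed or inconsistent life-table input."""


def _validate_qx_block(age: np.ndarray, qx: np.ndarray, label: str) -> None:
    if len(age) == 0:
        raise LifeTableError(f"{label}: empty table")
    expected = np.arange(age.min(), age.max() + 1)
    if age.min() != 0:
        raise LifeTableError(f"{label}: ages must start at 0, got {age.min()}")
    missing = np.setdiff1d(expected, age)
    if missing.size:
        raise LifeTableError(f"{label}: missing ages {missing.tolist()}")
    if len(age) != len(expected):
        dup = age[pd.Index(age).duplicated()]
        raise LifeTableError(f"{label}: duplicated ages {np.unique(dup).tolist()}")
    if np.any((qx <= 0) | (qx >= 1)):
        raise LifeTableError(f"{label}: qx must lie strictly in (0, 1)")


def read_life_table(path, *, sep: str = ",") -> pd.DataFrame:
    """Read an abbreviated life table from delimited text.

    Expects columns ``period_start, period_end, sex, age, qx`` with one
    row per period x sex x age, ages contiguous from 0.  Gaps,
    duplicates and out-of-range ``qx`` raise :class:`LifeTableError`
    naming the offending ages.
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing_cols = set(LIFETABLE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise LifeTableError(f"missing columns: {sorted(missing_cols)}")
    df = df[LIFETABLE_COLUMNS].copy()
    df["age"] = df["age"].astype(int)
    for (p0, p1, sex), block in df.groupby(["period_start", "period_end", "sex"]):
        _validate_qx_block(
            block["age"].to_numpy(),
            block["qx"].to_numpy(),
            f"period {p0}-{p1} sex {sex}",
        )
    return df.sort_values(["period_start", "sex", "age"]).reset_index(drop=True)


def write_life_table(table: pd.DataFrame, path, *, sep: str = ",") -> None:
    """Write a life table as delimited text (decimal point, UTF-8)."""
    table.to_csv(path, sep=sep, index=False)


def hazard_from_qx(qx):
    """Cumulative hazard over a one-year interval: m(x) = -ln(1 - qx)."""
    return -np.log1p(-np.asarray(qx, dtype=float))


def qx_from_hazard(m):
    """One-year death probability from the interval hazard."""
    return -np.expm1(-np.asarray(m, dtype=float))


def extrapolate(
    qx: pd.Series,
    *,
    fit_ages: Iterable[int] = DEFAULT_FIT_AGES,
    closure_age: int = CLOSURE_AGE,
    form: str = "gompertz",
) -> pd.Series:
    """Extend observed ``qx`` (ages 0..90) to the closure age.

    The interval hazard ``m(x) = -ln(1-qx)`` is fitted over ``fit_ages``
    and extrapolated to ages ``max_obs+1 .. closure_age-1``;
    ``q(closure_age)`` is set to 1 exactly.

    form = "gompertz"
        least-squares line through ``log m(x)``; exact when the
        underlying hazard is Gompertz(-Makeham with negligible
        background term at old ages).
    form = "kannisto"
        least-squares line through ``logit m(x)``, i.e. the logistic
        hazard ``m = a e^{bx} / (1 + a e^{bx})`` that plateaus below 1.

    A non-increasing fitted old-age hazard (slope < 0) triggers a
    warning and a constant-hazard fallback at the last observed value.
    """
    qx = pd.Series(qx).sort_index()
    ages = qx.index.to_numpy()
    _validate_qx_block(ages, qx.to_numpy(), "extrapolation input")
    fit_ages = np.asarray(sorted(fit_ages))
    if fit_ages.size < 5:
        raise LifeTableError("need at least 5 ages to fit the old-age hazard")
    if np.setdiff1d(fit_ages, ages).size:
        raise LifeTableError("fit_ages must be observed ages")
    max_obs = int(ages.max())
    if closure_age <= max_obs + 1:
        raise LifeTableError("closure age must exceed the observed range")

    m_obs = hazard_from_qx(qx.loc[fit_ages])
    if form == "gompertz":
        y = np.log(m_obs)
    elif form == "kannisto":
        y = np.log(m_obs) - np.log1p(-np.clip(m_obs, None, 1 - 1e-12))
    else:
        raise ValueError(f"unknown extrapolation form {form!r}")
    slope, intercept = np.polyfit(fit_ages, y, 1)

    new_ages = np.arange(max_obs + 1, closure_age)
    if slope < 0:
        warnings.warn(
            "fitted old-age hazard is declining; holding the last observed "
            "hazard constant instead",
            stacklevel=2,
        )
        m_new = np.full(new_ages.shape, hazard_from_qx(qx.loc[max_obs]))
    else:
        eta = intercept + slope * new_ages
        if form == "gompertz":
            m_new = np.exp(eta)
        else:
            m_new = 1.0 / (1.0 + np.exp(-eta))
    q_new = np.clip(qx_from_hazard(m_new), None, 1.0 - 1e-12)
    q_new = np.maximum.accumulate(np.maximum(q_new, qx.loc[max_obs]))

    out = pd.concat(
        [
            qx,
            pd.Series(q_new, index=new_ages),
            pd.Series([1.0], index=[closure_age]),
        ]
    )
    out.index.name = "age"
    out.name = "qx"
    return out


def complete_table(qx: pd.Series, *, ax: float | pd.Series = 0.5) -> pd.DataFrame:
    """Build a complete life table from death probabilities.

    Parameters
    ----------
    qx
        One-year death probabilities indexed by age 0..closure, with
        ``q`` at the last age equal to 1.
    ax
        Average fraction of the year lived by those dying within it
        (scalar or per-age), 0.5 by default.

    Returns
    -------
    DataFrame indexed by age with columns ``qx``, ``lx`` (survivors at
    exact age x, l0 = 1), ``Lx`` (person-years lived in [x, x+1)) and
    ``ex`` (remaining life expectancy at exact age x).
    """
    qx = pd.Series(qx).sort_index().astype(float)
    ages = qx.index.to_numpy()
    if ages[0] != 0 or np.any(np.diff(ages) != 1):
        raise LifeTableError("qx must cover contiguous ages from 0")
    if np.any((qx < 0) | (qx > 1)):
        raise LifeTableError("qx must lie in [0, 1]")
    if qx.iloc[-1] != 1.0:
        raise LifeTableError("the last age must have qx = 1 (table closure)")
    a = np.broadcast_to(np.asarray(ax, dtype=float), ages.shape)

    surv = np.concatenate([[1.0], np.cumprod(1.0 - qx.to_numpy())])
    lx, lx_next = surv[:-1], surv[1:]
    Lx = lx_next + a * (lx - lx_next)
    Tx = np.cumsum(Lx[::-1])[::-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        ex = np.where(lx > 0, Tx / np.where(lx > 0, lx, 1.0), 0.0)
    return pd.DataFrame({"qx": qx.to_numpy(), "lx": lx, "Lx": Lx, "ex": ex}, index=qx.index)


def life_expectancy(table: pd.DataFrame, age: int = 0) -> float:
    """Remaining life expectancy at an exact age from a complete table."""
    return float(table.loc[age, "ex"])


def prob_death_before(table: pd.DataFrame, age: int = 65) -> float:
    """Probability of dying before an exact age (1 - lx)."""
    return 1.0 - float(table.loc[age, "lx"])


def pooled_baseline_qx(tables: pd.DataFrame, window: tuple[int, int]) -> pd.DataFrame:
    """Average yearly ``qx`` over a calendar window, per sex and age.

    Implements the pooled-period baseline: the unweighted mean of age-
    and sex-specific death probabilities across the window's yearly
    tables.  Returns a long frame with columns ``sex, age, qx``.
    """
    lo, hi = window
    sel = tables[(tables["period_start"] >= lo) & (tables["period_end"] <= hi)]
    if sel.empty:
        raise LifeTableError(f"no life tables inside window {lo}-{hi}")
    out = sel.groupby(["sex", "age"], as_index=False)["qx"].mean()
    return out.sort_values(["sex", "age"]).reset_index(drop=True)


def validate_extrapolation(
    extrapolated: pd.DataFrame, reference: pd.DataFrame
) -> dict:
    """Compare an extrapolated complete table against a reference table.

    Returns the absolute deviation of life expectancy at birth, at 65,
    and the maximum absolute per-age deviation of ``ex`` over the ages
    shared by both tables.
    """
    shared = extrapolated.index.intersection(reference.index)
    if shared.empty:
        raise LifeTableError("tables share no ages")
    dev = (extrapolated.loc[shared, "ex"] - reference.loc[shared, "ex"]).abs()
    return {
        "e0_deviation": abs(
            life_expectancy(extrapolated, 0) - life_expectancy(reference, 0)
        ),
        "e65_deviation": abs(
            life_expectancy(extrapolated, 65) - life_expectancy(reference, 65)
        ),
        "max_ex_deviation": float(dev.max()),
    }
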