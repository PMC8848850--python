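"""Synthetic panels and synthetic official life tables.

The restricted household panel behind the original analyses (annual
waves 1992-2016, ~83,000 adults, ~5% deaths, income observed every
wave) cannot be redistributed, and neither can the official period
life tables.  This module generates both with the statistical
structure the pipeline assumes:

* mortality follows a Gompertz-Makeham hazard
  ``h(age) = makeham_c + gompertz_a * exp(gompertz_b * age)``,
  scaled per sex, per calendar year (a secular improvement factor) and
  per income group x sex x age band through effect-coded true log
  hazard ratios;
* log equivalised income evolves as a stationary AR(1) around a
  lognormal marginal, so income-group membership is time-varying;
* entry into the panel is staggered over the observation window and
  exit is death, geometric attrition, or the end of the window
  (attrition can optionally depend on current health, i.e. on the
  person's hazard multiplier);
* every person owns a dedicated random stream spawned from the global
  seed, so results do not depend on iteration order.

The accompanying life tables are computed from the same hazard (exact
integration over one-year age intervals), which makes generating-truth
life expectancies available in closed form for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .income import DEFAULT_THRESHOLDS, INCOME_GROUPS, group_shares_lognormal
from .lifetable import LIFETABLE_COLUMNS
from .survival import AGE_BANDS

PANEL_COLUMNS = [
    "person_id",
    "sex",
    "birth_year",
    "wave_year",
    "hh_net_income",
    "n_adults",
    "n_children",
    "died_this_wave",
    "death_age",
]

#: Risk of the lowest vs highest income group used to calibrate the
#: default generator, per (sex, age band).
DEFAULT_G1_G5_RATIOS = {
    ("female", "up_to_50"): 2.2,
    ("male", "up_to_50"): 2.4,
    ("female", "fifty_one_plus"): 1.5,
    ("male", "fifty_one_plus"): 1.9,
}

#: Monotone decrease of log risk across groups G1..G5 (scaled so that
#: the G1-G5 log difference equals log of the target ratio).
_HR_PROFILE = np.array([1.0, 0.55, 0.3, 0.12, 0.0])


def centered_log_hr(ratio: float, shares, profile=_HR_PROFILE) -> np.ndarray:
    """Effect-coded true log hazard ratios for the five income groups.

    ``ratio`` is the desired G1/G5 hazard ratio; ``shares`` the group
    population shares used for the weighted sum-to-zero centring.  The
    returned vector ``v`` satisfies ``sum(shares * v) == 0`` and
    ``v[0] - v[4] == log(ratio)``.
    """
    s = np.asarray([shares[g] for g in INCOME_GROUPS] if isinstance(shares, dict) else shares)
    raw = np.log(ratio) * np.asarray(profile)
    return raw - float(s @ raw) / s.sum()


def default_true_log_hr(sigma: float, ratios=None, thresholds=DEFAULT_THRESHOLDS) -> dict:
    """Centred true log-HR vectors per (sex, age band) for given targets."""
    shares = group_shares_lognormal(sigma, thresholds)
    ratios = ratios or DEFAULT_G1_G5_RATIOS
    return {key: centered_log_hr(r, shares) for key, r in ratios.items()}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic panel and life-table generator.

    Hazard parameters are per year; ``gompertz_a`` and ``makeham_c``
    describe the female baseline, men carry an extra log-hazard
    ``male_log_excess``.  ``annual_improvement`` is the secular decline
    of the log hazard per calendar year, anchored at the midpoint of
    the observation window.  ``true_log_hr`` maps (sex, age_band) to a
    length-5 vector of effect-coded log hazard ratios whose
    share-weighted mean is zero.
    """

    n_persons: int = 83_287
    period_start: int = 1992
    period_end: int = 2016
    gompertz_a: float = 7.922e-6
    gompertz_b: float = 0.11
    makeham_c: float = 2.0e-4
    male_log_excess: float = 0.5956
    annual_improvement: float = 0.016
    true_log_hr: dict = field(default_factory=dict)
    attrition_rate: float = 0.075
    health_dependent_attrition: bool = False
    income_lognormal_mu: float = float(np.log(1495.0))
    income_lognormal_sigma: float = 0.45
    income_ar1_rho: float = 0.92
    entry_age_min: int = 17
    entry_age_max: int = 90
    entry_age_shape1: float = 1.0
    entry_age_shape2: float = 2.45
    staggered_entry: bool = True
    thresholds: tuple = DEFAULT_THRESHOLDS
    seed: int = 0

    def __post_init__(self):
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        if self.period_end < self.period_start:
            raise ValueError("period_end must be >= period_start")
        if self.gompertz_a < 0 or self.gompertz_b < 0 or self.makeham_c < 0:
            raise ValueError("hazard parameters must be non-negative")
        if not 0 <= self.attrition_rate < 1:
            raise ValueError("attrition_rate must lie in [0, 1)")
        if self.income_lognormal_sigma <= 0:
            raise ValueError("income_lognormal_sigma must be positive")
        if not 0 <= self.income_ar1_rho < 1:
            raise ValueError("income_ar1_rho must lie in [0, 1)")
        if not self.true_log_hr:
            self.true_log_hr = default_true_log_hr(
                self.income_lognormal_sigma, thresholds=self.thresholds
            )
        shares = self.group_shares()
        s = np.array([shares[g] for g in INCOME_GROUPS])
        for key, v in self.true_log_hr.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (len(INCOME_GROUPS),):
                raise ValueError(f"true_log_hr[{key}] must have length 5")
            if abs(s @ v) > 1e-6:
                raise ValueError(
                    f"true_log_hr[{key}] violates the effect-coding convention: "
                    f"share-weighted mean is {s @ v:.3g}, not 0"
                )
            self.true_log_hr[key] = v

    def group_shares(self) -> dict:
        """Stationary income-group shares implied by the income law."""
        return group_shares_lognormal(self.income_lognormal_sigma, self.thresholds)

    @property
    def reference_year(self) -> int:
        """Calendar anchor of the secular mortality improvement."""
        return (self.period_start + self.period_end) // 2

    def log_hr_array(self) -> np.ndarray:
        """true_log_hr as an array indexed [sex, band, group] (female=0)."""
        arr = np.zeros((2, 2, len(INCOME_GROUPS)))
        for si, sex in enumerate(("female", "male")):
            for bi, band in enumerate(AGE_BANDS):
                arr[si, bi] = self.true_log_hr[(sex, band)]
        return arr


def cumulative_hazard_year(config: SimulationConfig, age):
    """Integral of the female baseline hazard over [age, age+1)."""
    a, b, c = config.gompertz_a, config.gompertz_b, config.makeham_c
    age = np.asarray(age, dtype=float)
    if b > 0:
        gomp = a * (np.exp(b * (age + 1)) - np.exp(b * age)) / b
    else:
        gomp = a * np.ones_like(age)
    return c + gomp


def hazard_multiplier(config: SimulationConfig, sex_is_male, year):
    """Sex and calendar-year scaling of the baseline hazard."""
    sexm = np.asarray(sex_is_male, dtype=float)
    yr = np.asarray(year, dtype=float)
    return np.exp(
        config.male_log_excess * sexm
        - config.annual_improvement * (yr - config.reference_year)
    )


def _draw_uniform_blocks(seed: int, n_persons: int, block: int) -> np.ndarray:
    """One fixed-length uniform block per person from spawned streams."""
    children = np.random.SeedSequence(seed).spawn(n_persons)
    out = np.empty((n_persons, block))
    for i, child in enumerate(children):
        out[i] = np.random.Generator(np.random.Philox(child)).random(block)
    return out


def _within_year_death_time(u, H_total, config, age, mult):
    """Exact fraction of the year survived before death, given death.

    Solves ``Lambda(s) = -log(1 - u*q)`` for ``s`` in (0, 1], where
    ``Lambda`` is the person's cumulative hazard from the start of the
    year and ``q = 1 - exp(-H_total)``; Newton iteration from the
    constant-hazard solution (exact already when the Gompertz term
    vanishes).
    """
    a, b, c = config.gompertz_a, config.gompertz_b, config.makeham_c
    q = -np.expm1(-H_total)
    target = -np.log1p(-u * q)
    s = np.clip(target / H_total, 1e-12, 1.0)
    if a > 0 and b > 0:
        eba = np.exp(b * age)
        for _ in range(6):
            Lam = mult * (c * s + a * eba * (np.exp(b * s) - 1.0) / b)
            dLam = mult * (c + a * eba * np.exp(b * s))
            s = np.clip(s - (Lam - target) / dLam, 1e-12, 1.0)
    return s


def simulate_panel(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a person-wave panel.

    Returns a long frame with one row per observed person-wave and the
    columns ``person_id, sex, birth_year, wave_year, hh_net_income,
    n_adults, n_children, died_this_wave, death_age``.  ``death_age``
    is the exact (fractional) age at death, simulation ground truth
    that real panels do not observe; it is NaN for survivors.

    Death times are drawn by inverse transform of the cumulative
    Gompertz-Makeham hazard, piecewise over one-year episodes so the
    person's time-varying income group (and hence hazard multiplier)
    is honoured exactly.  Attrition is geometric per wave and
    independent of future mortality unless
    ``health_dependent_attrition`` is set.
    """
    n = config.n_persons
    years = np.arange(config.period_start, config.period_end + 1)
    W = len(years)
    # per-person uniforms: [sex, entry wave, entry age, comp1, comp2,
    #                       W income innovations, W attrition, W death]
    u = _draw_uniform_blocks(config.seed, n, 5 + 3 * W)
    u_sex, u_entry, u_age, u_c1, u_c2 = (u[:, i] for i in range(5))
    u_inc = u[:, 5 : 5 + W]
    u_att = u[:, 5 + W : 5 + 2 * W]
    u_dth = u[:, 5 + 2 * W : 5 + 3 * W]

    is_male = u_sex < 0.5
    if config.staggered_entry:
        first_wave = years[0] + np.floor(u_entry * W).astype(int)
    else:
        first_wave = np.full(n, years[0])
    entry_age = np.rint(
        config.entry_age_min
        + (config.entry_age_max - config.entry_age_min)
        * beta_dist.ppf(u_age, config.entry_age_shape1, config.entry_age_shape2)
    ).astype(int)
    birth_year = first_wave - entry_age
    n_adults = 1 + (u_c1 < 0.70).astype(int)
    n_children = np.select([u_c2 < 0.62, u_c2 < 0.84], [0, 1], default=2)

    rho = config.income_ar1_rho
    z = norm.ppf(np.clip(u_inc, 1e-12, 1 - 1e-12))
    # stationary AR(1) in standard-normal units, innovated per wave
    zs = np.empty_like(z)
    zs[:, 0] = z[:, 0]
    for w in range(1, W):
        zs[:, w] = rho * zs[:, w - 1] + np.sqrt(1 - rho * rho) * z[:, w]
    equiv_income = np.exp(
        config.income_lognormal_mu + config.income_lognormal_sigma * zs
    )

    divisor = 1.0 + 0.5 * (n_adults - 1) + 0.3 * n_children
    median_true = np.exp(config.income_lognormal_mu)
    thresh = median_true * np.asarray(config.thresholds)
    log_hr = config.log_hr_array()

    alive = np.ones(n, dtype=bool)
    attrited = np.zeros(n, dtype=bool)
    records = []
    for w, year in enumerate(years):
        active = alive & ~attrited & (first_wave <= year)
        if not active.any():
            continue
        idx = np.flatnonzero(active)
        age = year - birth_year[idx]
        e_inc = equiv_income[idx, w]
        group = np.digitize(e_inc, thresh)
        band = (age > 50).astype(int)
        lhr = log_hr[is_male[idx].astype(int), band, group]
        mult = hazard_multiplier(config, is_male[idx], year) * np.exp(lhr)
        H = cumulative_hazard_year(config, age) * mult
        q = -np.expm1(-H)
        dies = u_dth[idx, w] < q
        death_age = np.full(len(idx), np.nan)
        if dies.any():
            d = np.flatnonzero(dies)
            v = u_dth[idx[d], w] / q[d]  # U(0,1) given death
            s = _within_year_death_time(v, H[d], config, age[d], mult[d])
            death_age[d] = age[d] + s
        records.append(
            pd.DataFrame(
                {
                    "person_id": idx,
                    "sex": np.where(is_male[idx], "male", "female"),
                    "birth_year": birth_year[idx],
                    "wave_year": year,
                    "hh_net_income": e_inc * divisor[idx],
                    "n_adults": n_adults[idx],
                    "n_children": n_children[idx],
                    "died_this_wave": dies,
                    "death_age": death_age,
                }
            )
        )
        alive[idx[dies]] = False
        survivors = idx[~dies]
        if config.attrition_rate > 0 and survivors.size:
            p_att = np.full(survivors.size, config.attrition_rate)
            if config.health_dependent_attrition:
                p_att = np.clip(p_att * mult[~dies], 0, 0.95)
            attrited[survivors[u_att[survivors, w] < p_att]] = True

    panel = pd.concat(records, ignore_index=True)
    panel = panel.sort_values(["person_id", "wave_year"], ignore_index=True)
    return panel[PANEL_COLUMNS]


def persons_summary(panel: pd.DataFrame) -> pd.DataFrame:
    """Person-level view: entry/exit waves, death flag and year."""
    g = panel.groupby("person_id")
    out = pd.DataFrame(
        {
            "sex": g["sex"].first(),
            "birth_year": g["birth_year"].first(),
            "first_wave": g["wave_year"].min(),
            "last_wave": g["wave_year"].max(),
            "n_waves": g.size(),
            "died": g["died_this_wave"].any(),
        }
    )
    death_year = panel.loc[panel["died_this_wave"]].set_index("person_id")["wave_year"]
    out["death_year"] = death_year.reindex(out.index)
    return out.reset_index()


def simulate_abbreviated_life_table(
    config: SimulationConfig,
    period: tuple[int, int] | None = None,
    *,
    max_age: int = 90,
) -> pd.DataFrame:
    """Sex-specific one-year death probabilities from the generating hazard.

    ``q(x) = 1 - exp(-integral of the hazard over [x, x+1))`` for ages
    0..``max_age``, averaged over the period's calendar years (secular
    improvement makes yearly tables differ).  ``max_age=90`` mimics the
    abbreviated official tables; larger values (e.g. 111) produce the
    full reference table used to validate the extrapolation.
    """
    if period is None:
        period = (config.period_start, config.period_end)
    lo, hi = period
    ages = np.arange(0, max_age + 1)
    H0 = cumulative_hazard_year(config, ages)
    rows = []
    for sex, sexm in (("female", 0), ("male", 1)):
        factors = hazard_multiplier(config, sexm, np.arange(lo, hi + 1))
        q = np.mean(-np.expm1(-np.outer(factors, H0)), axis=0)
        q = np.clip(q, 1e-12, 1 - 1e-12)
        rows.append(
            pd.DataFrame(
                {
                    "period_start": lo,
                    "period_end": hi,
                    "sex": sex,
                    "age": ages,
                    "qx": q,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)[LIFETABLE_COLUMNS]


def simulate_life_tables(config: SimulationConfig) -> pd.DataFrame:
    """Yearly abbreviated life tables over the whole observation window."""
    tables = [
        simulate_abbreviated_life_table(config, (y, y))
        for y in range(config.period_start, config.period_end + 1)
    ]
    return pd.concat(tables, ignore_index=True)


def write_panel(panel: pd.DataFrame, path, *, sep: str = ",") -> None:
    """Write the panel as delimited text, one row per person-wave."""
    panel.to_csv(path, sep=sep, index=False)


def read_panel(path, *, sep: str = ",") -> pd.DataFrame:
    """Read a person-wave panel written by :func:`write_panel`."""
    panel = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = set(PANEL_COLUMNS) - {"death_age"} - set(panel.columns)
    if missing:
        raise ValueError(f"panel file is missing columns {sorted(missing)}")
    return panel
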