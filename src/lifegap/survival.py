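"""One-year survival episodes and effect-coded relative mortality risks.

The panel is split into one-year episodes on the attained-age time
scale with delayed entry (left truncation at the age of the first
observed wave).  Income-group relative risks are then estimated with a
semi-parametric proportional-hazards model, fitted separately for each
sex x age-band stratum (ages up to 50 at episode start; 51 and above),
with income group as the sole covariate.

Coefficients are reported in *effect coding* against the population
average: the episode-weighted mean of the log hazard ratios within a
stratum is zero, so ``exp(coef)`` is the group's mortality risk
relative to the average risk in the panel rather than to an arbitrary
reference category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _cox
from .income import (
    DEFAULT_THRESHOLDS,
    INCOME_GROUPS,
    EquivalenceScale,
    classify_income_group,
    equivalised_income,
    pooled_median,
)

AGE_BANDS = ("up_to_50", "fifty_one_plus")
AGE_BAND_BOUNDARY = 50  # episodes starting at age <= 50 are "up_to_50"

EPISODE_COLUMNS = [
    "person_id",
    "sex",
    "age_start",
    "age_stop",
    "event",
    "income_group",
    "age_band",
    "calendar_year",
]

RR_COLUMNS = ["income_group", "sex", "age_band", "hr", "se_log_hr", "n_episodes", "n_events"]


class EpisodeError(ValueError):
    """Panel rows cannot be turned into valid survival episodes."""


def build_episodes(
    panel: pd.DataFrame,
    median: float | None = None,
    *,
    thresholds=DEFAULT_THRESHOLDS,
    scale: EquivalenceScale | None = None,
    median_weights=None,
    use_exact_death_age: bool = False,
) -> pd.DataFrame:
    """Turn a person-wave panel into one-year survival episodes.

    Parameters
    ----------
    panel
        Long panel with one row per person-wave and columns
        ``person_id, sex, birth_year, wave_year, hh_net_income,
        n_adults, n_children, died_this_wave``.
    median
        Pooled median net equivalised income used for group
        classification.  Computed from the panel itself when omitted.
    use_exact_death_age
        When the panel carries an exact ``death_age`` column (synthetic
        ground truth), end death episodes at that age instead of the
        integer episode end.  Off by default, matching real panels
        which record only the year of death.

    Returns
    -------
    DataFrame with one episode per person-year: half-open age interval
    ``[age_start, age_stop)``, death indicator, income group measured
    at episode start, age band, calendar year.
    """
    required = {
        "person_id", "sex", "birth_year", "wave_year",
        "hh_net_income", "n_adults", "n_children", "died_this_wave",
    }
    missing = required - set(panel.columns)
    if missing:
        raise EpisodeError(f"panel is missing columns {sorted(missing)}")
    if panel.empty:
        raise EpisodeError("panel is empty")
    if panel.duplicated(["person_id", "wave_year"]).any():
        bad = panel[panel.duplicated(["person_id", "wave_year"])]["person_id"]
        raise EpisodeError(
            f"overlapping episodes for persons {sorted(set(bad))[:5]}"
        )
    if (panel["hh_net_income"] <= 0).any():
        raise EpisodeError("non-positive household income in panel")
    # a death must terminate the person's observation
    last_wave = panel.groupby("person_id")["wave_year"].transform("max")
    premature = panel["died_this_wave"] & (panel["wave_year"] < last_wave)
    if premature.any():
        raise EpisodeError(
            "waves observed after death for persons "
            f"{sorted(set(panel.loc[premature, 'person_id']))[:5]}"
        )

    equiv = equivalised_income(
        panel["hh_net_income"].to_numpy(),
        panel["n_adults"].to_numpy(),
        panel["n_children"].to_numpy(),
        scale,
    )
    if median is None:
        median = pooled_median(equiv, median_weights)

    age_start = (panel["wave_year"] - panel["birth_year"]).to_numpy(dtype=float)
    if np.any(age_start < 0):
        raise EpisodeError("negative age at episode start")
    age_stop = age_start + 1.0
    event = panel["died_this_wave"].to_numpy(dtype=bool)
    if use_exact_death_age and "death_age" in panel.columns:
        exact = panel["death_age"].to_numpy(dtype=float)
        ok = event & np.isfinite(exact)
        age_stop[ok] = np.clip(exact[ok], age_start[ok] + 1e-9, age_start[ok] + 1.0)

    episodes = pd.DataFrame(
        {
            "person_id": panel["person_id"].to_numpy(),
            "sex": panel["sex"].to_numpy(),
            "age_start": age_start,
            "age_stop": age_stop,
            "event": event,
            "income_group": classify_income_group(equiv, median, thresholds),
            "age_band": np.where(
                age_start <= AGE_BAND_BOUNDARY, AGE_BANDS[0], AGE_BANDS[1]
            ),
            "calendar_year": panel["wave_year"].to_numpy(),
        }
    )
    episodes.attrs["median"] = float(median)
    return episodes


@dataclass
class RelativeRiskSet:
    """Hazard ratios per income group x sex x age band, effect-coded.

    ``table`` has one row per combination with columns ``income_group,
    sex, age_band, hr, se_log_hr, n_episodes, n_events``.  Within each
    sex x age band, the episode-weighted mean of ``log(hr)`` is zero,
    so each ``hr`` is relative to the population-average hazard of the
    stratum.  An ``hr`` of NaN marks a group whose estimate is
    undefined (no events in the stratum).
    """

    table: pd.DataFrame
    coding: str = "episode_weighted"
    covariances: dict = field(default_factory=dict, repr=False)

    def hr(self, income_group: str, sex: str, age_band: str) -> float:
        t = self.table
        row = t[
            (t["income_group"] == income_group)
            & (t["sex"] == sex)
            & (t["age_band"] == age_band)
        ]
        if row.empty:
            raise KeyError(f"no estimate for {(income_group, sex, age_band)}")
        return float(row["hr"].iloc[0])

    def episode_weights(self, sex: str, age_band: str) -> pd.Series:
        t = self.table
        sel = t[(t["sex"] == sex) & (t["age_band"] == age_band)]
        return sel.set_index("income_group")["n_episodes"]

    def to_csv(self, path, *, sep: str = ",") -> None:
        self.table[RR_COLUMNS].to_csv(path, sep=sep, index=False)

    @classmethod
    def from_csv(cls, path, *, sep: str = ",") -> "RelativeRiskSet":
        return cls(pd.read_csv(path, sep=sep))

    @classmethod
    def from_values(cls, hr: dict, n_episodes: int = 1) -> "RelativeRiskSet":
        """Build a set from ``{(group, sex, age_band): hr}`` values.

        Missing combinations default to 1 (the population average);
        useful for null scenarios and for applying externally given
        ratios.
        """
        rows = []
        sexes = sorted({k[1] for k in hr} or {"female", "male"})
        bands = sorted({k[2] for k in hr} or set(AGE_BANDS))
        for sex in sexes:
            for band in bands:
                for g in INCOME_GROUPS:
                    rows.append(
                        (g, sex, band, float(hr.get((g, sex, band), 1.0)),
                         np.nan, n_episodes, 0)
                    )
        return cls(pd.DataFrame(rows, columns=RR_COLUMNS))


class RelativeRiskEstimator:
    """Proportional-hazards relative risks against the population average.

    scikit-learn style estimator: construct with hyper-parameters, call
    :meth:`fit` on an episode frame, read fitted state from
    trailing-underscore attributes.

    Parameters
    ----------
    ties : {"efron", "breslow"}
        Correction for tied event ages.  Efron by default: event ages
        tie heavily when episodes end at integer ages.
    coding : {"episode_weighted", "unweighted"}
        Weighting of the sum-to-zero (effect) coding.  Episode-weighted
        by default, so the reference level is the episode-weighted
        population average of the stratum.
    gtol, max_iter
        Newton solver controls for the partial likelihood.

    Attributes
    ----------
    relative_risks_ : RelativeRiskSet
        Fitted hazard ratios with standard errors and stratum sizes.
    log_likelihood_ : dict
        Maximized partial log-likelihood per (sex, age_band) stratum.
    n_iter_ : dict
        Newton iterations per stratum.
    """

    def __init__(
        self,
        ties: str = "efron",
        coding: str = "episode_weighted",
        weights_col: str | None = None,
        gtol: float = 1e-9,
        max_iter: int = 100,
    ):
        self.ties = ties
        self.coding = coding
        self.weights_col = weights_col
        self.gtol = gtol
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {
            "ties": self.ties,
            "coding": self.coding,
            "weights_col": self.weights_col,
            "gtol": self.gtol,
            "max_iter": self.max_iter,
        }

    def set_params(self, **params) -> "RelativeRiskEstimator":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "RelativeRiskEstimator":
        """Fit one stratified model per sex x age band.

        ``X`` is an episode frame as produced by :func:`build_episodes`.
        Groups with zero events in a stratum are flagged with ``hr``
        NaN (undefined) and excluded from the likelihood rather than
        silently dropped.
        """
        if self.coding not in ("episode_weighted", "unweighted"):
            raise ValueError(f"unknown coding {self.coding!r}")
        missing = set(EPISODE_COLUMNS) - set(X.columns)
        if missing:
            raise ValueError(f"episode frame is missing columns {sorted(missing)}")
        rows = []
        self.log_likelihood_ = {}
        self.n_iter_ = {}
        self.covariances_ = {}
        groups = list(INCOME_GROUPS)
        for (sex, band), stratum in X.groupby(["sex", "age_band"], sort=True):
            res = self._fit_stratum(stratum, groups, (sex, band))
            rows.extend(res)
        table = pd.DataFrame(rows, columns=RR_COLUMNS)
        self.relative_risks_ = RelativeRiskSet(
            table, coding=self.coding, covariances=self.covariances_
        )
        return self

    def _fit_stratum(self, stratum: pd.DataFrame, groups: list, key: tuple):
        g_codes = pd.Categorical(
            stratum["income_group"], categories=groups
        ).codes.astype(np.int64)
        if (g_codes < 0).any():
            raise ValueError("income_group outside the configured categories")
        n_eps = np.bincount(g_codes, minlength=len(groups))
        n_evt = np.bincount(
            g_codes[stratum["event"].to_numpy(dtype=bool)], minlength=len(groups)
        )
        fit_mask = (n_eps > 0) & (n_evt > 0)
        undefined = (n_eps > 0) & (n_evt == 0)
        if undefined.any():
            warnings.warn(
                f"stratum {key}: no events for groups "
                f"{[groups[i] for i in np.flatnonzero(undefined)]}; "
                "their estimates are undefined",
                stacklevel=3,
            )
        fit_groups = np.flatnonzero(fit_mask)
        in_fit = np.isin(g_codes, fit_groups)
        sub = stratum[in_fit]
        lookup = np.full(len(groups), -1, dtype=np.int64)
        lookup[fit_groups] = np.arange(fit_groups.size)
        codes = lookup[g_codes[in_fit]]
        w = sub[self.weights_col].to_numpy(float) if self.weights_col else None

        if fit_groups.size and sub["event"].any():
            res = _cox.fit_cox_categorical(
                sub["age_start"].to_numpy(float),
                sub["age_stop"].to_numpy(float),
                sub["event"].to_numpy(bool),
                codes,
                len(fit_groups),
                ties=self.ties,
                weights=w,
                gtol=self.gtol,
                max_iter=self.max_iter,
            )
            beta, cov = res["beta"], res["cov"]
            self.log_likelihood_[key] = res["loglik"]
            self.n_iter_[key] = res["n_iter"]
        else:
            beta = np.zeros(fit_groups.size)
            cov = np.zeros((fit_groups.size, fit_groups.size))

        # effect coding: centre on the (weighted) stratum average
        if self.coding == "episode_weighted":
            wts = n_eps[fit_groups].astype(float)
        else:
            wts = np.ones(fit_groups.size)
        wts = wts / wts.sum() if wts.size else wts
        log_hr = beta - wts @ beta
        # var of the centred contrast c'beta with c = e_g - wts
        se = np.full(fit_groups.size, np.nan)
        for i in range(fit_groups.size):
            c = -wts.copy()
            c[i] += 1.0
            se[i] = np.sqrt(c @ cov @ c)
        self.covariances_[key] = {
            "groups": [groups[i] for i in fit_groups],
            "cov_log_hr": _centered_cov(cov, wts),
        }

        rows = []
        for i, gi in enumerate(fit_groups):
            rows.append(
                (groups[gi], key[0], key[1], float(np.exp(log_hr[i])),
                 float(se[i]), int(n_eps[gi]), int(n_evt[gi]))
            )
        for gi in np.flatnonzero(undefined):
            rows.append(
                (groups[gi], key[0], key[1], np.nan, np.nan,
                 int(n_eps[gi]), 0)
            )
        rows.sort(key=lambda r: groups.index(r[0]))
        return rows


def _centered_cov(cov: np.ndarray, wts: np.ndarray) -> np.ndarray:
    C = np.eye(len(wts)) - np.tile(wts, (len(wts), 1))
    return C @ cov @ C.T


def fit_relative_risks(
    episodes: pd.DataFrame,
    span: tuple[int, int] | None = None,
    **params,
) -> RelativeRiskSet:
    """Estimate effect-coded relative risks, optionally on a calendar span.

    Thin wrapper over :class:`RelativeRiskEstimator`.
    """
    if span is not None:
        lo, hi = span
        episodes = episodes[
            (episodes["calendar_year"] >= lo) & (episodes["calendar_year"] <= hi)
        ]
        if episodes.empty:
            raise ValueError(f"no episodes in calendar span {lo}-{hi}")
    est = RelativeRiskEstimator(**params)
    est.fit(episodes)
    return est.relative_risks_


def hr_vs_top_group(
    rr: RelativeRiskSet, sex: str, age_band: str,
    low: str = "G1", high: str = "G5",
) -> float:
    """Mortality risk of the lowest relative to the highest income group."""
    hr_low = rr.hr(low, sex, age_band)
    hr_high = rr.hr(high, sex, age_band)
    if not (np.isfinite(hr_low) and np.isfinite(hr_high)):
        raise ValueError(f"undefined estimate for {low} or {high} in {(sex, age_band)}")
    return hr_low / hr_high
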