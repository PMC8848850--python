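"""Net equivalised income and median-relative income groups.

Household net income is made comparable across household sizes with the
OECD-modified equivalence scale (head 1.0, each further person aged 15+
0.5, each child under 15 0.3) and persons are classified into five
income groups relative to the pooled population median:

    G1  < 60%          (at-risk-of-poverty)
    G2  60% - < 80%
    G3  80% - < 100%
    G4  100% - < 150%
    G5  >= 150%        (relative wealth)

All interval bounds are lower-inclusive / upper-exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Ordered labels of the five median-relative income groups.
INCOME_GROUPS = ("G1", "G2", "G3", "G4", "G5")

#: Human-readable group labels for reports.
GROUP_LABELS = {
    "G1": "<60%",
    "G2": "60%-<80%",
    "G3": "80%-<100%",
    "G4": "100%-<150%",
    "G5": ">=150%",
}

#: Default group boundaries as fractions of the pooled median.
DEFAULT_THRESHOLDS = (0.6, 0.8, 1.0, 1.5)


@dataclass(frozen=True)
class EquivalenceScale:
    """Needs weights of the OECD-modified equivalence scale.

    The household head carries weight 1.0, every further household
    member aged 15 or over 0.5, and every child under 15 0.3.  The
    equivalence divisor of a household is therefore
    ``1 + 0.5*(n_adults_15plus - 1) + 0.3*n_children_under15``,
    e.g. 1.5 for a two-adult household and 2.1 for two adults with
    two children under 15.
    """

    weight_head: float = 1.0
    weight_adult_15plus: float = 0.5
    weight_child_under15: float = 0.3

    def divisor(self, n_adults_15plus, n_children_under15):
        """Needs-weight sum for a household composition (vectorised)."""
        n_adults = np.asarray(n_adults_15plus)
        n_children = np.asarray(n_children_under15)
        if np.any(n_adults < 1):
            raise ValueError("a household needs at least one adult (the head)")
        if np.any(n_children < 0):
            raise ValueError("negative number of children")
        d = (
            self.weight_head
            + self.weight_adult_15plus * (n_adults - 1)
            + self.weight_child_under15 * n_children
        )
        return d if d.ndim else float(d)


def equivalised_income(
    hh_net_income,
    n_adults_15plus,
    n_children_under15,
    scale: EquivalenceScale | None = None,
):
    """Net equivalised income: household net income / needs-weight sum.

    Parameters
    ----------
    hh_net_income
        Household net income (scalar or array), must be positive.
    n_adults_15plus, n_children_under15
        Household composition counts; at least one adult.
    scale
        Equivalence scale, OECD-modified by default.

    Returns
    -------
    float or ndarray
        Income per equivalent adult, same shape as the inputs.
    """
    scale = scale or EquivalenceScale()
    income = np.asarray(hh_net_income, dtype=float)
    if np.any(income <= 0):
        raise ValueError("household net income must be positive")
    out = income / scale.divisor(n_adults_15plus, n_children_under15)
    return out if out.ndim else float(out)


def pooled_median(incomes, weights=None) -> float:
    """Median over pooled person-period income observations.

    With ``weights`` the weighted median is returned: the smallest value
    at which the cumulative weight reaches half the total.
    """
    x = np.asarray(incomes, dtype=float)
    if x.size == 0:
        raise ValueError("cannot take the median of an empty collection")
    if weights is None:
        return float(np.median(x))
    w = np.asarray(weights, dtype=float)
    if w.shape != x.shape:
        raise ValueError("weights must match incomes in shape")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive total")
    order = np.argsort(x, kind="stable")
    cw = np.cumsum(w[order])
    return float(x[order][np.searchsorted(cw, 0.5 * cw[-1])])


def classify_income_group(
    equiv_income,
    median: float,
    thresholds=DEFAULT_THRESHOLDS,
):
    """Assign median-relative income groups (G1..G5).

    Boundaries are lower-inclusive: an income of exactly 100% of the
    median falls in G4, exactly 150% in G5.

    Returns a single label for scalar input, otherwise an array of
    labels aligned with ``equiv_income``.
    """
    if median <= 0:
        raise ValueError("median must be positive")
    x = np.asarray(equiv_income, dtype=float)
    if np.any(x <= 0):
        raise ValueError("equivalised income must be positive")
    t = np.asarray(thresholds, dtype=float)
    if t.size != len(INCOME_GROUPS) - 1 or np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be 4 increasing median fractions")
    idx = np.digitize(x / median, t, right=False)
    labels = np.asarray(INCOME_GROUPS)[np.atleast_1d(idx)]
    return labels if x.ndim else str(labels[0])


def group_shares_lognormal(sigma: float, thresholds=DEFAULT_THRESHOLDS) -> dict:
    """Population share of each income group under a lognormal income law.

    For lognormal equivalised income the median is ``exp(mu)`` and the
    share below a fraction ``t`` of the median is ``Phi(ln t / sigma)``,
    independent of ``mu``.  Used by the synthetic-data generator to
    centre group effects on the population average.
    """
    from scipy.stats import norm

    if sigma <= 0:
        raise ValueError("sigma must be positive")
    cut = norm.cdf(np.log(np.asarray(thresholds, dtype=float)) / sigma)
    probs = np.diff(np.concatenate([[0.0], cut, [1.0]]))
    return dict(zip(INCOME_GROUPS, probs))
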