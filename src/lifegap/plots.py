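"""Optional matplotlib figures: survivor curves, premature mortality,
trend series.  Requires the ``plot`` extra (matplotlib)."""

from __future__ import annotations

import pandas as pd

from .income import GROUP_LABELS, INCOME_GROUPS


def _mpl():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (pip install lifegap[plot])") from exc
    return plt


def plot_survivor_curves(results, *, max_age: int = 100):
    """Survivor functions by income group, one panel per sex."""
    plt = _mpl()
    curves = results.survivor_curves
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, sex in zip(axes, ("female", "male")):
        for group in INCOME_GROUPS:
            c = curves[(curves.sex == sex) & (curves.income_group == group)]
            c = c[c.age <= max_age]
            ax.plot(c["age"], c["lx"], label=GROUP_LABELS[group])
        ax.set_title(sex)
        ax.set_xlabel("age")
        ax.set_ylim(0, 1.02)
    axes[0].set_ylabel("proportion surviving")
    axes[1].legend(title="income", fontsize=8)
    fig.tight_layout()
    return fig


def plot_premature_mortality(results):
    """Share dying before 65 by income group and sex (bar chart)."""
    plt = _mpl()
    t = results.table
    t = t[t.income_group != "total"]
    fig, ax = plt.subplots(figsize=(7, 4))
    width = 0.35
    for i, (sex, off) in enumerate((("female", -width / 2), ("male", width / 2))):
        sel = t[t.sex == sex].set_index("income_group").loc[list(INCOME_GROUPS)]
        ax.bar(
            [j + off for j in range(len(INCOME_GROUPS))],
            100 * sel["p_death_before_65"],
            width,
            label=sex,
        )
    ax.set_xticks(range(len(INCOME_GROUPS)))
    ax.set_xticklabels([GROUP_LABELS[g] for g in INCOME_GROUPS], fontsize=8)
    ax.set_ylabel("% dying before age 65")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_trends(series, metric: str = "e0"):
    """Metric per income group over calendar windows, one panel per sex."""
    plt = _mpl()
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, sex in zip(axes, ("female", "male")):
        for group in INCOME_GROUPS:
            s = series.metric_series(group, sex, metric)
            ax.plot(s.index, s.to_numpy(), marker="o", ms=3, label=GROUP_LABELS[group])
        ax.set_title(sex)
        ax.set_xlabel("window midpoint")
    axes[0].set_ylabel(metric)
    axes[1].legend(title="income", fontsize=8)
    fig.tight_layout()
    return fig
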