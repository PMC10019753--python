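"""Between-group comparisons of connectivity features with significance stars.

For each (measure, band, state) cell, epoch-level features are first
averaged within subject — the subject is the independent unit, and
epoch-level testing would pseudo-replicate — and group means are then
compared with Welch's two-sample t-test (unequal variances). Stars
follow the conventional thresholds * p<0.05, ** p<0.01, *** p<0.001.

A one-way ANOVA over the three groups is available as an alternative
omnibus test; no multiple-testing correction is applied by default
(each cell is reported on its own), with Benjamini-Hochberg adjustment
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .features import MEASURES

GROUP_PAIRS: tuple[tuple[str, str], ...] = (("LTM", "NM"), ("STM", "NM"), ("LTM", "STM"))

_STAR_LEVELS: tuple[tuple[float, str], ...] = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_from_p(p: float) -> str:
    """Significance star for a p-value: * <0.05, ** <0.01, *** <0.001."""
    for threshold, star in _STAR_LEVELS:
        if p < threshold:
            return star
    return "ns"


@dataclass
class GroupComparison:
    measure: str
    band: str
    state: str
    groups: tuple[str, str]
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    n: tuple[int, int]
    p_value: float
    star: str
    t_statistic: float


def subject_means(features: pd.DataFrame) -> pd.DataFrame:
    """Epoch-averaged feature values per (subject, group, state, band)."""
    return (
        features.groupby(["subject", "group", "state", "band"], as_index=False)[
            list(MEASURES)
        ].mean()
    )


def compare_groups(
    values_a: np.ndarray,
    values_b: np.ndarray,
    *,
    measure: str,
    band: str,
    state: str,
    pair: tuple[str, str],
) -> GroupComparison:
    """Welch t-test on two groups' subject-level feature values."""
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    if len(values_a) < 2 or len(values_b) < 2:
        raise ValueError(
            f"need >= 2 subjects per group for {pair}; got {len(values_a)}, {len(values_b)}"
        )
    t, p = stats.ttest_ind(values_a, values_b, equal_var=False)
    return GroupComparison(
        measure=measure,
        band=band,
        state=state,
        groups=pair,
        group_means=(float(values_a.mean()), float(values_b.mean())),
        group_sds=(float(values_a.std(ddof=1)), float(values_b.std(ddof=1))),
        n=(len(values_a), len(values_b)),
        p_value=float(p),
        star=star_from_p(float(p)),
        t_statistic=float(t),
    )


def comparison_grid(
    features: pd.DataFrame,
    *,
    pairs: tuple[tuple[str, str], ...] = GROUP_PAIRS,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """All (measure x band x state x group-pair) comparisons as a tidy frame.

    With the full design (4 measures, 4 bands, 4 states, 3 pairs) this is
    192 rows. Optional Benjamini-Hochberg adjustment replaces raw p-values
    with FDR-adjusted ones before star assignment.
    """
    if features.empty:
        raise ValueError("empty feature frame")
    per_subject = subject_means(features)
    states = sorted(set(per_subject["state"]))
    bands = sorted(set(per_subject["band"]))
    needed = {g for p in pairs for g in p}
    missing = sorted(needed - set(per_subject["group"]))
    if missing:
        raise ValueError(f"missing group(s) in cohort: {missing}")

    rows = []
    for measure in MEASURES:
        for band in bands:
            for state in states:
                cell = per_subject[
                    (per_subject["band"] == band) & (per_subject["state"] == state)
                ]
                for pair in pairs:
                    va = cell.loc[cell["group"] == pair[0], measure].to_numpy()
                    vb = cell.loc[cell["group"] == pair[1], measure].to_numpy()
                    gc = compare_groups(
                        va, vb, measure=measure, band=band, state=state, pair=pair
                    )
                    rows.append(
                        {
                            "measure": measure,
                            "band": band,
                            "state": state,
                            "pair": f"{pair[0]} vs {pair[1]}",
                            "mean_1": gc.group_means[0],
                            "mean_2": gc.group_means[1],
                            "sd_1": gc.group_sds[0],
                            "sd_2": gc.group_sds[1],
                            "n_1": gc.n[0],
                            "n_2": gc.n[1],
                            "t": gc.t_statistic,
                            "p_value": gc.p_value,
                            "star": gc.star,
                        }
                    )
    out = pd.DataFrame(rows)
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests(out["p_value"], method="fdr_bh")
        out["p_value_bh"] = p_adj
        out["star"] = [star_from_p(p) for p in p_adj]
    return out


def anova_grid(features: pd.DataFrame) -> pd.DataFrame:
    """One-way ANOVA across all three groups per (measure, band, state)."""
    per_subject = subject_means(features)
    rows = []
    for measure in MEASURES:
        for (band, state), cell in per_subject.groupby(["band", "state"]):
            samples = [
                grp[measure].to_numpy() for _, grp in cell.groupby("group") if len(grp) >= 2
            ]
            if len(samples) < 2:
                continue
            f, p = stats.f_oneway(*samples)
            rows.append(
                {"measure": measure, "band": band, "state": state,
                 "F": float(f), "p_value": float(p), "star": star_from_p(float(p))}
            )
    return pd.DataFrame(rows)


def plot_group_bars(features: pd.DataFrame, measure: str, *, ax_grid=None):
    """Bar chart of group means (subject-level) per state, one panel per
    band: the tabular comparison grid rendered graphically. Requires
    matplotlib; returns the Figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    per_subject = subject_means(features)
    bands = sorted(set(per_subject["band"]))
    groups = [g for g in ("LTM", "STM", "NM") if g in set(per_subject["group"])]
    states = [s for s in ("baseline", "meditation", "transmission", "post")
              if s in set(per_subject["state"])]

    fig, axes = plt.subplots(1, len(bands), figsize=(4 * len(bands), 3), squeeze=False)
    width = 0.8 / len(groups)
    for ax, band in zip(axes[0], bands):
        cell = per_subject[per_subject["band"] == band]
        for gi, group in enumerate(groups):
            vals = [
                cell[(cell["group"] == group) & (cell["state"] == s)][measure].mean()
                for s in states
            ]
            errs = [
                cell[(cell["group"] == group) & (cell["state"] == s)][measure].std()
                for s in states
            ]
            x = np.arange(len(states)) + gi * width
            ax.bar(x, vals, width=width, yerr=errs, capsize=2, label=group)
        ax.set_xticks(np.arange(len(states)) + 0.4 - width / 2)
        ax.set_xticklabels(states, rotation=30, ha="right", fontsize=8)
        ax.set_title(band)
    axes[0][0].set_ylabel(f"mean {measure}")
    axes[0][-1].legend(fontsize=8)
    fig.tight_layout()
    return fig
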