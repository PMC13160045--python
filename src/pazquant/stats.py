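"""Normalization, gated test selection, and Pearson colocalization.

Group comparisons follow a gated scheme: normality (Shapiro-Wilk, per
group) and homogeneity of variances (Levene) are checked at a gate level
of 0.05; if all gates pass, a parametric test is used (two-sided t-test
for two groups, one-way ANOVA with Tukey-Kramer post hoc for more),
otherwise a nonparametric one (Mann-Whitney U, or Kruskal-Wallis with
pairwise Mann-Whitney and Holm correction).  Observations are
per-synapse / per-NMJ values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupData:
    condition: str
    values: np.ndarray
    culture_ids: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class StatsResult:
    test: str  # "t", "mannwhitneyu", "anova", "kruskal"
    parametric: bool
    statistic: float
    p_value: float
    shapiro_p: dict  # condition -> p
    levene_p: float
    posthoc: list = field(default_factory=list)  # (a, b, raw_p, adj_p, stars)
    stars: str = ""


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def normalize_per_culture(values, culture_ids, conditions, reference: str):
    """Express each value as % of its own culture's reference-condition
    mean.  The pooled reference mean is 100% by construction."""
    values = np.asarray(values, dtype=float)
    culture_ids = np.asarray(culture_ids)
    conditions = np.asarray(conditions)
    out = np.empty_like(values)
    for cult in np.unique(culture_ids):
        in_c = culture_ids == cult
        ref = values[in_c & (conditions == reference)]
        if ref.size == 0:
            raise ValueError(f"culture {cult!r} has no {reference!r} observations")
        m = ref.mean()
        if not m > 0:
            raise ValueError(f"culture {cult!r} reference mean is not positive")
        out[in_c] = values[in_c] / m * 100.0
    return out


def pearson_colocalization(ch_a, ch_b, mask) -> float:
    """Pearson correlation of two channels over the mask pixels."""
    pixels = mask.pixels if hasattr(mask, "pixels") else np.asarray(mask, bool)
    a = np.asarray(ch_a, float)[pixels]
    b = np.asarray(ch_b, float)[pixels]
    if a.size < 2:
        raise ValueError("mask must contain at least 2 pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant channel within mask: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def select_and_run_test(groups, alpha_gate: float = 0.05) -> StatsResult:
    """Assumption-gated two-sided comparison of >= 2 groups."""
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.values.size < 3:
            raise ValueError(f"group {g.condition!r} has fewer than 3 observations")
        if np.ptp(g.values) == 0:
            raise ValueError(f"group {g.condition!r} has all-identical values")
    arrays = [g.values for g in groups]

    shapiro_p = {g.condition: float(sps.shapiro(g.values).pvalue) for g in groups}
    levene_p = float(sps.levene(*arrays, center="mean").pvalue)
    parametric = all(p >= alpha_gate for p in shapiro_p.values()) and levene_p >= alpha_gate

    posthoc = []
    if len(groups) == 2:
        if parametric:
            res = sps.ttest_ind(*arrays)
            name = "t"
        else:
            res = sps.mannwhitneyu(*arrays, alternative="two-sided")
            name = "mannwhitneyu"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        if parametric:
            res = sps.f_oneway(*arrays)
            name = "anova"
            stat, p = float(res.statistic), float(res.pvalue)
            tk = sps.tukey_hsd(*arrays)
            for i, j in combinations(range(len(groups)), 2):
                adj = float(tk.pvalue[i, j])
                posthoc.append(
                    (
                        groups[i].condition,
                        groups[j].condition,
                        adj,  # Tukey-Kramer p is already adjusted
                        adj,
                        significance_stars(adj),
                    )
                )
        else:
            res = sps.kruskal(*arrays)
            name = "kruskal"
            stat, p = float(res.statistic), float(res.pvalue)
            pairs = list(combinations(range(len(groups)), 2))
            raw = [
                float(
                    sps.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided").pvalue
                )
                for i, j in pairs
            ]
            adj = multipletests(raw, method="holm")[1]
            for (i, j), rp, ap in zip(pairs, raw, adj):
                posthoc.append(
                    (
                        groups[i].condition,
                        groups[j].condition,
                        rp,
                        float(ap),
                        significance_stars(float(ap)),
                    )
                )

    return StatsResult(
        test=name,
        parametric=parametric,
        statistic=stat,
        p_value=p,
        shapiro_p=shapiro_p,
        levene_p=levene_p,
        posthoc=posthoc,
        stars=significance_stars(p),
    )
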