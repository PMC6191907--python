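"""Functional-category statistics and half-life correlations.

Genes are grouped by annotated functional category; a one-way ANOVA asks
whether mean half-lives differ between categories at all, and a post-hoc
one-sample t-test per category asks whether that category's mean differs
from the fixed global mean half-life, with Bonferroni correction over the
number of categories tested. Half-life is also correlated (Pearson) with
transcript abundance (log10 FPKM by default) and with ORF length.

The ANOVA is computed directly from the between/within sums of squares;
the post-hoc t-test treats the global mean as a known constant, since each
category is compared against the overall average rather than against a
second sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


@dataclass(frozen=True)
class CategoryResult:
    category: str
    n_genes: int
    mean_half_life: float
    t_statistic: float
    p_value: float
    p_bonferroni: float
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    variable_pair: str
    r: float
    n: int
    p_value: float


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA from the sum-of-squares decomposition.

    F = (SSB/dfB) / (SSW/dfW) with dfB = k-1 and dfW = N-k; the p-value
    comes from the F distribution's survival function. Every group must
    contain at least two values and there must be at least two groups.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    n_total = sum(a.size for a in arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)
    if ssw == 0.0:
        if ssb == 0.0:
            raise ValueError("zero variance within and between groups")
        return AnovaResult(np.inf, df_between, df_within, 0.0)
    f = (ssb / df_between) / (ssw / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), df_between, df_within, p)


def posthoc_vs_global(group_values: Sequence[float], global_mean: float,
                      m: int, category: str = "") -> CategoryResult:
    """One-sample two-sided t-test of a category against the global mean.

    ``m`` is the Bonferroni multiplier (number of categories tested);
    the adjusted p-value is min(1, m*p). A zero-variance group is flagged
    degenerate with p = 0 (mean differs) or p = 1 (mean equals global).
    """
    values = np.asarray(group_values, dtype=float)
    if values.size < 2:
        raise ValueError("post-hoc test needs at least two values")
    mean = float(values.mean())
    if np.ptp(values) == 0.0:
        p = 1.0 if mean == global_mean else 0.0
        t = 0.0 if mean == global_mean else np.inf * np.sign(mean - global_mean)
        return CategoryResult(category, values.size, mean, float(t), p,
                              min(1.0, m * p), degenerate=True)
    t, p = stats.ttest_1samp(values, popmean=global_mean)
    return CategoryResult(category, values.size, mean, float(t), float(p),
                          min(1.0, m * float(p)))


def category_tests(category_map: Mapping[str, str],
                   half_lives: Mapping[str, float],
                   min_group_size: int = 2
                   ) -> tuple[AnovaResult, list[CategoryResult]]:
    """ANOVA plus per-category post-hoc tests against the global mean.

    ``category_map`` maps gene_id to category; ``half_lives`` maps gene_id
    to accepted half-life estimates. The global mean is taken over all
    genes with both a category and a half-life. Categories with fewer than
    ``min_group_size`` estimated genes are not tested and do not count
    toward the Bonferroni multiplier.
    """
    groups: dict[str, list[float]] = {}
    for gene_id, category in category_map.items():
        if gene_id in half_lives:
            groups.setdefault(category, []).append(half_lives[gene_id])
    groups = {c: v for c, v in groups.items() if len(v) >= min_group_size}
    if len(groups) < 2:
        raise ValueError("need at least two testable categories")
    global_mean = float(np.mean([x for v in groups.values() for x in v]))
    anova = one_way_anova(groups)
    m = len(groups)
    results = [posthoc_vs_global(v, global_mean, m, category=c)
               for c, v in sorted(groups.items())]
    return anova, results


def pearson(x: Sequence[float], y: Sequence[float],
            variable_pair: str = "x_vs_y") -> CorrelationResult:
    """Pearson correlation with a two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined for a constant variable")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(variable_pair, float(r), int(x.size), float(p))


def correlate_half_life_abundance(half_lives: Mapping[str, float],
                                  fpkm: Mapping[str, float],
                                  transform: str = "log10") -> CorrelationResult:
    """Half-life vs abundance over genes with FPKM > 0.

    Abundance enters as log10(FPKM) by default, matching the logarithmic
    axis such data are plotted on; ``transform='raw'`` uses FPKM directly.
    """
    genes = sorted(g for g in half_lives if g in fpkm and fpkm[g] > 0)
    hl = [half_lives[g] for g in genes]
    ab = [fpkm[g] for g in genes]
    if transform == "log10":
        ab = list(np.log10(ab))
    elif transform != "raw":
        raise ValueError("transform must be 'log10' or 'raw'")
    return pearson(hl, ab, f"half_life_vs_{transform}_fpkm")


def correlate_half_life_length(half_lives: Mapping[str, float],
                               orf_lengths: Mapping[str, float]) -> CorrelationResult:
    genes = sorted(g for g in half_lives if g in orf_lengths)
    return pearson([half_lives[g] for g in genes],
                   [orf_lengths[g] for g in genes],
                   "half_life_vs_orf_length")


def reproduce_supplementary_summary(half_life_table: pd.DataFrame,
                                    fpkm_table: pd.DataFrame | None = None
                                    ) -> dict[str, float]:
    """Global mean/median (and abundance correlation) from published tables.

    ``half_life_table`` needs columns gene_id and half_life_min;
    ``fpkm_table`` (optional) needs gene_id and fpkm. Returns a dict with
    ``mean``, ``median`` and, when abundance is supplied, ``r_abundance``.
    """
    hl = half_life_table.set_index("gene_id")["half_life_min"].astype(float)
    out = {"mean": float(hl.mean()), "median": float(hl.median()),
           "n": int(hl.size)}
    if fpkm_table is not None:
        res = correlate_half_life_abundance(
            hl.to_dict(), fpkm_table.set_index("gene_id")["fpkm"].astype(float).to_dict()
        )
        out["r_abundance"] = res.r
    return out
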