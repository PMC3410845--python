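"""Phenotype-distribution tallies and the associated statistical tests.

Embryo phenotypes are scored into three classes — wild type, Full Gex (no
epidermal enclosure, gut fully exposed) and Partial Gex (incomplete
enclosure) — and summarized as integer percentages with total embryonic
lethality = Full + Partial.  Group comparisons use the conventions of the
source analyses: mean +/- SEM, one-way ANOVA with the Tukey HSD post-test
for ungrouped data, and two-way ANOVA with the Bonferroni post-test for
grouped (two-factor) data.

The sums of squares are computed directly here; the F and studentized-range
distributions come from scipy.stats.  Count-based exact tests
(Fisher/chi-square) are deliberately not substituted for the ANOVA-on-
percentages convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

SIGNIFICANCE_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Asterisk annotation at the 0.05/0.01/0.001/0.0001 levels."""
    for cutoff, stars in SIGNIFICANCE_LEVELS:
        if p < cutoff:
            return stars
    return "ns"


@dataclass
class PhenotypeCounts:
    """Embryo class counts for one genotype at one temperature."""

    genotype: str
    temperature: float
    n_wildtype: int
    n_full_gex: int
    n_partial_gex: int

    def __post_init__(self) -> None:
        for c in (self.n_wildtype, self.n_full_gex, self.n_partial_gex):
            if c < 0:
                raise ValueError("counts must be >= 0")

    @property
    def n(self) -> int:
        return self.n_wildtype + self.n_full_gex + self.n_partial_gex


@dataclass
class PhenotypeSummary:
    """Integer-rounded percentage columns of a phenotype table row."""

    pct_wildtype: int
    pct_full: int
    pct_partial: int
    pct_total_lethality: int
    exact: dict  # unrounded percentages, for ">99" / "<1" display


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def format_percent(exact: float) -> str:
    """Display convention: values in (99, 100) print as '>99', in (0, 1) as '<1'."""
    if 99.0 < exact < 100.0:
        return ">99"
    if 0.0 < exact < 1.0:
        return "<1"
    return str(_round_half_away(exact))


def tally(counts: PhenotypeCounts) -> PhenotypeSummary:
    """Class percentages (nearest integer, half away from zero) and lethality."""
    n = counts.n
    if n < 1:
        raise ValueError("cannot tally zero embryos")
    exact = {
        "wildtype": 100.0 * counts.n_wildtype / n,
        "full": 100.0 * counts.n_full_gex / n,
        "partial": 100.0 * counts.n_partial_gex / n,
        "total_lethality": 100.0 * (counts.n_full_gex + counts.n_partial_gex) / n,
    }
    return PhenotypeSummary(
        pct_wildtype=_round_half_away(exact["wildtype"]),
        pct_full=_round_half_away(exact["full"]),
        pct_partial=_round_half_away(exact["partial"]),
        pct_total_lethality=_round_half_away(exact["total_lethality"]),
        exact=exact,
    )


def sem(values) -> float:
    """Standard error of the mean: sample SD (n-1 denominator) / sqrt(n)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("SEM needs at least 2 values")
    return float(values.std(ddof=1) / math.sqrt(values.size))


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ms_within: float
    infinite: bool = False  # zero within-group variance with distinct means


def one_way_anova(groups: list) -> AnovaResult:
    """One-way fixed-effects ANOVA from standard sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 groups, each with >= 1 value")
    n_total = sum(len(g) for g in groups)
    df_within = n_total - len(groups)
    if df_within < 1:
        raise ValueError("need at least one group with >= 2 values")
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        if ms_between == 0:
            return AnovaResult(0.0, df_between, df_within, 1.0, 0.0)
        return AnovaResult(math.inf, df_between, df_within, 0.0, 0.0, infinite=True)
    F = ms_between / ms_within
    p = float(sps.f.sf(F, df_between, df_within))
    return AnovaResult(float(F), df_between, df_within, p, float(ms_within))


def tukey_hsd(groups: list, labels: list | None = None) -> list:
    """Tukey HSD pairwise comparisons after a one-way ANOVA.

    For each pair, q = |mean_i - mean_j| / sqrt(MS_within/2 * (1/n_i + 1/n_j))
    (the Tukey-Kramer statistic for unequal group sizes) and the adjusted
    p-value is the upper tail of the studentized-range distribution with
    (k, df_within).  Returns a list of dicts with mean_diff, q, p_adj and
    significance stars.
    """
    anova = one_way_anova(groups)
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group-{i}" for i in range(len(arrays))]
    k = len(arrays)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = float(arrays[i].mean() - arrays[j].mean())
        if anova.ms_within == 0:
            q = math.inf if diff != 0 else 0.0
            p_adj = 0.0 if diff != 0 else 1.0
        else:
            se = math.sqrt(
                anova.ms_within / 2.0 * (1.0 / len(arrays[i]) + 1.0 / len(arrays[j]))
            )
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, anova.df_within))
        rows.append(
            {
                "a": labels[i],
                "b": labels[j],
                "mean_diff": diff,
                "q": q,
                "p_adj": min(1.0, p_adj),
                "stars": significance_stars(p_adj),
            }
        )
    return rows


@dataclass
class TwoWayAnovaResult:
    effects: dict       # name -> dict(ss, df, ms, F, p)
    comparisons: list   # Bonferroni-adjusted simple-effect comparisons
    m_comparisons: int


def two_way_anova_bonferroni(
    table: np.ndarray,
    m_comparisons: int | None = None,
    a_labels: list | None = None,
    b_labels: list | None = None,
) -> TwoWayAnovaResult:
    """Balanced two-way fixed-effects ANOVA with Bonferroni post-tests.

    ``table`` has shape (a, b, r): levels of factor A x levels of factor B x
    replicates.  Main effects and the interaction use the standard balanced
    decomposition.  The post-test compares the levels of factor A within
    each level of B by t statistics on MS_within, with each p multiplied by
    the number of comparisons (capped at 1).
    """
    y = np.asarray(table, dtype=float)
    if y.ndim != 3:
        raise ValueError("table must be (a_levels, b_levels, replicates); "
                         "unbalanced designs are out of scope")
    a, b, r = y.shape
    if a < 2 or b < 2 or r < 2:
        raise ValueError("need >= 2 levels per factor and >= 2 replicates")
    grand = y.mean()
    mean_a = y.mean(axis=(1, 2))
    mean_b = y.mean(axis=(0, 2))
    mean_ab = y.mean(axis=2)
    ss_a = b * r * ((mean_a - grand) ** 2).sum()
    ss_b = a * r * ((mean_b - grand) ** 2).sum()
    ss_ab = r * ((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2).sum()
    ss_within = ((y - mean_ab[:, :, None]) ** 2).sum()
    df = {"A": a - 1, "B": b - 1, "AxB": (a - 1) * (b - 1), "within": a * b * (r - 1)}
    ms_within = ss_within / df["within"]
    effects = {}
    for name, ss in (("A", ss_a), ("B", ss_b), ("AxB", ss_ab)):
        ms = ss / df[name]
        if ms_within == 0:
            F = math.inf if ms > 0 else 0.0
            p = 0.0 if ms > 0 else 1.0
        else:
            F = ms / ms_within
            p = float(sps.f.sf(F, df[name], df["within"]))
        effects[name] = {"ss": float(ss), "df": df[name], "ms": float(ms), "F": F, "p": p}
    effects["within"] = {
        "ss": float(ss_within), "df": df["within"], "ms": float(ms_within),
        "F": None, "p": None,
    }

    if a_labels is None:
        a_labels = [f"A{i}" for i in range(a)]
    if b_labels is None:
        b_labels = [f"B{j}" for j in range(b)]
    pairs = list(itertools.combinations(range(a), 2))
    if m_comparisons is None:
        m_comparisons = len(pairs) * b
    comparisons = []
    for j in range(b):
        for i1, i2 in pairs:
            diff = float(mean_ab[i1, j] - mean_ab[i2, j])
            if ms_within == 0:
                p = 0.0 if diff != 0 else 1.0
            else:
                t = diff / math.sqrt(ms_within * 2.0 / r)
                p = float(2 * sps.t.sf(abs(t), df["within"]))
            p_adj = min(1.0, m_comparisons * p)
            comparisons.append(
                {
                    "within": b_labels[j],
                    "a": a_labels[i1],
                    "b": a_labels[i2],
                    "mean_diff": diff,
                    "p": p,
                    "p_adj": p_adj,
                    "stars": significance_stars(p_adj),
                }
            )
    return TwoWayAnovaResult(effects=effects, comparisons=comparisons,
                             m_comparisons=m_comparisons)


def bonferroni_adjust(p: float, m: int) -> float:
    """Per-comparison Bonferroni adjustment: min(1, m * p)."""
    return min(1.0, m * p)
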