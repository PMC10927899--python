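"""Statistical comparison of fitted diffusion coefficients across conditions.

The decision tree mirrors common practice for small groups of replicate
measurements: Shapiro–Wilk normality per group at α = 0.05; if both groups
pass, an F-test on variances chooses between the pooled and the Welch
unpaired t-test; if either fails, the comparison falls back to the
rank-based path (Mann–Whitney for two groups, Kruskal–Wallis with Dunn's
post hoc versus a control for three or more). Groups can also be given as
(n, mean, sd) summaries, in which case the gates cannot run and the t-test
variant must be named explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "StatsReport",
    "compare_two_groups",
    "compare_variability",
    "compare_many_groups",
    "dunn_posthoc",
]

ALPHA = 0.05


@dataclass
class GroupSummary:
    """A labelled group of D_app replicates, raw or summarized."""

    label: str
    values: Optional[np.ndarray] = None
    n: Optional[int] = None
    mean: Optional[float] = None
    sd: Optional[float] = None

    def __post_init__(self):
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)
            self.n = int(self.values.size)
            self.mean = float(self.values.mean())
            self.sd = float(self.values.std(ddof=1)) if self.n > 1 else 0.0
        if self.n is None or self.mean is None or self.sd is None:
            raise ValueError("provide raw values or a complete (n, mean, sd) summary")
        if self.n < 2:
            raise ValueError("groups must have n >= 2")

    @property
    def has_raw(self) -> bool:
        return self.values is not None

    @property
    def cv_percent(self) -> float:
        return 100.0 * self.sd / self.mean


@dataclass
class StatsReport:
    comparison: str
    test_used: str
    statistic: float
    p_value: float
    gates: Dict[str, float] = field(default_factory=dict)
    alpha: float = ALPHA
    extra: Dict[str, float] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "test_used": self.test_used,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "significant": self.significant,
            "alpha": self.alpha,
            "gates": self.gates,
            **self.extra,
        }


def _t_from_summary(a: GroupSummary, b: GroupSummary, equal_var: bool):
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=equal_var
    )
    return float(res.statistic), float(res.pvalue)


def _f_test(a: GroupSummary, b: GroupSummary):
    """Two-sided F-test on variances; symmetric in the argument order."""
    if a.sd == 0 or b.sd == 0:
        raise ValueError("F-test requires non-zero variance in both groups")
    F = a.sd**2 / b.sd**2
    dfn, dfd = a.n - 1, b.n - 1
    cdf = stats.f.cdf(F, dfn, dfd)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return float(F), float(min(p, 1.0))


def compare_two_groups(
    a: GroupSummary,
    b: GroupSummary,
    alpha: float = ALPHA,
    test: Optional[str] = None,
) -> StatsReport:
    """Two-group comparison following the normality/variance decision tree.

    With raw values the path is data-driven; with summaries only, ``test``
    must name ``"pooled"`` or ``"welch"`` explicitly (the gates need raw
    data). An explicit ``test`` also overrides the gates on raw data.
    """
    label = f"{a.label} vs {b.label}"
    gates: Dict[str, float] = {}
    if test is None:
        if not (a.has_raw and b.has_raw):
            raise ValueError("summary-only groups need an explicit test ('pooled' or 'welch')")
        if a.n < 3 or b.n < 3:
            raise ValueError("Shapiro-Wilk gate needs n >= 3 in both groups")
        p_sw_a = float(stats.shapiro(a.values).pvalue)
        p_sw_b = float(stats.shapiro(b.values).pvalue)
        gates["shapiro_p_a"] = p_sw_a
        gates["shapiro_p_b"] = p_sw_b
        if p_sw_a < alpha or p_sw_b < alpha:
            test = "mann-whitney"
        else:
            F, p_f = _f_test(a, b)
            gates["f_statistic"] = F
            gates["f_p"] = p_f
            test = "welch" if p_f < alpha else "pooled"
    if test == "pooled":
        stat, p = _t_from_summary(a, b, equal_var=True)
        name = "pooled t-test"
    elif test == "welch":
        stat, p = _t_from_summary(a, b, equal_var=False)
        name = "Welch t-test"
    elif test == "mann-whitney":
        if not (a.has_raw and b.has_raw):
            raise ValueError("rank tests need raw values")
        res = stats.mannwhitneyu(a.values, b.values, alternative="two-sided")
        stat, p, name = float(res.statistic), float(res.pvalue), "Mann-Whitney U"
    else:
        raise ValueError(f"unknown test {test!r}")
    return StatsReport(
        comparison=label, test_used=name, statistic=stat, p_value=p, gates=gates, alpha=alpha
    )


def compare_variability(a: GroupSummary, b: GroupSummary, alpha: float = ALPHA) -> StatsReport:
    """Two-sided F-test on variances, with the CV% of each group reported."""
    F, p = _f_test(a, b)
    return StatsReport(
        comparison=f"{a.label} vs {b.label} (variability)",
        test_used="F-test on variances",
        statistic=F,
        p_value=p,
        alpha=alpha,
        extra={"cv_percent_a": a.cv_percent, "cv_percent_b": b.cv_percent},
    )


def dunn_posthoc(
    groups: Sequence[GroupSummary], control_label: str, adjust: str = "bonferroni"
) -> List[StatsReport]:
    """Dunn's rank-based multiple comparisons of each group against a
    control, Bonferroni-adjusted over the family of contrasts (the default
    of the commercial package commonly used for this design)."""
    raw = [g.values for g in groups]
    labels = [g.label for g in groups]
    if control_label not in labels:
        raise ValueError(f"control {control_label!r} not among groups")
    pooled = np.concatenate(raw)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g, lab in zip(raw, labels):
        mean_ranks[lab] = ranks[start : start + g.size].mean()
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_corr = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    var_factor = N * (N + 1) / 12.0 - tie_corr
    ci = next(g for g in groups if g.label == control_label)
    others = [g for g in groups if g.label != control_label]
    m = len(others)
    reports = []
    for g in others:
        se = np.sqrt(var_factor * (1.0 / ci.n + 1.0 / g.n))
        z = (mean_ranks[g.label] - mean_ranks[control_label]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p * m) if adjust == "bonferroni" else p
        reports.append(
            StatsReport(
                comparison=f"{g.label} vs {control_label} (Dunn)",
                test_used=f"Dunn post hoc ({adjust})",
                statistic=float(z),
                p_value=float(p_adj),
                extra={"p_unadjusted": float(p)},
            )
        )
    return reports


def compare_many_groups(
    groups: Sequence[GroupSummary], control_label: str, alpha: float = ALPHA
) -> List[StatsReport]:
    """Kruskal–Wallis omnibus plus Dunn's post hoc versus the control.

    Returns the omnibus report first, then one report per contrast with the
    multiplicity-adjusted p value.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups; use compare_two_groups for two")
    if not all(g.has_raw for g in groups):
        raise ValueError("Kruskal-Wallis needs raw values in every group")
    H, p = stats.kruskal(*[g.values for g in groups])
    omnibus = StatsReport(
        comparison=" / ".join(g.label for g in groups),
        test_used="Kruskal-Wallis",
        statistic=float(H),
        p_value=float(p),
        alpha=alpha,
    )
    return [omnibus] + dunn_posthoc(groups, control_label)
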