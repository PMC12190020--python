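"""Between-sample comparison of TEAC values.

The comparison protocol mirrors common chemometrics practice: a Cochran C
test first checks that the group variances are homogeneous, a one-way
ANOVA F test then asks whether any group means differ, and a multiple-range
test (Fisher's LSD by default, Tukey HSD as an option) partitions the
groups into homogeneous subsets. All statistics are computable from
summary statistics (n, mean, sd) alone, so published tables can be
re-analysed without the raw replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataValidationError

#: p-values below this are floored for display (full value kept internally)
P_FLOOR = 1e-12


@dataclass(frozen=True)
class GroupSummary:
    """Replicate count, mean and sample SD for one group."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DataValidationError(f"group {self.label!r}: n must be >= 2")
        if self.sd < 0 or not math.isfinite(self.sd):
            raise DataValidationError(f"group {self.label!r}: invalid sd {self.sd}")

    @property
    def variance(self) -> float:
        return self.sd**2


def summarize_groups(raw: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    out = []
    for label, vals in raw.items():
        v = np.asarray(list(vals), dtype=float)
        if v.size < 2:
            raise DataValidationError(f"group {label!r} has n < 2")
        out.append(GroupSummary(str(label), int(v.size), float(v.mean()), float(v.std(ddof=1))))
    return out


def _coerce_groups(groups) -> list[GroupSummary]:
    if isinstance(groups, Mapping):
        return summarize_groups(groups)
    gs = list(groups)
    if all(isinstance(g, GroupSummary) for g in gs):
        return gs
    raise ConfigurationError(
        "groups must be a mapping label -> replicates or a list of GroupSummary"
    )


@dataclass
class CochranResult:
    statistic: float
    critical: float
    alpha: float
    k: int
    n: int
    homogeneous: bool


def cochran_c(
    variances: Sequence[float] | None = None,
    n: int | None = None,
    alpha: float = 0.05,
    groups: Iterable[GroupSummary] | None = None,
) -> CochranResult:
    """Cochran's C test for homogeneity of k group variances (equal n).

    C = max(var_i) / sum(var_i). The critical value follows from the F
    distribution: C_crit = [1 + (k-1)/F(alpha/k; n-1, (k-1)(n-1))]^-1,
    where F(q; d1, d2) is the upper-q quantile. The test is undefined for
    unequal replicate counts.
    """
    if groups is not None:
        gs = list(groups)
        ns = {g.n for g in gs}
        if len(ns) != 1:
            raise DataValidationError("Cochran's C requires equal n in all groups")
        variances = [g.variance for g in gs]
        n = ns.pop()
    if variances is None or n is None:
        raise ConfigurationError("provide either (variances, n) or groups")
    v = np.asarray(list(variances), dtype=float)
    k = v.size
    if k < 2:
        raise DataValidationError("Cochran's C needs >= 2 groups")
    if np.any(v < 0):
        raise DataValidationError("negative variance")
    total = v.sum()
    if total == 0:
        raise DataValidationError("all variances are zero; C undefined")
    c = float(v.max() / total)
    fq = stats.f.ppf(1.0 - alpha / k, n - 1, (k - 1) * (n - 1))
    crit = float(1.0 / (1.0 + (k - 1) / fq))
    return CochranResult(
        statistic=c, critical=crit, alpha=alpha, k=k, n=n, homogeneous=c < crit
    )


@dataclass
class AnovaResult:
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    ms_between: float
    ms_within: float

    @property
    def p_display(self) -> float:
        return max(self.p_value, P_FLOOR)


def oneway_f(groups) -> AnovaResult:
    """One-way ANOVA from raw replicates or from (n, mean, sd) summaries.

    The between/within sum-of-squares decomposition only needs the group
    summaries, so both input forms give identical results.
    """
    gs = _coerce_groups(groups)
    if len(gs) < 2:
        raise DataValidationError("ANOVA needs >= 2 groups")
    N = sum(g.n for g in gs)
    grand = sum(g.n * g.mean for g in gs) / N
    ssb = sum(g.n * (g.mean - grand) ** 2 for g in gs)
    ssw = sum((g.n - 1) * g.variance for g in gs)
    dfb = len(gs) - 1
    dfw = N - len(gs)
    msb = ssb / dfb
    msw = ssw / dfw
    if msw == 0:
        f = math.inf if msb > 0 else 0.0
        p = 0.0 if msb > 0 else 1.0
    else:
        f = msb / msw
        p = float(stats.f.sf(f, dfb, dfw))
    return AnovaResult(
        f_stat=float(f), p_value=p, df_between=dfb, df_within=dfw,
        ss_between=float(ssb), ss_within=float(ssw),
        ms_between=float(msb), ms_within=float(msw),
    )


@dataclass
class SubsetsResult:
    subsets: list[list[str]]            # homogeneous subsets, means ascending
    order: list[str]                    # group labels sorted by mean
    significant_pairs: list[tuple[str, str]]
    method: str
    alpha: float
    critical_difference: dict[str, float] = field(default_factory=dict)


def _pairwise_critical(g1: GroupSummary, g2: GroupSummary, msw: float, dfw: int,
                       alpha: float, k: int, method: str) -> float:
    se = math.sqrt(msw * (1.0 / g1.n + 1.0 / g2.n))
    if method == "lsd":
        return stats.t.ppf(1.0 - alpha / 2.0, dfw) * se
    if method == "tukey":
        # studentized range statistic; se already carries the 1/ni+1/nj factor
        return stats.studentized_range.ppf(1.0 - alpha, k, dfw) * se / math.sqrt(2.0)
    raise ConfigurationError(f"unknown multiple-range method {method!r}")


def lsd_subsets(groups, alpha: float = 0.05, method: str = "lsd") -> SubsetsResult:
    """Multiple-range test producing homogeneous subsets.

    Pairwise comparisons use the pooled within-group mean square from the
    one-way ANOVA. Groups are sorted by mean and merged into maximal runs
    of mutually non-significant groups; every group appears in at least
    one subset.
    """
    gs = sorted(_coerce_groups(groups), key=lambda g: g.mean)
    anova = oneway_f(gs)
    k = len(gs)
    sig = np.zeros((k, k), dtype=bool)
    sig_pairs = []
    crit_map = {}
    for i in range(k):
        for j in range(i + 1, k):
            crit = _pairwise_critical(gs[i], gs[j], anova.ms_within,
                                      anova.df_within, alpha, k, method)
            crit_map[f"{gs[i].label}|{gs[j].label}"] = crit
            if abs(gs[i].mean - gs[j].mean) > crit:
                sig[i, j] = sig[j, i] = True
                sig_pairs.append((gs[i].label, gs[j].label))
    # maximal runs of consecutive (mean-ordered) mutually homogeneous groups
    subsets: list[list[str]] = []
    for i in range(k):
        j = i
        while j + 1 < k and not sig[i : j + 2, i : j + 2].any():
            j += 1
        run = [g.label for g in gs[i : j + 1]]
        if not subsets or not set(run).issubset(set(subsets[-1])):
            subsets.append(run)
    # drop runs contained in an earlier maximal run
    maximal = [s for s in subsets if not any(
        set(s) < set(t) for t in subsets if s is not t
    )]
    return SubsetsResult(
        subsets=maximal,
        order=[g.label for g in gs],
        significant_pairs=sig_pairs,
        method=method,
        alpha=alpha,
        critical_difference=crit_map,
    )


@dataclass
class ComparisonReport:
    groups: list[GroupSummary]
    cochran: CochranResult
    anova: AnovaResult
    subsets: SubsetsResult
    alpha: float
    method: str


class AntioxidantComparison:
    """Model object for comparing TEAC across sample groups.

    Accepts raw replicates (mapping label -> values) or summary statistics
    (list of :class:`GroupSummary`); ``fit`` runs the Cochran C test, the
    one-way ANOVA and the multiple-range test.
    """

    def __init__(self, groups):
        self.groups = _coerce_groups(groups)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, default_n: int = 3) -> "AntioxidantComparison":
        if {"replicate", "teac"}.issubset(df.columns):
            raw = {lab: grp["teac"].to_numpy() for lab, grp in df.groupby("label")}
            return cls(raw)
        if {"mean", "sd"}.issubset(df.columns):
            gs = [
                GroupSummary(
                    str(r["label"]),
                    int(r["n"]) if "n" in df.columns and not pd.isna(r.get("n")) else default_n,
                    float(r["mean"]), float(r["sd"]),
                )
                for _, r in df.iterrows()
            ]
            return cls(gs)
        raise ConfigurationError("dataframe needs (label,replicate,teac) or (label,n,mean,sd)")

    def fit(self, alpha: float = 0.05, method: str = "lsd") -> "ComparisonResults":
        cochran = cochran_c(groups=self.groups, alpha=alpha)
        anova = oneway_f(self.groups)
        subsets = lsd_subsets(self.groups, alpha=alpha, method=method)
        return ComparisonResults(
            ComparisonReport(
                groups=self.groups, cochran=cochran, anova=anova,
                subsets=subsets, alpha=alpha, method=method,
            )
        )


class ComparisonResults:
    def __init__(self, report: ComparisonReport):
        self.report = report

    @property
    def cochran(self) -> CochranResult:
        return self.report.cochran

    @property
    def anova(self) -> AnovaResult:
        return self.report.anova

    @property
    def subsets(self) -> list[list[str]]:
        return self.report.subsets.subsets

    def summary(self) -> str:
        r = self.report
        lines = ["TEAC group comparison"]
        for g in sorted(r.groups, key=lambda g: g.mean):
            lines.append(f"  {g.label}: {g.mean:.4g} +/- {g.sd:.4g} (n={g.n})")
        lines += [
            f"  Cochran C = {r.cochran.statistic:.3f} "
            f"(crit {r.cochran.critical:.3f}, alpha {r.cochran.alpha:g}) -> "
            + ("homogeneous" if r.cochran.homogeneous else "heterogeneous"),
            f"  one-way F({r.anova.df_between},{r.anova.df_within}) = "
            f"{r.anova.f_stat:.3f}, p = {r.anova.p_display:.3g}",
            f"  homogeneous subsets ({r.method}, alpha {r.alpha:g}): "
            + "; ".join("{" + ", ".join(s) + "}" for s in r.subsets.subsets),
        ]
        return "\n".join(lines)
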