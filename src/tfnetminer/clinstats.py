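"""qPCR quantification and clinicopathological association statistics.

Expression is quantified as dCt = Ct(target) - Ct(reference); a smaller
dCt means higher expression.  Relative expression between conditions is
2**(-ddCt).  The module provides the paired and independent t-tests,
rank-sum test, summary-statistics t-test/ANOVA (for association tables
published as per-group n / mean / SD triplets), Pearson correlation and
rank-based ROC AUC used to associate expression with clinical variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    """Per-group summary triplet in dCt units."""

    label: str
    n: int
    mean: float
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.sd is not None and self.sd < 0:
            raise ValueError("negative SD")
        if self.n >= 2 and self.sd is None:
            raise ValueError(f"group {self.label!r}: SD required for n >= 2")

    @classmethod
    def from_values(cls, label: str, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        sd = float(v.std(ddof=1)) if len(v) >= 2 else None
        return cls(label, len(v), float(v.mean()), sd)


def delta_ct(ct_target, ct_reference):
    """dCt = Ct(target) - Ct(reference); elementwise on arrays."""
    t = np.asarray(ct_target, dtype=float)
    r = np.asarray(ct_reference, dtype=float)
    if not (np.isfinite(t).all() and np.isfinite(r).all()):
        raise ValueError("missing or non-finite Ct values")
    out = t - r
    return float(out) if out.ndim == 0 else out


def fold_change(ddct):
    """Relative expression 2**(-ddCt)."""
    return 2.0 ** (-np.asarray(ddct, dtype=float)) if np.ndim(ddct) else float(2.0 ** (-ddct))


def paired_ttest(case, control):
    """Two-sided paired t-test; returns (t, df, p, degenerate_flag).

    Degenerate inputs (all pairwise differences identical) cannot support
    a t statistic: all-zero differences report p = 1, constant non-zero
    differences report p = 0, both flagged.
    """
    a = np.asarray(case, dtype=float)
    b = np.asarray(control, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    df = len(d) - 1
    if np.ptp(d) == 0:
        return 0.0, df, (1.0 if d[0] == 0 else 0.0), True
    res = stats.ttest_rel(a, b)
    return float(res.statistic), df, float(res.pvalue), False


def ranksum(group_a, group_b):
    """Two-sided Mann-Whitney test; returns (U, p).

    Exact enumeration when both groups have <= 8 observations and no
    ties span the groups; otherwise the tie-corrected normal
    approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def ttest_from_summary(g1: GroupSummary, g2: GroupSummary, pooled: bool = True):
    """Two-sided two-sample t-test from (n, mean, SD) triplets.

    Pooled variance by default (the convention that reproduces published
    association tables); Welch with ``pooled=False``.  Returns
    (t, df, p, degenerate_flag).
    """
    for g in (g1, g2):
        if g.n < 2:
            raise ValueError(f"group {g.label!r} needs n >= 2 for a t-test")
    if g1.sd == 0 and g2.sd == 0:
        if g1.mean == g2.mean:
            return 0.0, g1.n + g2.n - 2, 1.0, True
        return np.inf if g1.mean > g2.mean else -np.inf, g1.n + g2.n - 2, 0.0, True
    res = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=pooled
    )
    if pooled:
        df = g1.n + g2.n - 2
    else:
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return float(res.statistic), float(df), float(res.pvalue), False


def anova_from_summary(groups):
    """One-way ANOVA from per-group (n, mean, SD) triplets.

    Between-group sum of squares is taken about the weighted grand mean;
    within-group sum of squares is sum((n_i - 1) * sd_i**2), groups of
    n = 1 contributing zero.  Returns (F, df1, df2, p).
    """
    groups = list(groups)
    if len(groups) < 3:
        raise ValueError("ANOVA here requires >= 3 groups (use a t-test for 2)")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups], dtype=float)
    sds = np.array([g.sd if g.sd is not None else 0.0 for g in groups], dtype=float)
    n_total, k = ns.sum(), len(groups)
    if n_total <= k:
        raise ValueError("no residual degrees of freedom")
    grand = (ns * means).sum() / n_total
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df1, df2 = k - 1, int(n_total) - k
    if ssw == 0:
        return (np.inf if ssb > 0 else 0.0), df1, df2, (0.0 if ssb > 0 else 1.0)
    f = (ssb / df1) / (ssw / df2)
    return float(f), df1, df2, float(stats.f.sf(f, df1, df2))


def pearson_corr(x, y):
    """Pearson correlation with its two-sided t-transform p; (r, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def roc_auc(case_scores, control_scores, smaller_is_positive: bool = True):
    """Rank-based AUC: P(case outranks control) + 0.5 * P(tie).

    With ``smaller_is_positive`` (the dCt convention: lower dCt = higher
    expression = more case-like) a smaller score counts toward the case.
    """
    case = np.asarray(case_scores, dtype=float)
    control = np.asarray(control_scores, dtype=float)
    if len(case) == 0 or len(control) == 0:
        raise ValueError("empty group")
    if smaller_is_positive:
        case, control = -case, -control
    ranks = stats.rankdata(np.concatenate([case, control]))
    r_case = ranks[: len(case)].sum()
    return float((r_case - len(case) * (len(case) + 1) / 2) / (len(case) * len(control)))


def association_table(
    clinical: pd.DataFrame,
    covariates,
    value_column: str = "dct_tumor",
    pooled: bool = True,
) -> pd.DataFrame:
    """Association of a dCt value with each clinical covariate.

    Per covariate level: n, percentage, mean +/- SD of ``value_column``.
    Covariates with two levels are tested by the summary-statistics
    t-test, three or more by one-way ANOVA; single-level covariates get
    no test.  Stars mark p < 0.05.
    """
    rows = []
    for cov in covariates:
        if cov not in clinical.columns:
            raise ValueError(f"covariate {cov!r} absent from table")
        levels = sorted(clinical[cov].dropna().unique())
        summaries = [
            GroupSummary.from_values(str(lv), clinical.loc[clinical[cov] == lv, value_column])
            for lv in levels
        ]
        if len(summaries) < 2:
            p = None
        elif len(summaries) == 2:
            _, _, p, _ = ttest_from_summary(summaries[0], summaries[1], pooled=pooled)
        else:
            _, _, _, p = anova_from_summary(summaries)
        n_total = sum(s.n for s in summaries)
        for i, s in enumerate(summaries):
            rows.append(
                {
                    "covariate": cov,
                    "level": s.label,
                    "n": s.n,
                    "pct": 100.0 * s.n / n_total,
                    "mean": s.mean,
                    "sd": s.sd,
                    "p": p if i == 0 else None,
                    "significant": (p is not None and p < 0.05) if i == 0 else None,
                }
            )
    return pd.DataFrame(rows)
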