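"""Group-level statistics for saccadic latency modulation.

Covers every test the analysis uses: per-subject task means and the
saccadic latency difference SLD = SL(color) - SL(landolt); percent latency
reduction; paired and Welch t-tests; RMS-pooled paired Cohen's d; Levene's
variance test; Wilcoxon signed-rank and rank-sum tests (R's V and W
conventions); Pearson chi-square on contingency tables; a mixed-design
ANOVA (between factor group, within factor task); Pearson correlation; and
paired-t power from the noncentral t distribution.

Standard tests delegate to scipy / pingouin; only quantities specific to
this analysis (SLD, percent reduction, the RMS-pooled d) are computed
directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

TASKS = ("color", "landolt")


@dataclass(frozen=True)
class TestResult:
    """A named test statistic with df, p-value, tails and optional effect size."""

    name: str
    statistic: float
    df: float | tuple | None
    p_value: float
    tails: int = 2
    effect_size: float | None = None
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "statistic": float(self.statistic),
            "df": self.df if not isinstance(self.df, tuple) else list(self.df),
            "p_value": float(self.p_value),
            "tails": self.tails,
        }
        if self.effect_size is not None:
            d["effect_size"] = float(self.effect_size)
        d.update({k: v for k, v in self.details.items()})
        return d


def task_means(records: pd.DataFrame, behavior: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-subject mean latency per task, with the SLD attached.

    ``records`` needs columns ``subject_id, group, task, latency_ms, valid``.
    Only valid trials enter the means.  Subjects missing a task entirely are
    excluded with a warning.  If a ``behavior`` table (columns
    ``subject_id, task, correct, response_time_ms``) is given, per-task
    accuracy and mean response time are attached as well.
    """
    import warnings

    valid = records[records["valid"].astype(bool)]
    wide = (valid.groupby(["subject_id", "task"])["latency_ms"].mean()
            .unstack())
    for t in TASKS:
        if t not in wide.columns:
            wide[t] = np.nan
    incomplete = wide[wide[list(TASKS)].isna().any(axis=1)].index
    if len(incomplete):
        warnings.warn(
            f"excluding {len(incomplete)} subject(s) missing a task: "
            f"{sorted(incomplete)}", stacklevel=2)
        wide = wide.drop(index=incomplete)
    groups = records.drop_duplicates("subject_id").set_index("subject_id")["group"]
    out = pd.DataFrame({
        "group": groups.reindex(wide.index),
        "sl_color": wide["color"],
        "sl_landolt": wide["landolt"],
    })
    out["sld"] = out["sl_color"] - out["sl_landolt"]
    if behavior is not None:
        acc = behavior.groupby(["subject_id", "task"])["correct"].mean().unstack()
        rt = behavior.groupby(["subject_id", "task"])["response_time_ms"].mean().unstack()
        for t in TASKS:
            out[f"acc_{t}"] = acc[t].reindex(out.index)
            out[f"rt_{t}"] = rt[t].reindex(out.index)
    out.index.name = "subject_id"
    return out


def percent_reduction(mean_color: float, mean_landolt: float) -> float:
    """Percent latency reduction in the Landolt task relative to color."""
    if mean_color <= 0:
        raise ValueError("mean_color must be positive")
    return 100.0 * (mean_color - mean_landolt) / mean_color


def paired_t(a, b, tails: int = 2) -> TestResult:
    """Classic paired t-test on the differences a - b, df = n - 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("paired samples must have equal length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero variance of paired differences")
    res = st.ttest_rel(a, b)
    p = float(res.pvalue) if tails == 2 else float(st.t.sf(abs(res.statistic), len(a) - 1))
    return TestResult("paired t", float(res.statistic), len(a) - 1, p, tails)


def welch_t(a, b, tails: int = 2) -> TestResult:
    """Welch two-sample t-test with Welch-Satterthwaite fractional df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance")
    res = st.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa ** 2 / (len(a) - 1) + sb ** 2 / (len(b) - 1))
    p = float(res.pvalue) if tails == 2 else float(st.t.sf(abs(res.statistic), df))
    return TestResult("Welch t", float(res.statistic), float(df), p, tails)


def cohens_d_paired(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """Standardized mean difference with the RMS of the two condition SDs.

    d = (mean_a - mean_b) / sqrt((sd_a^2 + sd_b^2) / 2).
    """
    if sd_a < 0 or sd_b < 0:
        raise ValueError("SDs must be non-negative")
    if sd_a == 0 and sd_b == 0:
        raise ValueError("both SDs are zero")
    return (mean_a - mean_b) / np.sqrt((sd_a ** 2 + sd_b ** 2) / 2.0)


def levene_test(a, b, center: str = "mean") -> TestResult:
    """Levene's test for equal variances, df = (1, n1 + n2 - 2).

    ``center='mean'`` is the classic Levene test (ANOVA on absolute
    deviations from the group mean); ``'median'`` gives Brown-Forsythe.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need >= 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and np.isclose(a.mean(), b.mean()):
        raise ValueError("degenerate samples")
    stat, p = st.levene(a, b, center=center)
    return TestResult("Levene F", float(stat), (1, len(a) + len(b) - 2), float(p))


def rank_tests(a, b=None, paired: bool = False, tails: int = 2) -> TestResult:
    """Wilcoxon signed-rank V (paired) or rank-sum W (unpaired), R convention.

    The paired statistic is V, the sum of ranks of positive differences
    (zeros dropped); the unpaired statistic is W, the Mann-Whitney U of the
    first sample.  p-values are exact where the sample permits (n <= 25, no
    ties/zeros for the signed-rank test), otherwise a tie-corrected normal
    approximation is used.
    """
    a = np.asarray(a, dtype=float)
    if paired:
        if b is None:
            d = a
        else:
            b = np.asarray(b, dtype=float)
            if len(a) != len(b):
                raise ValueError("paired samples must have equal length")
            d = a - b
        d = d[d != 0]
        if len(d) == 0:
            raise ValueError("all paired differences are zero")
        ranks = st.rankdata(np.abs(d))
        v = float(ranks[d > 0].sum())
        exact_ok = len(d) <= 25 and len(np.unique(np.abs(d))) == len(d)
        method = "exact" if exact_ok else "approx"
        alternative = "two-sided" if tails == 2 else "greater"
        res = st.wilcoxon(d, alternative=alternative, method=method)
        return TestResult("Wilcoxon V", v, None, float(res.pvalue), tails,
                          details={"n": int(len(d)), "method": method})
    if b is None:
        raise ValueError("unpaired test needs two samples")
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    alternative = "two-sided" if tails == 2 else "greater"
    method = "exact" if (len(a) <= 25 and len(b) <= 25
                         and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)) \
        else "asymptotic"
    res = st.mannwhitneyu(a, b, alternative=alternative, method=method)
    return TestResult("Wilcoxon W", float(res.statistic), None, float(res.pvalue),
                      tails, details={"method": method})


def chi_square_independence(table) -> TestResult:
    """Pearson chi-square of independence, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, df, _ = st.chi2_contingency(table, correction=False)
    return TestResult("chi-square", float(chi2), int(df), float(p))


def mixed_anova(data: pd.DataFrame, dv: str, within: str = "task",
                subject: str = "subject_id", between: str = "group") -> list[TestResult]:
    """Mixed-design ANOVA: between factor group, within factor task.

    Subjects-within-groups is the error term for the group effect; the
    task-by-subjects interaction is the error term for task and for the
    task x group interaction.  With N subjects and g groups the df are
    (g-1, N-g) for group, (1, N-g) for a two-level task factor, and
    (g-1, N-g) for the interaction.  Subjects missing a task level are
    excluded.  Delegates to ``pingouin.mixed_anova``.
    """
    import pingouin as pg

    counts = data.groupby(subject)[within].nunique()
    complete = counts[counts == data[within].nunique()].index
    data = data[data[subject].isin(complete)]
    if data[between].nunique() < 2:
        raise ValueError("need >= 2 groups")
    aov = pg.mixed_anova(data=data, dv=dv, within=within,
                         subject=subject, between=between)
    name_map = {"group": between, "task": within,
                "interaction": f"{within} x {between}"}
    out = []
    for _, row in aov.iterrows():
        source = str(row["Source"]).lower()
        label = name_map.get(source, f"{within} x {between}")
        f, p = float(row["F"]), float(row["p_unc"])
        if not np.isfinite(f) and np.isclose(float(row["SS"]), 0.0):
            f, p = 0.0, 1.0  # no effect variance at all
        out.append(TestResult(
            f"ANOVA {label}", f,
            (float(row["DF1"]), float(row["DF2"])), p,
            details={"np2": float(row["np2"])}))
    return out


def pearson_r(x, y, tails: int = 2) -> TestResult:
    """Pearson correlation with t = r sqrt((n-2)/(1-r^2)), df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("zero variance")
    r, p2 = st.pearsonr(x, y)
    n = len(x)
    t = r * np.sqrt((n - 2) / (1 - r ** 2)) if abs(r) < 1 else np.inf
    p = float(p2) if tails == 2 else float(st.t.sf(abs(t), n - 2))
    return TestResult("Pearson r", float(t), n - 2, p, tails, effect_size=float(r))


def power_paired_t(d: float, n: int, alpha: float = 0.05, tails: int = 2) -> float:
    """Power of a paired t-test from the noncentral t distribution.

    Noncentrality ncp = d * sqrt(n) with df = n - 1; for a two-sided test
    both rejection tails count.  At d = 0 the power equals alpha.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    df = n - 1
    ncp = d * np.sqrt(n)
    if tails == 2:
        crit = st.t.ppf(1.0 - alpha / 2.0, df)
        power = st.nct.sf(crit, df, ncp) + st.nct.cdf(-crit, df, ncp)
    else:
        crit = st.t.ppf(1.0 - alpha, df)
        power = st.nct.sf(crit, df, ncp)
    if not np.isfinite(power):
        # noncentral-t tails underflow for large df/ncp; the normal
        # approximation is exact in that limit
        power = st.norm.sf(crit - ncp) + (st.norm.cdf(-crit - ncp)
                                          if tails == 2 else 0.0)
    return float(power)
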