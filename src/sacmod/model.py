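"""Fitted-model interface for the latency-modulation analysis.

``LatencyModulation`` is built from a trial-level latency table (and
optionally a behavioral table); ``fit()`` aggregates to subject task means
and runs the full battery of group statistics, returning a
``LatencyModulationResults`` with the estimates, the individual test
results and a ``summary()`` table.

The scientific question the model answers: does task demand modulate
saccadic latency (shorter SL under the higher-demand Landolt task), and is
that modulation — summarised per subject as the saccadic latency
difference SLD = SL(color) - SL(landolt) — reduced in patients relative to
controls and first-degree relatives?
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as sx

GROUP_ORDER = ("patient", "control", "relative")


class LatencyModulation:
    """Saccadic-latency modulation model over a cohort latency table.

    Parameters
    ----------
    latencies : DataFrame
        Trial-level table with columns ``subject_id, group, task,
        latency_ms, valid``.
    behavior : DataFrame, optional
        Trial-level table with ``subject_id, group, task, correct,
        response_time_ms`` for the accuracy / response-time analysis.
    sld_tails : int
        Tails for the between-group Welch tests on SLD.  Both tails are
        always computed and reported; this selects which is quoted as the
        headline p-value.
    levene_center : str
        'mean' for classic Levene, 'median' for Brown-Forsythe.
    """

    def __init__(self, latencies: pd.DataFrame, behavior: pd.DataFrame | None = None,
                 *, sld_tails: int = 1, levene_center: str = "mean"):
        required = {"subject_id", "group", "task", "latency_ms", "valid"}
        missing = required - set(latencies.columns)
        if missing:
            raise ValueError(f"latency table is missing columns: {sorted(missing)}")
        self.latencies = latencies
        self.behavior = behavior
        self.sld_tails = sld_tails
        self.levene_center = levene_center

    @classmethod
    def from_cohort(cls, dataset, **kwargs) -> "LatencyModulation":
        """Build from a simulated ``CohortDataset`` using true latencies."""
        return cls(dataset.latency_table(), dataset.behavior_table(), **kwargs)

    def fit(self) -> "LatencyModulationResults":
        summaries = sx.task_means(self.latencies, self.behavior)
        groups = [g for g in GROUP_ORDER if g in set(summaries["group"])]
        groups += sorted(set(summaries["group"]) - set(groups))

        group_table = pd.DataFrame(index=pd.Index(groups, name="group"))
        tests: dict[str, sx.TestResult] = {}
        for g in groups:
            sub = summaries[summaries["group"] == g]
            mc, ml = sub["sl_color"].mean(), sub["sl_landolt"].mean()
            sc, sl = sub["sl_color"].std(ddof=1), sub["sl_landolt"].std(ddof=1)
            group_table.loc[g, "n"] = len(sub)
            group_table.loc[g, "sl_color_mean"] = mc
            group_table.loc[g, "sl_color_sd"] = sc
            group_table.loc[g, "sl_landolt_mean"] = ml
            group_table.loc[g, "sl_landolt_sd"] = sl
            group_table.loc[g, "sld"] = mc - ml
            group_table.loc[g, "pct_reduction"] = sx.percent_reduction(mc, ml)
            group_table.loc[g, "cohens_d"] = sx.cohens_d_paired(mc, sc, ml, sl)
            if len(sub) >= 2:
                tests[f"paired t {g}"] = sx.paired_t(sub["sl_color"], sub["sl_landolt"])
            if len(sub) >= 3:  # Levene is degenerate on two-point samples
                tests[f"levene {g}"] = sx.levene_test(
                    sub["sl_color"], sub["sl_landolt"], center=self.levene_center)
        group_table["n"] = group_table["n"].astype(int)

        for i, g1 in enumerate(groups):
            for g2 in groups[i + 1:]:
                a = summaries.loc[summaries["group"] == g1, "sld"]
                b = summaries.loc[summaries["group"] == g2, "sld"]
                if len(a) < 2 or len(b) < 2:
                    continue
                two = sx.welch_t(a, b, tails=2)
                one = sx.welch_t(a, b, tails=1)
                headline = one if self.sld_tails == 1 else two
                d = sx.cohens_d_paired(a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1))
                tests[f"welch sld {g1} vs {g2}"] = sx.TestResult(
                    headline.name, headline.statistic, headline.df,
                    headline.p_value, headline.tails, effect_size=abs(d),
                    details={"p_two_sided": two.p_value, "p_one_sided": one.p_value})

        long = summaries.reset_index().melt(
            id_vars=["subject_id", "group"], value_vars=["sl_color", "sl_landolt"],
            var_name="task", value_name="sl")
        long["task"] = long["task"].str.replace("sl_", "", regex=False)
        if len(groups) >= 2:
            for res in sx.mixed_anova(long, dv="sl"):
                tests[f"sl {res.name}"] = res

        if self.behavior is not None and {"rt_color", "rt_landolt"} <= set(summaries.columns):
            rt_long = summaries.reset_index().melt(
                id_vars=["subject_id", "group"], value_vars=["rt_color", "rt_landolt"],
                var_name="task", value_name="rt")
            rt_long["task"] = rt_long["task"].str.replace("rt_", "", regex=False)
            if len(groups) >= 2:
                for res in sx.mixed_anova(rt_long, dv="rt"):
                    tests[f"rt {res.name}"] = res
            for g in groups:
                sub = summaries[summaries["group"] == g]
                diffs = (sub["acc_color"] - sub["acc_landolt"]).to_numpy()
                if len(sub) >= 2 and np.any(diffs != 0):
                    tests[f"wilcoxon accuracy {g}"] = sx.rank_tests(
                        sub["acc_color"], sub["acc_landolt"], paired=True)

        return LatencyModulationResults(
            model=self, subject_summaries=summaries,
            group_table=group_table, tests=tests)


@dataclass
class LatencyModulationResults:
    """Estimates and test results from ``LatencyModulation.fit``."""

    model: LatencyModulation
    subject_summaries: pd.DataFrame
    group_table: pd.DataFrame
    tests: dict = field(default_factory=dict)

    def sld(self, group: str) -> float:
        return float(self.group_table.loc[group, "sld"])

    def correlate_with(self, covariate: pd.Series, group: str,
                       column: str = "sld") -> "sx.TestResult":
        """Correlate a per-subject covariate (e.g. medication dose) with SLD."""
        sub = self.subject_summaries[self.subject_summaries["group"] == group]
        joined = pd.concat([sub[column], covariate.reindex(sub.index)], axis=1).dropna()
        return sx.pearson_r(joined.iloc[:, 0], joined.iloc[:, 1])

    def to_dict(self) -> dict:
        return {
            "group_table": json.loads(self.group_table.to_json(orient="index")),
            "tests": {k: v.to_dict() for k, v in self.tests.items()},
        }

    def to_json(self, path=None, **kwargs) -> str | None:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    def summary(self) -> str:
        lines = ["Saccadic latency modulation", "=" * 60]
        g = self.group_table
        lines.append(f"{'group':<10}{'n':>4}{'color':>14}{'landolt':>14}"
                     f"{'SLD':>8}{'red.%':>8}{'d':>6}")
        for name, row in g.iterrows():
            lines.append(
                f"{name:<10}{int(row['n']):>4}"
                f"{row['sl_color_mean']:>8.0f}+-{row['sl_color_sd']:<4.0f}"
                f"{row['sl_landolt_mean']:>8.0f}+-{row['sl_landolt_sd']:<4.0f}"
                f"{row['sld']:>8.0f}{row['pct_reduction']:>8.1f}"
                f"{row['cohens_d']:>6.1f}")
        lines.append("-" * 60)
        for key, res in self.tests.items():
            df = res.df
            if isinstance(df, tuple):
                df = f"({df[0]:g}, {df[1]:g})"
            elif isinstance(df, float):
                df = f"{df:.1f}"
            lines.append(f"{key:<34} stat={res.statistic:>7.2f}  df={df}"
                         f"  p={res.p_value:.4g}")
        return "\n".join(lines)
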