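"""Group statistics across conditions and report assembly.

The omnibus path is normality-screened: if every group passes Shapiro-Wilk at
0.05 the one-way (Fisher) ANOVA is used, otherwise Kruskal-Wallis.  Post-hoc
pairwise tests (Tukey HSD after ANOVA, Dunn with Holm adjustment after
Kruskal-Wallis) run only when the omnibus test is significant at alpha=0.05.
Significance stars follow the usual convention: * p<0.05, ** p<0.01,
*** p<0.001.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ALPHA",
    "ComparisonResult",
    "compare_groups",
    "correlate",
    "chi_squared_independence",
    "stars",
    "build_report",
]

ALPHA = 0.05


def stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class ComparisonResult:
    metric: str
    region: str
    groups: list[str]
    omnibus_test: str
    omnibus_stat: float
    omnibus_p: float
    posthoc_test: str | None = None
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.omnibus_p < ALPHA

    def pairwise_stars(self) -> dict[tuple[str, str], str]:
        return {pair: stars(p) for pair, p in self.pairwise_p.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "metric": self.metric,
                "region": self.region,
                "group_a": a,
                "group_b": b,
                "omnibus_test": self.omnibus_test,
                "omnibus_p": self.omnibus_p,
                "posthoc_test": self.posthoc_test,
                "p_adjusted": p,
                "stars": stars(p),
            }
            for (a, b), p in self.pairwise_p.items()
        ]
        if not rows:
            rows = [
                {
                    "metric": self.metric,
                    "region": self.region,
                    "group_a": None,
                    "group_b": None,
                    "omnibus_test": self.omnibus_test,
                    "omnibus_p": self.omnibus_p,
                    "posthoc_test": None,
                    "p_adjusted": np.nan,
                    "stars": stars(self.omnibus_p),
                }
            ]
        return pd.DataFrame(rows)


def _holm(pvals: Sequence[float]) -> list[float]:
    m = len(pvals)
    order = np.argsort(pvals)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def _dunn(groups: Mapping[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Dunn's rank-based pairwise z-tests with tie correction (raw p-values)."""
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    n = all_vals.size
    ranks = stats.rankdata(all_vals)
    offsets = np.cumsum([0] + [groups[g].size for g in names])
    mean_rank = {
        g: ranks[offsets[i] : offsets[i + 1]].mean() for i, g in enumerate(names)
    }
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    out = {}
    for a, b in itertools.combinations(names, 2):
        na, nb = groups[a].size, groups[b].size
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_rank[a] - mean_rank[b]) / se
        out[(a, b)] = 2 * stats.norm.sf(abs(z))
    return out


def compare_groups(
    rows: pd.DataFrame,
    metric: str,
    region: str | None = None,
    group_col: str = "condition",
) -> ComparisonResult:
    """Omnibus + post-hoc comparison of ``metric`` across conditions.

    Rows with NaN metric values are dropped; every group must keep at least 3
    observations.
    """
    data = rows
    if region is not None and "region_group" in rows.columns:
        data = rows[rows["region_group"] == region]
    data = data[[group_col, metric]].dropna()
    groups = {
        str(name): grp[metric].to_numpy(float)
        for name, grp in data.groupby(group_col, sort=False)
    }
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    for name, vals in groups.items():
        if vals.size < 3:
            raise ValueError(f"group {name!r} has fewer than 3 observations")

    degenerate = all(np.ptp(v) == 0 for v in groups.values()) and (
        len({v[0] for v in groups.values()}) == 1
    )
    if degenerate:
        return ComparisonResult(metric, region or "all", list(groups),
                                "degenerate", 0.0, 1.0)

    normal = all(
        np.ptp(v) > 0 and stats.shapiro(v).pvalue >= ALPHA for v in groups.values()
    )
    vals = list(groups.values())
    if normal:
        stat, p = stats.f_oneway(*vals)
        test = "anova"
    else:
        stat, p = stats.kruskal(*vals)
        test = "kruskal-wallis"

    result = ComparisonResult(metric, region or "all", list(groups), test,
                              float(stat), float(p))
    if p < ALPHA:
        if test == "anova":
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            flat = data[metric].to_numpy(float)
            labels = data[group_col].astype(str).to_numpy()
            tk = pairwise_tukeyhsd(flat, labels, alpha=ALPHA)
            result.posthoc_test = "tukey-hsd"
            result.pairwise_p = {
                (row[0], row[1]): float(row[3])
                for row in tk._results_table.data[1:]
            }
        else:
            raw = _dunn(groups)
            adj = _holm(list(raw.values()))
            result.posthoc_test = "dunn-holm"
            result.pairwise_p = dict(zip(raw.keys(), adj))
    return result


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> tuple[float, float]:
    """Pearson or Spearman correlation with two-sided p-value.

    Returns (nan, nan) when either input has zero variance.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)


def chi_squared_independence(table: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """Chi-squared test of independence for a contingency table."""
    res = stats.chi2_contingency(np.asarray(table))
    return float(res.statistic), float(res.pvalue)


def build_report(
    metric_summary: pd.DataFrame,
    comparisons: Sequence[ComparisonResult],
    flow_tables: Mapping[str, pd.DataFrame] | None = None,
    nonlinear_summary: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    manifest: Mapping | None = None,
) -> str:
    """Assemble a Markdown report plus machine-readable CSV tables.

    Missing stages are reported as explicit gaps rather than silently
    dropped.  Returns the Markdown text; when ``out_dir`` is given the text
    and all tables are also written there.
    """
    lines = ["# Microcircuit condition comparison", ""]
    if manifest:
        lines += ["## Provenance", ""]
        lines += [f"- {k}: {v}" for k, v in manifest.items()]
        lines.append("")

    lines.append("## Neuronal metrics (mean over cells x runs)")
    lines.append("")
    if metric_summary is None or metric_summary.empty:
        lines.append("*GAP: no metric table supplied.*")
    else:
        lines.append(metric_summary.to_markdown(index=False, floatfmt=".1f"))
    lines.append("")

    lines.append("## Group comparisons")
    lines.append("")
    if not comparisons:
        lines.append("*GAP: no statistical comparisons supplied.*")
    else:
        cmp_table = pd.concat([c.to_frame() for c in comparisons], ignore_index=True)
        lines.append(cmp_table.to_markdown(index=False, floatfmt=".4f"))
    lines.append("")

    lines.append("## Nonlinear dynamics")
    lines.append("")
    if nonlinear_summary is None or nonlinear_summary.empty:
        lines.append("*GAP: no nonlinear-dynamics table supplied.*")
    else:
        lines.append(nonlinear_summary.to_markdown(index=False, floatfmt=".3f"))
    lines.append("")

    lines.append("## Information flow")
    lines.append("")
    if not flow_tables:
        lines.append("*GAP: no information-flow tables supplied.*")
    else:
        for name, tbl in flow_tables.items():
            lines += [f"### {name}", "", tbl.to_markdown(floatfmt=".4f"), ""]

    text = "\n".join(lines)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.md").write_text(text)
        if metric_summary is not None and not metric_summary.empty:
            metric_summary.to_csv(out / "metrics_summary.csv", index=False)
        if comparisons:
            pd.concat([c.to_frame() for c in comparisons], ignore_index=True).to_csv(
                out / "comparisons.csv", index=False
            )
        if nonlinear_summary is not None and not nonlinear_summary.empty:
            nonlinear_summary.to_csv(out / "nonlinear_summary.csv", index=False)
        for name, tbl in (flow_tables or {}).items():
            tbl.to_csv(out / f"{name}.csv")
    return text
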