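"""Formatting of analysis outputs into table-style human-readable text.

The renderer only formats numbers already present in the results bundle;
it performs no computation beyond rounding.  Percentages round half away
from zero to integers, descriptives render as ``mean (SD)``.
"""

from __future__ import annotations

import math

import pandas as pd

from .performance import METRIC_LABELS, PrevalenceEstimate


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def fmt_mean_sd(mean: float, sd: float, digits: int = 1) -> str:
    if mean is None or (isinstance(mean, float) and math.isnan(mean)):
        return "—"
    return f"{mean:.{digits}f} ({sd:.{digits}f})"


def fmt_prevalence(est) -> str:
    """Render a prevalence estimate as ``30% (23, 36)``; empty strata as ``—``."""
    if isinstance(est, PrevalenceEstimate):
        den, p, lo, hi = est.denominator, est.proportion, est.ci_low, est.ci_high
    else:  # mapping / namedtuple-style row
        den, p, lo, hi = est["denominator"], est["proportion"], est["ci_low"], est["ci_high"]
    if den == 0 or (isinstance(p, float) and math.isnan(p)):
        return "—"
    return (
        f"{round_half_away(100 * p)}% "
        f"({round_half_away(100 * lo)}, {round_half_away(100 * hi)})"
    )


def _render_descriptive(descriptive: pd.DataFrame) -> list[str]:
    lines = ["Performance statistics, mean (SD)", ""]
    wide: dict[str, dict[str, str]] = {}
    for row in descriptive.itertuples():
        label = METRIC_LABELS.get(row.metric, row.metric)
        wide.setdefault(label, {})[row.period] = fmt_mean_sd(row.mean, row.sd)
    header = f"{'Metric':<32}{'1 y prior':>14}{'1 y after':>14}{'2 y after':>14}"
    lines.append(header)
    for label, cells in wide.items():
        lines.append(
            f"{label:<32}{cells.get('pre', '—'):>14}{cells.get('post1', '—'):>14}"
            f"{cells.get('post2', '—'):>14}"
        )
    return lines


def _render_prevalence(prevalence: pd.DataFrame) -> list[str]:
    lines = ["Prevalence of players reaching preinjury performance", ""]
    for year in sorted(prevalence["year"].unique()):
        lines.append(f"{year} y following severe injury")
        sub = prevalence[prevalence["year"] == year]
        for stratum in sub["stratum"].unique():
            block = sub[sub["stratum"] == stratum]
            dens = block["denominator"].unique()
            n = int(dens[0]) if len(dens) == 1 else None
            suffix = f" (n = {n})" if n else ""
            lines.append(f"  {stratum}{suffix}")
            for row in block.itertuples():
                label = METRIC_LABELS.get(row.metric, row.metric)
                lines.append(f"    {label:<32}{fmt_prevalence(row._asdict()):>16}")
        lines.append("")
    return lines


def _render_models(results: pd.DataFrame) -> list[str]:
    lines = ["Prognostic regression coefficients (post on pre)", ""]
    for row in results.itertuples():
        label = METRIC_LABELS.get(row.metric, row.metric)
        p = "<0.001" if row.p_value < 0.001 else f"={row.p_value:.3f}"
        lines.append(
            f"  {row.model_id:<22}{label:<30}{row.year} y: "
            f"{row.coefficient:.1f} (95% CI: {row.ci_low:.1f}, {row.ci_high:.1f}), P{p}"
        )
    return lines


def _render_anova(anova: dict) -> list[str]:
    parts = [
        f"{label} [{fmt_mean_sd(mean, sd, 0)}]"
        for label, mean, sd in zip(
            anova["group_labels"], anova["group_means"], anova["group_sds"]
        )
    ]
    return [
        "Days to return to sport by region: " + ", ".join(parts),
        f"  one-way ANOVA: F = {anova['f_statistic']:.3f}, P = {anova['p_value']:.3f}",
    ]


def render_tables(bundle: dict) -> str:
    """Render a results bundle (see cli.run_pipeline) as a plain-text report."""
    lines: list[str] = ["Return to performance after severe lower-extremity injury", ""]
    if "strata_counts" in bundle:
        counts = bundle["strata_counts"]
        lines.append("Cohort flow (players): " + ", ".join(
            f"{name}: severe {c['severe']}, played 1 y {c['post1']}, played 2 y {c['post2']}"
            for name, c in counts.items()
        ))
        lines.append("")
    if "anova_return_days" in bundle:
        lines += _render_anova(bundle["anova_return_days"]) + [""]
    if "descriptive" in bundle:
        lines += _render_descriptive(pd.DataFrame(bundle["descriptive"])) + [""]
    if "prevalence" in bundle:
        lines += _render_prevalence(pd.DataFrame(bundle["prevalence"]))
    if "models" in bundle:
        lines += _render_models(pd.DataFrame(bundle["models"]))
    return "\n".join(lines) + "\n"
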