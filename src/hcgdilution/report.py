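"""Full evaluation runs and their JSON/Markdown reports.

:func:`evaluate` executes every configured strategy on the same synthetic
cohort and collates, per arm: the TAT percentile summary, threshold
compliance at each expectation value, first-assignment compliance/rework,
and the realized additional cost — plus pairwise t-tests on TAT between arms
and the formula-based preset-vs-strip cost comparison.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import pandas as pd

import hcgdilution
from hcgdilution.config import RunConfig
from hcgdilution.cohort import generate_cohort
from hcgdilution.costs import (
    additional_cost_preset,
    additional_cost_strip,
    cost_from_outcomes,
    cost_rate,
)
from hcgdilution.metrics import compliance, summarize_tat, two_sample_ttest
from hcgdilution.workflow import Strategy, compliance_rate, run_workflow

__all__ = ["evaluate", "render_markdown", "validate_report"]

_ARM_KEYS = {"strategy", "n", "tat_summary", "tat_compliance",
             "first_assignment", "additional_cost_alpha"}


def evaluate(config: RunConfig, cohort: Optional[pd.DataFrame] = None) -> dict:
    """Run all configured strategies on one shared cohort and build the report."""
    if cohort is None:
        cohort = generate_cohort(config.cohort)
    if cohort.empty:
        raise ValueError("cannot evaluate an empty cohort")

    arms = {}
    outcomes = {}
    for strat_cfg in config.strategies:
        name = strat_cfg.strategy.value
        out = run_workflow(cohort, strat_cfg, config.ruleset,
                           config.analyzer, config.timing)
        outcomes[name] = out
        comp = compliance_rate(out)
        arms[name] = {
            "strategy": name,
            "n": len(out),
            "tat_summary": summarize_tat(out["tat"]).as_dict(),
            "tat_compliance": [
                compliance(out["tat"], t).as_dict() for t in config.thresholds
            ],
            "first_assignment": comp,
            "additional_cost_alpha": cost_from_outcomes(out, config.cost),
        }

    names = list(arms)
    ttests = [
        {
            "arms": [a, b],
            **two_sample_ttest(outcomes[a]["tat"], outcomes[b]["tat"]).as_dict(),
        }
        for i, a in enumerate(names)
        for b in names[i + 1:]
    ]

    report = {
        "meta": {
            "package": "hcgdilution",
            "version": hcgdilution.__version__,
            "seed": config.seed,
            "n_samples": len(cohort),
            "config_hash": config_hash(config),
        },
        "arms": arms,
        "tat_ttests": ttests,
    }

    if Strategy.PRESET.value in arms:
        preset_rework = arms[Strategy.PRESET.value]["first_assignment"]["rework_rate"]
        strip_rework = (
            arms[Strategy.STRIP.value]["first_assignment"]["rework_rate"]
            if Strategy.STRIP.value in arms
            else 0.07
        )
        preset_cost = additional_cost_preset(preset_rework, config.cost)
        strip_cost = additional_cost_strip(strip_rework, config.cost)
        report["cost_comparison"] = {
            "preset_rework_rate": preset_rework,
            "strip_rework_rate": strip_rework,
            "preset_additional_cost_alpha": preset_cost,
            "strip_additional_cost_alpha": strip_cost,
            **cost_rate(preset_cost, strip_cost).as_dict(),
        }

    validate_report(report)
    return report


def config_hash(config: RunConfig) -> str:
    """Short stable digest of the run configuration, for report provenance."""
    blob = repr(config).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def validate_report(report: dict) -> None:
    """Schema check before anything is written to disk."""
    for key in ("meta", "arms", "tat_ttests"):
        if key not in report:
            raise ValueError(f"report missing section {key!r}")
    for name, arm in report["arms"].items():
        missing = _ARM_KEYS - set(arm)
        if missing:
            raise ValueError(f"arm {name!r} missing keys {sorted(missing)}")


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def render_markdown(report: dict) -> str:
    """Markdown rendering: TAT descriptives, threshold compliance, costs."""
    lines = []
    meta = report["meta"]
    lines.append("# hCG dilution strategy evaluation")
    lines.append("")
    lines.append(
        f"Package {meta['package']} {meta['version']} — seed {meta['seed']}, "
        f"{meta['n_samples']} specimens, config `{meta['config_hash']}`."
    )

    lines.append("")
    lines.append("## In-laboratory TAT (min)")
    lines.append("")
    lines.append("| Arm | n | Mean | Median | Range | 5% | 25% | 75% | 95% |")
    lines.append("|---|---|---|---|---|---|---|---|---|")
    for name, arm in report["arms"].items():
        s = arm["tat_summary"]
        lines.append(
            f"| {name} | {s['n']} | {_fmt(s['mean'])} | {_fmt(s['median'])} "
            f"| {_fmt(s['min'])}–{_fmt(s['max'])} | {_fmt(s['p5'])} "
            f"| {_fmt(s['p25'])} | {_fmt(s['p75'])} | {_fmt(s['p95'])} |"
        )

    lines.append("")
    lines.append("## TAT expectation compliance")
    lines.append("")
    lines.append("| Arm | Threshold (min) | Compliant | n | Rate |")
    lines.append("|---|---|---|---|---|")
    for name, arm in report["arms"].items():
        for c in arm["tat_compliance"]:
            lines.append(
                f"| {name} | {c['threshold']:.0f} | {c['n_compliant']} "
                f"| {c['n_total']} | {100 * c['rate']:.2f}% |"
            )

    lines.append("")
    lines.append("## First-assignment compliance and additional cost")
    lines.append("")
    lines.append("| Arm | Compliance | Rework | Additional cost (α) |")
    lines.append("|---|---|---|---|")
    for name, arm in report["arms"].items():
        fa = arm["first_assignment"]
        lines.append(
            f"| {name} | {100 * fa['rate']:.2f}% | {100 * fa['rework_rate']:.2f}% "
            f"| {arm['additional_cost_alpha']:.4f} |"
        )

    if "tat_ttests" in report and report["tat_ttests"]:
        lines.append("")
        lines.append("## Pairwise TAT t-tests (Student, two-sided)")
        lines.append("")
        lines.append("| Arms | t | df | p | Mean diff | 95% CI | F (var ratio) |")
        lines.append("|---|---|---|---|---|---|---|")
        for tt in report["tat_ttests"]:
            lines.append(
                f"| {tt['arms'][0]} vs {tt['arms'][1]} | {tt['t']:.3f} "
                f"| {tt['df']:.0f} | {tt['p']:.3g} | {_fmt(tt['mean_diff'])} "
                f"| [{_fmt(tt['ci_low'])}, {_fmt(tt['ci_high'])}] "
                f"| {tt['f_variance_ratio']:.3f} |"
            )

    if "cost_comparison" in report:
        cc = report["cost_comparison"]
        lines.append("")
        lines.append("## Preset vs strip cost (formula basis)")
        lines.append("")
        lines.append(
            f"Preset additional cost R×{100 * cc['preset_rework_rate']:.2f}% = "
            f"{cc['preset_additional_cost_alpha']:.4f} α; strip arm "
            f"R×{100 * cc['strip_rework_rate']:.2f}% + 1 α = "
            f"{cc['strip_additional_cost_alpha']:.4f} α; cost rate "
            f"{100 * cc['cost_rate']:.2f}% (savings {100 * cc['savings_rate']:.2f}%)."
        )
    lines.append("")
    return "\n".join(lines)


def write_report(report: dict, out_dir) -> tuple[str, str]:
    """Write ``report.json`` and ``report.md``; returns the two paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "report.json"
    md_path = out / "report.md"
    json_path.write_text(json.dumps(report, indent=2) + "\n")
    md_path.write_text(render_markdown(report))
    return str(json_path), str(md_path)
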