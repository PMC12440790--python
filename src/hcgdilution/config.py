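"""Run configuration: parsing, validation, and the seed-expansion scheme.

A single YAML or JSON file drives a whole evaluation run.  Every section is
optional and falls back to the package defaults; validation errors always
name the offending key.

One global ``seed`` expands deterministically into independent child seeds —
child 0 for the cohort, children 1..k for the configured strategies — via
``numpy.random.SeedSequence(seed).generate_state``, so each module can be
re-run in isolation with its own seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from hcgdilution.analyzer import AnalyzerSpec
from hcgdilution.cohort import CohortConfig, WeekConcentrationModel
from hcgdilution.costs import CostParams
from hcgdilution.rules import DilutionRule, RuleSet, default_ruleset
from hcgdilution.workflow import Strategy, StrategyConfig, TimingProfile

__all__ = ["ConfigError", "RunConfig", "load_config", "child_seeds"]


class ConfigError(ValueError):
    """Malformed run configuration; the message names the offending key."""


def child_seeds(seed: int, n: int) -> list[int]:
    """Expand one global seed into ``n`` independent 31-bit child seeds."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    ruleset: RuleSet = field(default_factory=default_ruleset)
    analyzer: AnalyzerSpec = field(default_factory=AnalyzerSpec)
    strategies: list[StrategyConfig] = field(
        default_factory=lambda: [StrategyConfig(strategy=s) for s in Strategy]
    )
    timing: TimingProfile = field(default_factory=TimingProfile)
    cost: CostParams = field(default_factory=CostParams)
    thresholds: list[float] = field(default_factory=lambda: [90.0, 80.0, 60.0])
    output_dir: Path = Path("results")
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.thresholds or any(t <= 0 for t in self.thresholds):
            raise ConfigError("thresholds: must be non-empty and positive")
        self.cohort.validate()
        # propagate the seed scheme: cohort first, then one child per strategy
        seeds = child_seeds(self.seed, 1 + len(self.strategies))
        self.cohort.seed = seeds[0]
        for cfg, s in zip(self.strategies, seeds[1:]):
            cfg.seed = s


def _section(raw: dict, key: str) -> dict:
    value = raw.get(key, {})
    if not isinstance(value, dict):
        raise ConfigError(f"{key}: expected a mapping")
    return value


def _build(cls, section: dict, key: str, **extra):
    try:
        return cls(**{**section, **extra})
    except TypeError as exc:
        raise ConfigError(f"{key}: {exc}") from exc
    except ValueError as exc:
        raise ConfigError(f"{key}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("top level: expected a mapping")
    known = {"cohort", "ruleset", "analyzer", "strategies", "timing", "cost",
             "thresholds", "output_dir", "seed"}
    for key in raw:
        if key not in known:
            raise ConfigError(f"{key}: unknown configuration key")

    cohort_raw = dict(_section(raw, "cohort"))
    if "week_weights" in cohort_raw:
        ww = cohort_raw["week_weights"]
        if not isinstance(ww, dict):
            raise ConfigError("cohort.week_weights: expected a mapping week -> weight")
        cohort_raw["week_weights"] = {int(k): float(v) for k, v in ww.items()}
    if "concentration_model" in cohort_raw:
        cm = cohort_raw["concentration_model"]
        cohort_raw["concentration_model"] = _build(
            WeekConcentrationModel,
            {k: ({int(w): float(x) for w, x in v.items()} if isinstance(v, dict) else v)
             for k, v in cm.items()},
            "cohort.concentration_model",
        )
    cohort = _build(CohortConfig, cohort_raw, "cohort")
    try:
        cohort.validate()
    except ValueError as exc:
        raise ConfigError(f"cohort: {exc}") from exc

    if "ruleset" in raw:
        rs = _section(raw, "ruleset")
        try:
            rules = tuple(
                DilutionRule(int(r["week_low"]), int(r["week_high"]), float(r["factor"]))
                for r in rs.get("rules", [])
            )
            ruleset = RuleSet(rules, int(rs.get("eligible_low", 5)),
                              int(rs.get("eligible_high", 40)))
        except (KeyError, ValueError, TypeError) as exc:
            raise ConfigError(f"ruleset: {exc}") from exc
    else:
        ruleset = default_ruleset()

    analyzer = _build(AnalyzerSpec, _section(raw, "analyzer"), "analyzer")

    strategies_raw = raw.get("strategies")
    if strategies_raw is None:
        strategies = [StrategyConfig(strategy=s) for s in Strategy]
    else:
        if not isinstance(strategies_raw, list) or not strategies_raw:
            raise ConfigError("strategies: expected a non-empty list")
        strategies = []
        valid = ", ".join(s.value for s in Strategy)
        for i, s_raw in enumerate(strategies_raw):
            name = s_raw.get("strategy") if isinstance(s_raw, dict) else s_raw
            if name not in Strategy.__members__:
                raise ConfigError(
                    f"strategies[{i}].strategy: unknown strategy {name!r} (valid: {valid})"
                )
            section = dict(s_raw) if isinstance(s_raw, dict) else {"strategy": name}
            if "retest_factor_schedule" in section:
                section["retest_factor_schedule"] = tuple(
                    float(f) for f in section["retest_factor_schedule"]
                )
            strategies.append(_build(StrategyConfig, section, f"strategies[{i}]"))

    timing_raw = {k: tuple(v) if isinstance(v, (list, tuple)) else (float(v), 0.0)
                  for k, v in _section(raw, "timing").items()}
    timing = _build(TimingProfile, timing_raw, "timing")
    cost = _build(CostParams, _section(raw, "cost"), "cost")

    try:
        thresholds = [float(t) for t in raw.get("thresholds", [90.0, 80.0, 60.0])]
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"thresholds: {exc}") from exc

    return RunConfig(
        cohort=cohort,
        ruleset=ruleset,
        analyzer=analyzer,
        strategies=strategies,
        timing=timing,
        cost=cost,
        thresholds=thresholds,
        output_dir=Path(raw.get("output_dir", "results")),
        seed=int(raw.get("seed", 0)),
    )
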