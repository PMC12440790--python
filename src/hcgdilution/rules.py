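"""Eligibility triage and the gestational-week → dilution-factor rule set.

The preset strategy assigns a dilution fold from the gestational week before
the first measurement: 100-fold at weeks 5–6 and 13–40, 200-fold at the
weeks 7–12 peak.  Specimens that cannot be triaged automatically — sample
errors, missing requisition information, non-pregnant patients, missing or
out-of-window gestational week — are pushed out for manual immunostrip
judgment.  Weeks below 5 are deliberately excluded from automation: hCG
changes too fast there for the week to predict the needed dilution.

The rule set is data, not code, so the engine can be reused for other
analytes whose concentration correlates with a scheduling variable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from hcgdilution.cohort import SampleRecord

__all__ = [
    "DilutionRule",
    "RuleSet",
    "Route",
    "TriageReason",
    "TriageDecision",
    "default_ruleset",
    "assign_factor",
    "triage",
]


class Route(str, Enum):
    AUTO_DILUTE = "AUTO_DILUTE"
    MANUAL_STRIP = "MANUAL_STRIP"


class TriageReason(str, Enum):
    OK = "OK"
    SAMPLE_ERROR = "SAMPLE_ERROR"
    MISSING_INFO = "MISSING_INFO"
    NONPREGNANT = "NONPREGNANT"
    WEEK_MISSING = "WEEK_MISSING"
    WEEK_OUT_OF_RANGE = "WEEK_OUT_OF_RANGE"


@dataclass(frozen=True)
class DilutionRule:
    """Inclusive week interval mapped to a dilution fold."""

    week_low: int
    week_high: int
    factor: float

    def __post_init__(self) -> None:
        if self.week_low > self.week_high:
            raise ValueError("week_low must be <= week_high")
        if self.factor < 1:
            raise ValueError("factor must be >= 1")

    def contains(self, week: int) -> bool:
        return self.week_low <= week <= self.week_high


@dataclass(frozen=True)
class RuleSet:
    """Ordered, non-overlapping rules covering the eligibility window exactly."""

    rules: tuple[DilutionRule, ...]
    eligible_low: int = 5
    eligible_high: int = 40

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("RuleSet needs at least one rule")
        ordered = sorted(self.rules, key=lambda r: r.week_low)
        if ordered[0].week_low != self.eligible_low:
            raise ValueError("rules must start at eligible_low")
        if ordered[-1].week_high != self.eligible_high:
            raise ValueError("rules must end at eligible_high")
        for a, b in zip(ordered, ordered[1:]):
            if b.week_low != a.week_high + 1:
                raise ValueError(
                    f"rules must tile the window: gap/overlap at weeks {a.week_high}/{b.week_low}"
                )

    def to_json(self) -> str:
        return json.dumps(
            {
                "eligible_low": self.eligible_low,
                "eligible_high": self.eligible_high,
                "rules": [
                    {"week_low": r.week_low, "week_high": r.week_high, "factor": r.factor}
                    for r in self.rules
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RuleSet":
        obj = json.loads(text)
        try:
            rules = tuple(
                DilutionRule(int(r["week_low"]), int(r["week_high"]), float(r["factor"]))
                for r in obj["rules"]
            )
            return cls(rules, int(obj["eligible_low"]), int(obj["eligible_high"]))
        except KeyError as exc:  # strict validation on load
            raise ValueError(f"rule set JSON missing key {exc}") from exc


@dataclass(frozen=True)
class TriageDecision:
    route: Route
    reason: TriageReason
    factor: Optional[float] = None

    def __post_init__(self) -> None:
        manual = self.route is Route.MANUAL_STRIP
        if manual != (self.reason is not TriageReason.OK):
            raise ValueError("route must be MANUAL_STRIP iff reason != OK")
        if (self.factor is not None) != (self.route is Route.AUTO_DILUTE):
            raise ValueError("factor present iff route is AUTO_DILUTE")


def default_ruleset() -> RuleSet:
    """Week→factor mapping of the default preset process: {[5,6]→100, [7,12]→200, [13,40]→100}."""
    return RuleSet(
        rules=(
            DilutionRule(5, 6, 100.0),
            DilutionRule(7, 12, 200.0),
            DilutionRule(13, 40, 100.0),
        ),
        eligible_low=5,
        eligible_high=40,
    )


def assign_factor(week: float, ruleset: RuleSet) -> float:
    """Dilution fold for an eligible week; raises outside the eligibility window.

    Fractional weeks are floored — the rule intervals are integer bins.
    """
    week = math.floor(week)
    if not ruleset.eligible_low <= week <= ruleset.eligible_high:
        raise ValueError(
            f"week {week} outside eligibility window "
            f"[{ruleset.eligible_low}, {ruleset.eligible_high}]; triage first"
        )
    for rule in ruleset.rules:
        if rule.contains(week):
            return rule.factor
    raise AssertionError("unreachable: RuleSet tiles its window")  # pragma: no cover


#: Flag precedence when several push-out conditions apply at once.
_FLAG_ORDER: Sequence[tuple[str, TriageReason]] = (
    ("flag_sample_error", TriageReason.SAMPLE_ERROR),
    ("flag_missing_info", TriageReason.MISSING_INFO),
    ("flag_nonpregnant", TriageReason.NONPREGNANT),
)


def triage(sample: SampleRecord, ruleset: RuleSet) -> TriageDecision:
    """Route a specimen: automatic dilution, or push-out for manual strip judgment.

    Total on any well-formed record; never raises.  Reason precedence:
    SAMPLE_ERROR > MISSING_INFO > NONPREGNANT > WEEK_MISSING >
    WEEK_OUT_OF_RANGE.
    """
    for attr, reason in _FLAG_ORDER:
        if getattr(sample, attr):
            return TriageDecision(Route.MANUAL_STRIP, reason)
    week = sample.gestational_week
    if week is None:
        return TriageDecision(Route.MANUAL_STRIP, TriageReason.WEEK_MISSING)
    week = int(week)
    if not ruleset.eligible_low <= week <= ruleset.eligible_high:
        return TriageDecision(Route.MANUAL_STRIP, TriageReason.WEEK_OUT_OF_RANGE)
    return TriageDecision(Route.AUTO_DILUTE, TriageReason.OK,
                          factor=assign_factor(week, ruleset))
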