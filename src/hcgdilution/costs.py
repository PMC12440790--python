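"""Additional-cost accounting in strip-price units.

Prices are expressed in units of α, the price of one colloidal-gold
immunostrip; one quantitative chemiluminescence (CLIA) test costs R·α with
R = 31.91 by default.  "Additional cost" is everything beyond the one CLIA
test every specimen needs regardless of strategy:

- preset arm:  R × rework_rate          (a repeat test per misjudged factor)
- strip arm:   R × rework_rate + 1      (plus one strip for every specimen)

The cost rate is the preset arm's additional cost as a fraction of the strip
arm's; its complement is the savings rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CostParams",
    "CostReport",
    "additional_cost_preset",
    "additional_cost_strip",
    "cost_rate",
    "cost_from_outcomes",
]


@dataclass(frozen=True)
class CostParams:
    """CLIA-to-strip price ratio R (strip price is the unit, 1 α)."""

    clia_cost_ratio: float = 31.91
    strip_cost: float = 1.0

    def __post_init__(self) -> None:
        if self.clia_cost_ratio <= 0:
            raise ValueError("clia_cost_ratio must be > 0")
        if self.strip_cost != 1.0:
            raise ValueError("strip price is the α unit and is fixed at 1")


@dataclass(frozen=True)
class CostReport:
    additional_cost_per_test: float  # α units
    cost_rate: float  # fraction of the control (strip) arm's cost
    savings_rate: float  # 1 - cost_rate

    def as_dict(self) -> dict:
        return {
            "additional_cost_per_test": self.additional_cost_per_test,
            "cost_rate": self.cost_rate,
            "savings_rate": self.savings_rate,
        }


def _check_rate(rate: float) -> None:
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rework_rate must be in [0, 1]")


def additional_cost_preset(rework_rate: float, params: CostParams = CostParams()) -> float:
    """Mean additional α per specimen under the preset strategy: R × rework_rate."""
    _check_rate(rework_rate)
    return params.clia_cost_ratio * rework_rate


def additional_cost_strip(rework_rate: float, params: CostParams = CostParams()) -> float:
    """Mean additional α per specimen under the strip strategy:
    R × rework_rate + 1 (one strip per specimen)."""
    _check_rate(rework_rate)
    return params.clia_cost_ratio * rework_rate + params.strip_cost


def cost_rate(preset_cost: float, strip_cost: float) -> CostReport:
    """Preset additional cost as a fraction of the strip arm's."""
    if strip_cost <= 0:
        raise ValueError("strip arm cost must be > 0")
    if preset_cost < 0:
        raise ValueError("preset arm cost must be >= 0")
    rate = preset_cost / strip_cost
    return CostReport(
        additional_cost_per_test=preset_cost,
        cost_rate=rate,
        savings_rate=1.0 - rate,
    )


def cost_from_outcomes(outcomes: pd.DataFrame, params: CostParams = CostParams()) -> float:
    """Mean per-specimen additional α actually consumed in a simulation:
    every CLIA test beyond the first at R·α, every strip at 1 α."""
    if outcomes.empty:
        raise ValueError("cost_from_outcomes needs a non-empty outcome table")
    extra_tests = (outcomes["n_clia_tests"] - 1).clip(lower=0).sum()
    strips = outcomes["n_strips"].sum()
    n = len(outcomes)
    return float((extra_tests * params.clia_cost_ratio + strips * params.strip_cost) / n)
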