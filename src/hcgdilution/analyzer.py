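"""Phenomenological immunoassay model: AMR validity, hook effect, reporting.

A chemiluminescence hCG assay can only quantify within its analytical
measurement range (AMR); the default upper limit is 1,000 IU/L and the lower
quantitation limit 2 IU/L.  A diluted aliquot produces the instrument-scale
signal ``true/factor``; the reported concentration is the signal multiplied
back by the factor, valid only when the signal is inside the AMR.

Undiluted specimens far above the assay's design range can suffer the
high-dose hook effect: antigen excess saturates both antibodies of the
sandwich and the signal collapses to a falsely low, in-range-looking value.
The model is phenomenological — above a configurable neat-concentration
threshold an undiluted measurement returns an unreliable uniform draw inside
the AMR, flagged ``HOOKED``.

Optional analytical imprecision is a single multiplicative lognormal CV.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "AnalyzerSpec",
    "MeasurementStatus",
    "MeasurementResult",
    "measure",
    "needs_rework",
    "factor_is_adequate",
    "correct_factor_exists",
]


@dataclass(frozen=True)
class AnalyzerSpec:
    """Assay configuration (IU/L)."""

    amr_low: float = 2.0
    amr_high: float = 1000.0
    hook_threshold: float = 500_000.0
    cv: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.amr_low < self.amr_high:
            raise ValueError("require 0 < amr_low < amr_high")
        if self.hook_threshold <= self.amr_high:
            raise ValueError("hook_threshold must exceed amr_high")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")


class MeasurementStatus(str, Enum):
    WITHIN_AMR = "WITHIN_AMR"
    ABOVE_AMR = "ABOVE_AMR"
    BELOW_AMR = "BELOW_AMR"
    HOOKED = "HOOKED"


@dataclass(frozen=True)
class MeasurementResult:
    measured_value: float  # instrument-scale signal, IU/L
    status: MeasurementStatus
    factor_used: float
    reported_concentration: Optional[float] = None  # = measured × factor iff WITHIN_AMR


RngLike = Union[int, np.random.Generator, None]


def _as_rng(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def measure(
    true_concentration: float,
    factor: float,
    spec: AnalyzerSpec = AnalyzerSpec(),
    rng: RngLike = None,
) -> MeasurementResult:
    """Measure a diluted aliquot.

    With ``cv = 0`` and no hook the result is deterministic and the
    within-AMR report reproduces ``true_concentration`` exactly.  ``rng`` is
    only consulted for the noise and hooked-signal draws.
    """
    if true_concentration <= 0:
        raise ValueError("true_concentration must be > 0")
    if factor < 1:
        raise ValueError("factor must be >= 1")

    if factor == 1 and true_concentration > spec.hook_threshold:
        # antigen excess: unreliable falsely-low signal inside the AMR
        signal = float(_as_rng(rng).uniform(spec.amr_low, spec.amr_high))
        return MeasurementResult(signal, MeasurementStatus.HOOKED, factor)

    signal = true_concentration / factor
    if spec.cv > 0:
        sigma = np.sqrt(np.log1p(spec.cv**2))
        signal *= float(np.exp(_as_rng(rng).normal(-sigma**2 / 2, sigma)))
        reported = signal * factor
    else:
        # signal is exactly true/factor, so the back-calculation is exact
        reported = true_concentration

    if signal > spec.amr_high:
        return MeasurementResult(signal, MeasurementStatus.ABOVE_AMR, factor)
    if signal < spec.amr_low:
        return MeasurementResult(signal, MeasurementStatus.BELOW_AMR, factor)
    return MeasurementResult(
        signal, MeasurementStatus.WITHIN_AMR, factor,
        reported_concentration=reported,
    )


def needs_rework(result: MeasurementResult) -> bool:
    """True when the first measurement cannot be reported and must be repeated."""
    return result.status is not MeasurementStatus.WITHIN_AMR


def factor_is_adequate(
    true_concentration: float, factor: float, spec: AnalyzerSpec = AnalyzerSpec()
) -> bool:
    """Would this fold put the ideal (noise-free) signal inside the AMR?"""
    signal = true_concentration / factor
    return spec.amr_low <= signal <= spec.amr_high


def correct_factor_exists(
    true_concentration: float,
    factors: Sequence[float],
    spec: AnalyzerSpec = AnalyzerSpec(),
) -> Optional[float]:
    """Smallest adequate fold among ``factors``, or ``None`` if no fold works."""
    if not factors:
        raise ValueError("factors must be non-empty")
    if any(f < 1 for f in factors):
        raise ValueError("all factors must be >= 1")
    for f in sorted(factors):
        if factor_is_adequate(true_concentration, f, spec):
            return f
    return None
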