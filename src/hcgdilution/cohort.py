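"""Synthetic specimen cohorts with gestational-week-dependent hCG kinetics.

The generator emulates what a laboratory information system would export for
an hCG workload: one row per specimen with a reception timestamp, the
gestational week stated on the requisition (occasionally missing), the true
serum hCG concentration, and rare pre-analytical problem flags.

Concentrations follow the textbook kinetics of pregnancy hCG: a steep
exponential rise through early gestation (doubling every 2–3 days), a peak of
30,000–200,000 mIU/mL at weeks 8–10, and a decline toward a lower steady
state thereafter.  Within a week, concentration is lognormal; the log10
spread is widest in early gestation, where a 2–3-day doubling time means that
specimens drawn a few days apart within the same nominal week differ several
fold.  Units: 1 mIU/mL ≡ 1 IU/L; everything internal is IU/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

__all__ = [
    "WeekConcentrationModel",
    "CohortConfig",
    "SampleRecord",
    "default_week_weights",
    "generate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]

WEEK_MIN = 2
WEEK_MAX = 40

#: Piecewise-linear anchors for median log10(hCG) in IU/L: ~1,000 at week 4,
#: 80,000 at the week-9 peak, 20,000 at week 14, 10,000 at term.
_ANCHORS = ((4, math.log10(1_000)), (9, math.log10(80_000)),
            (14, math.log10(20_000)), (40, math.log10(10_000)))

#: Within-week log10 SD. Early weeks are widest (2–3-day doubling time plus
#: dating uncertainty); the spread narrows through the peak and settles at a
#: moderate between-patient level in later gestation.
_SIGMA_LOG10 = {2: 0.70, 3: 0.70, 4: 0.70, 5: 0.75, 6: 0.65, 7: 0.55,
                8: 0.55, 9: 0.55, 10: 0.55, 11: 0.50, 12: 0.50}
_SIGMA_LATE = 0.60


def _default_median_log10(week: int) -> float:
    """Interpolate the anchor curve; extrapolate the early slope below week 4."""
    (w0, a0), (w1, a1) = _ANCHORS[0], _ANCHORS[1]
    if week <= w1:
        return a0 + (a1 - a0) * (week - w0) / (w1 - w0)
    for (wl, al), (wh, ah) in zip(_ANCHORS[1:], _ANCHORS[2:]):
        if week <= wh:
            return al + (ah - al) * (week - wl) / (wh - wl)
    return _ANCHORS[-1][1]


@dataclass(frozen=True)
class WeekConcentrationModel:
    """Median/spread of log10 hCG per integer gestational week.

    Parameters
    ----------
    median_log10 : mapping week -> median log10 concentration (IU/L)
    sigma_log10 : mapping week -> lognormal log10 SD (> 0)
    nonpregnant_max : upper bound (IU/L) for non-pregnant specimens; serum
        hCG below 5 mIU/mL excludes pregnancy.
    """

    median_log10: Mapping[int, float]
    sigma_log10: Mapping[int, float]
    nonpregnant_max: float = 5.0

    @classmethod
    def default(cls) -> "WeekConcentrationModel":
        weeks = range(WEEK_MIN, WEEK_MAX + 1)
        return cls(
            median_log10={w: _default_median_log10(w) for w in weeks},
            sigma_log10={w: _SIGMA_LOG10.get(w, _SIGMA_LATE) for w in weeks},
        )

    def validate(self) -> None:
        weeks = range(WEEK_MIN, WEEK_MAX + 1)
        for w in weeks:
            if w not in self.median_log10 or w not in self.sigma_log10:
                raise ValueError(f"concentration model must cover week {w}")
            if self.sigma_log10[w] <= 0:
                raise ValueError(f"sigma_log10[{w}] must be > 0")
        med = self.median_log10
        if any(med[w + 1] <= med[w] for w in range(WEEK_MIN, 8)):
            raise ValueError("median_log10 must be strictly increasing on weeks 2-8")
        for w in (8, 9, 10):
            if not 30_000 <= 10 ** med[w] <= 200_000:
                raise ValueError(f"peak median at week {w} outside 30,000-200,000 IU/L")
        if any(med[w + 1] > med[w] for w in range(11, WEEK_MAX)):
            raise ValueError("median_log10 must be non-increasing on weeks 11-40")
        if self.nonpregnant_max <= 0:
            raise ValueError("nonpregnant_max must be > 0")


def default_week_weights() -> dict[int, float]:
    """Default gestational-week distribution of an hCG workload.

    Early-pregnancy confirmation dominates: mode at week 6, mean eligible
    week ≈ 7.0, a geometric tail through late gestation, and ~8% of requests
    at weeks 2–4 (outside the automation window).
    """
    raw = {2: 1.5, 3: 2.5, 4: 4.5, 5: 27.0, 6: 28.0, 7: 14.0, 8: 8.5,
           9: 5.5, 10: 3.8, 11: 2.6, 12: 1.9, 13: 1.4, 14: 1.0}
    for w in range(15, WEEK_MAX + 1):
        raw[w] = 0.26 * 0.8 ** (w - 15)
    total = sum(raw.values())
    return {w: raw[w] / total for w in sorted(raw)}


@dataclass(frozen=True)
class SampleRecord:
    """One specimen as received by the laboratory."""

    sample_id: str
    reception_time: datetime
    gestational_week: Optional[int]
    true_concentration: float  # IU/L
    flag_sample_error: bool = False
    flag_missing_info: bool = False
    flag_nonpregnant: bool = False


@dataclass
class CohortConfig:
    """Knobs for :func:`generate_cohort`.

    ``p_week_missing`` is the probability that the gestational week is absent
    from the requisition (the specimen still has a latent week driving its
    concentration).  The three flags mirror the triage push-out conditions.
    ``timing_profile`` is carried for the workflow stage and unused here.
    """

    n_samples: int = 1000
    seed: int = 0
    week_weights: Mapping[int, float] = field(default_factory=default_week_weights)
    p_sample_error: float = 0.02
    p_missing_info: float = 0.02
    p_nonpregnant: float = 0.02
    p_week_missing: float = 0.02
    concentration_model: WeekConcentrationModel = field(
        default_factory=WeekConcentrationModel.default
    )
    timing_profile: object | None = None
    start_time: datetime = datetime(2024, 1, 1, 8, 0)

    def validate(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        for name in ("p_sample_error", "p_missing_info", "p_nonpregnant", "p_week_missing"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.week_weights:
            raise ValueError("week_weights must be non-empty")
        weights = np.array(list(self.week_weights.values()), dtype=float)
        if (weights < 0).any():
            raise ValueError("week_weights must be non-negative")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("week_weights must sum to 1")
        for w in self.week_weights:
            if not (WEEK_MIN <= int(w) <= WEEK_MAX):
                raise ValueError(f"week_weights key {w} outside weeks {WEEK_MIN}-{WEEK_MAX}")
        self.concentration_model.validate()


COHORT_COLUMNS = [
    "sample_id", "reception_time", "gestational_week", "true_concentration",
    "flag_sample_error", "flag_missing_info", "flag_nonpregnant",
]


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a seeded synthetic cohort.

    Returns a DataFrame with one row per specimen (columns
    ``COHORT_COLUMNS``).  ``gestational_week`` uses pandas' nullable Int64;
    missing weeks are ``pd.NA``.  Identical config+seed gives identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    model = config.concentration_model

    weeks_support = np.array(sorted(config.week_weights), dtype=int)
    probs = np.array([config.week_weights[int(w)] for w in weeks_support], dtype=float)
    probs = probs / probs.sum()
    weeks = rng.choice(weeks_support, size=n, p=probs)

    medians = np.array([model.median_log10[int(w)] for w in weeks])
    sigmas = np.array([model.sigma_log10[int(w)] for w in weeks])
    log10_conc = rng.normal(medians, sigmas)

    flag_err = rng.random(n) < config.p_sample_error
    flag_info = rng.random(n) < config.p_missing_info
    flag_nonpreg = rng.random(n) < config.p_nonpregnant
    week_missing = rng.random(n) < config.p_week_missing

    # non-pregnant specimens: truncated lognormal strictly below nonpregnant_max
    n_np = int(flag_nonpreg.sum())
    if n_np:
        mu, sig = 0.0, 0.45  # median ~1 IU/L background
        upper = (math.log10(model.nonpregnant_max) - mu) / sig
        draws = truncnorm.rvs(-np.inf, upper, loc=mu, scale=sig,
                              size=n_np, random_state=rng)
        log10_conc[flag_nonpreg] = np.minimum(
            draws, math.log10(model.nonpregnant_max) - 1e-9
        )

    conc = np.power(10.0, log10_conc)

    offsets = np.sort(rng.uniform(0, 8 * 30 * 24 * 60, size=n))  # minutes over ~8 months
    times = [config.start_time + timedelta(minutes=float(m)) for m in offsets]

    week_col = pd.array(weeks, dtype="Int64")
    week_col[week_missing] = pd.NA

    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:06d}" for i in range(n)],
            "reception_time": times,
            "gestational_week": week_col,
            "true_concentration": conc,
            "flag_sample_error": flag_err,
            "flag_missing_info": flag_info,
            "flag_nonpregnant": flag_nonpreg,
        },
        columns=COHORT_COLUMNS,
    )


def record_from_row(row) -> SampleRecord:
    """Build a :class:`SampleRecord` from a cohort DataFrame row."""
    week = row["gestational_week"]
    return SampleRecord(
        sample_id=str(row["sample_id"]),
        reception_time=row["reception_time"],
        gestational_week=None if pd.isna(week) else int(week),
        true_concentration=float(row["true_concentration"]),
        flag_sample_error=bool(row["flag_sample_error"]),
        flag_missing_info=bool(row["flag_missing_info"]),
        flag_nonpregnant=bool(row["flag_nonpregnant"]),
    )


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write the cohort CSV (header row, ISO-8601 timestamps, empty = missing)."""
    out = cohort.copy()
    out["reception_time"] = pd.to_datetime(out["reception_time"]).map(
        lambda t: t.isoformat()
    )
    out.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort_csv` (lossless round-trip)."""
    df = pd.read_csv(
        path,
        dtype={"sample_id": str},
        parse_dates=["reception_time"],
    )
    df["gestational_week"] = df["gestational_week"].astype("Int64")
    for c in ("flag_sample_error", "flag_missing_info", "flag_nonpregnant"):
        df[c] = df[c].astype(bool)
    df["true_concentration"] = df["true_concentration"].astype(float)
    return df[COHORT_COLUMNS]
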