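# Methods

## Scope and design

The package evaluates how a clinical laboratory should choose dilution folds
for high-concentration hCG specimens. Its core is deterministic logic — a
triage + week→factor rules engine and an AMR/hook measurement model — wrapped
in a stochastic harness: a synthetic cohort generator standing in for a
laboratory information system export, a per-specimen workflow simulator for
three strategies, and the descriptive/inferential statistics a laboratory
quality report uses. Nothing is fitted; all stochastic components are
forward simulations with explicit seeds.

## Synthetic cohort model

Each specimen has an integer gestational week *w* ∈ [2, 40], a true
concentration, rare pre-analytical flags, and a reception timestamp.

**Concentration.** log₁₀(hCG) | *w* ~ Normal(μ(w), σ(w)). The median curve
μ(w) is piecewise linear through anchors 10³ IU/L at week 4, 8×10⁴ at the
week-9 peak, 2×10⁴ at week 14 and 10⁴ at term, extrapolated backward below
week 4 with the early-rise slope. This respects the canonical kinetics:
strictly rising to the peak (consistent with a 2–3-day doubling time),
peak medians inside 30,000–200,000 mIU/mL for weeks 8–10, non-increasing
afterwards. σ(w) is week-dependent: 0.70–0.75 in weeks 2–5, where the
doubling dynamics make specimens drawn days apart within one nominal week
differ several-fold, narrowing to 0.50–0.55 through weeks 7–12 and settling
at 0.60 from week 13 (between-patient variation). A flat σ cannot
simultaneously keep early weeks realistically dispersed and reproduce a
low-90s% first-pass compliance, which is the operating point this simulator
is built to represent; the week profile above yields an analytic (normal
CDF) in-AMR fraction of 0.923 for eligible specimens at the preset folds and
0.910 for weeks 7–12 at 1:200. These defaults were fixed once from that
analytic calibration, before any simulation was run.

**Week distribution.** A discrete distribution with mode at week 6, mean
eligible week 7.0 (SD 2.5), ~8% of requests at weeks 2–4 and a geometric
late-gestation tail — the early-pregnancy-dominated shape of an hCG
workload. Configurable per run.

**Flags.** Sample error, missing information, non-pregnant, and
week-missing are independent Bernoulli draws at 2% each (no empirical rates
exist for these push-out conditions; 2% makes every triage branch exercised
without dominating the cohort). Non-pregnant specimens draw from a
truncated lognormal strictly below 5 IU/L, the pregnancy-exclusion limit.
Week-missing specimens keep their latent week (it drives the concentration)
but present no week to the triage.

**Units.** 1 mIU/mL ≡ 1 IU/L; all arithmetic is in IU/L.

## Measurement model

A diluted aliquot at fold *f* gives signal *s = c/f*, reportable iff
2 ≤ s ≤ 1000 IU/L (AMR). Optional imprecision multiplies *s* by a mean-one
lognormal with the configured CV; the default CV is 0 so worked examples are
exact and the rework predicate coincides with the adequacy oracle
(2f ≤ c ≤ 1000f). Undiluted measurements of specimens above the hook
threshold (default 500,000 IU/L — an order of magnitude above the
physiological peak; the true onset for any given assay is not public) return
a seeded uniform draw inside the AMR flagged `HOOKED`, modelling the
falsely low signal of antigen excess. Neither the lower quantitation limit
nor the hook onset is an instrument datasheet value; both are configurable.

## Workflow simulation

TAT is a sum of independent stage draws, each lognormal around a stage
median with log-SD 0.30 (log-SD 0 makes a stage deterministic). Stage
medians (minutes): reception→analyzer 40, analyzer cycle 18,
verification→report 10, strip judgment 12, I/O push-out/push-in 6, manual
handling 5. Route compositions:

- PRESET, eligible: pre + cycle + post; on rework add push-out + strip +
  handling + one repeat cycle (and one strip consumed).
- PRESET, triage push-out / STRIP arm: strip + handling before the cycle
  (the PRESET push-out also pays the I/O stage); a strip misread (7%
  probability, resolving to an adjacent fold of {1, 10, 100, 200}) that
  lands out of AMR adds a push + repeat cycle.
- RETEST: walk the fold schedule (default 1 → 100 → 200); each escalation
  pays a push (dilute and re-queue) + repeat cycle.

After any rework the repeat test always happens, at the correct fold when
one exists, else at the nearest achievable end of the strip series with the
report left invalid — a laboratory retests a pushed-out specimen regardless.
Under these defaults the mean TATs land near 78 / 91 / 99 minutes for
PRESET / STRIP / RETEST on the default cohort: the tested claim is the
ordering and the ~13-minute preset saving per specimen, not the absolute
level, which in a real laboratory depends on staffing and batching that a
stage-sum model deliberately omits (no queueing, no contention, no
analyzer batching; stage draws are independent).

`correct_first_assignment` records whether the *first* fold used put the
ideal signal in the AMR; with CV = 0 under PRESET this coincides exactly
with ¬rework. First-assignment compliance + rework rate = 1 by
construction.

Per-specimen randomness uses child generators spawned from the strategy
seed (`SeedSequence.spawn`), so outcome tables are reproducible and
row-stable. A run config expands one global seed into cohort and
per-strategy child seeds the same way.

## Statistics

Percentiles use linear interpolation between closest ranks (methods differ
at small n; this one is declared and frozen). Threshold compliance counts
TAT ≤ threshold inclusively. The two-sample t-test defaults to Student's
pooled variant, mirroring single-F laboratory reporting, with Welch
available; the larger/smaller variance ratio is always reported.
Normality is Kolmogorov–Smirnov with estimated parameters, i.e. Lilliefors
(via statsmodels). The a-priori sample size searches the smallest integer
per-group n whose two-sided noncentral-t power reaches the target — 64 per
group at d = 0.50, α = 0.05, power 0.80 — with a normal-approximation
fallback only where scipy's noncentral t underflows (power ≈ 1); the
statsmodels power solver serves as an independent cross-check in the test
suite, never as the implementation. The degenerate one-sample case
(constant sample equal to the null mean) is defined as t = 0, p = 1.

## Costs

Strip price is the unit (1 α); one CLIA test is R α, R = 31.91 by default.
Additional cost excludes the mandatory first CLIA test of every specimen:
preset arm R × rework rate; strip arm R × rework rate + 1 (one strip per
specimen). Preset beats strip exactly when
R × (rework_preset − rework_strip) < 1, i.e. within ~3.13 percentage points
of rework excess at the default R. `cost_from_outcomes` instead counts what
a simulation actually consumed (repeat tests at R α, strips at 1 α), and on
a noise-free all-eligible PRESET run decomposes exactly into the formula
cost plus one strip per reworked specimen. Labor, depreciation and reagent
waste are out of scope.

## What passing tests do and do not show

The generator reproduces the *structure* the strategies are sensitive to —
week-dependent magnitude and spread, eligibility mix, stage-time scale —
not any hospital's empirical LIS distribution. Simulated compliance near
91% and the PRESET < STRIP < RETEST TAT ordering therefore validate the
pipeline's logic and accounting under stated assumptions; they are not
evidence about any particular laboratory. Problem sizes in the test suite
(10,000-specimen cohorts, 10,000-replicate Monte-Carlo power) were chosen
so the whole suite runs in seconds while keeping Monte-Carlo standard
errors a small fraction of every tested margin.

## Known limitations

- Integer gestational weeks (fractional inputs floored); no twin
  pregnancies, ectopic/molar pathology, or hCG isoform structure.
- Single-CV imprecision, no concentration-dependent imprecision profile.
- The hook effect is phenomenological (threshold + uniform false-low), not
  a two-site binding model.
- Stage times are independent draws; no discrete-event queueing.
- The strip-misread model (one adjacent fold) is a simplification of visual
  judgment error.
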