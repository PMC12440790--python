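"""Strategy execution: tests/strips consumed, rework, TAT, determinism."""

import pandas as pd
import pytest

from hcgdilution import (
    AnalyzerSpec,
    CohortConfig,
    StrategyConfig,
    TimingProfile,
    compliance_rate,
    cost_from_outcomes,
    additional_cost_preset,
    generate_cohort,
    run_workflow,
)
from conftest import make_cohort_row


class TestWorkedExamples:
    def test_preset_handles_week8_peak_sample_in_one_test(self, ruleset, spec):
        out = run_workflow(make_cohort_row(week=8, conc=150_000.0),
                           StrategyConfig(strategy="PRESET", seed=0),
                           ruleset, spec)
        row = out.iloc[0]
        assert row["n_clia_tests"] == 1
        assert row["n_strips"] == 0
        assert not row["rework"]
        assert row["correct_first_assignment"]
        assert row["reported_concentration"] == pytest.approx(150_000.0)

    def test_retest_same_sample_needs_extra_tests(self, ruleset, spec):
        out = run_workflow(make_cohort_row(week=8, conc=150_000.0),
                           StrategyConfig(strategy="RETEST", seed=0),
                           ruleset, spec)
        assert out.iloc[0]["n_clia_tests"] >= 2

    def test_preset_misjudged_factor_reworked_with_strip(self, ruleset, spec):
        # week 13 → factor 100, but 150,000/100 = 1500 is above the AMR
        out = run_workflow(make_cohort_row(week=13, conc=150_000.0),
                           StrategyConfig(strategy="PRESET", seed=0),
                           ruleset, spec)
        row = out.iloc[0]
        assert row["rework"] and not row["correct_first_assignment"]
        assert row["n_clia_tests"] == 2
        assert row["n_strips"] == 1
        assert row["reported_concentration"] == pytest.approx(150_000.0)
        assert row["factor_final"] == 200.0

    def test_ineligible_sample_routed_to_manual_strip(self, ruleset, spec):
        out = run_workflow(make_cohort_row(week=4, conc=2_000.0),
                           StrategyConfig(strategy="PRESET", seed=0,
                                          strip_error_rate=0.0),
                           ruleset, spec)
        row = out.iloc[0]
        assert row["route"] == "MANUAL_STRIP"
        assert row["n_strips"] == 1
        assert not row["rework"]
        assert row["reported_concentration"] == pytest.approx(2_000.0)

    def test_empty_cohort_gives_empty_outcomes(self, ruleset, spec):
        out = run_workflow(make_cohort_row().iloc[0:0],
                           StrategyConfig(strategy="PRESET", seed=0),
                           ruleset, spec)
        assert out.empty

    def test_schedule_exhaustion_is_not_an_error(self, ruleset, spec):
        out = run_workflow(make_cohort_row(week=8, conc=10_000_000.0),
                           StrategyConfig(strategy="RETEST", seed=0),
                           ruleset, spec)
        row = out.iloc[0]
        assert row["rework"]
        assert pd.isna(row["reported_concentration"])
        assert row["n_clia_tests"] == 3


class TestInvariants:
    def test_outcome_table_invariants(self, strategy_outcomes):
        for name, out in strategy_outcomes.items():
            assert (out["n_clia_tests"] >= 1).all(), name
            assert (out["tat"] > 0).all(), name
            reworked = out[out["rework"]]
            assert ((reworked["n_clia_tests"] >= 2) |
                    (reworked["n_strips"] >= 1)).all(), name

    def test_preset_rework_iff_first_assignment_wrong(self, strategy_outcomes):
        """Noise-free conservation: under PRESET, rework happens exactly when
        the first factor was inadequate."""
        out = strategy_outcomes["PRESET"]
        assert (out["rework"] == ~out["correct_first_assignment"]).all()

    def test_strip_strategy_consumes_one_strip_per_sample(self, strategy_outcomes):
        assert (strategy_outcomes["STRIP"]["n_strips"] >= 1).all()

    def test_retest_uses_more_tests_when_preset_factor_adequate(self, ruleset, spec):
        """A specimen above the AMR neat costs RETEST strictly more tests than
        PRESET whenever the preset factor already works."""
        for conc, week in [(150_000.0, 8), (50_000.0, 6), (30_000.0, 20)]:
            preset = run_workflow(make_cohort_row(week=week, conc=conc),
                                  StrategyConfig(strategy="PRESET", seed=0),
                                  ruleset, spec).iloc[0]
            retest = run_workflow(make_cohort_row(week=week, conc=conc),
                                  StrategyConfig(strategy="RETEST", seed=0),
                                  ruleset, spec).iloc[0]
            assert preset["correct_first_assignment"]
            assert retest["n_clia_tests"] > preset["n_clia_tests"]

    def test_seed_determinism_of_outcome_table(self, cohort10k, ruleset, spec):
        cfg = StrategyConfig(strategy="PRESET", seed=77)
        sub = cohort10k.head(300)
        pd.testing.assert_frame_equal(
            run_workflow(sub, cfg, ruleset, spec),
            run_workflow(sub, cfg, ruleset, spec),
        )

    def test_mean_tat_ordering(self, strategy_outcomes):
        """Preset dilution saves the strip stage; strip judgment saves the
        retest cycles."""
        means = {k: v["tat"].mean() for k, v in strategy_outcomes.items()}
        assert means["PRESET"] < means["STRIP"] < means["RETEST"]

    def test_event_log_matches_tat(self, ruleset, spec):
        events = []
        out = run_workflow(make_cohort_row(week=13, conc=150_000.0),
                           StrategyConfig(strategy="PRESET", seed=0),
                           ruleset, spec, event_log=events)
        assert len(events) == 1
        total = sum(d for _, d in events[0]["events"])
        assert total == pytest.approx(out.iloc[0]["tat"], abs=0.01)


class TestComplianceRate:
    def test_study_scale_arithmetic(self):
        """414 correct of 454 first assignments → 91.19% compliance, 8.81% rework."""
        outcomes = pd.DataFrame(
            {"correct_first_assignment": [True] * 414 + [False] * 40}
        )
        c = compliance_rate(outcomes)
        assert c["n_correct"] == 414 and c["n_total"] == 454
        assert round(100 * c["rate"], 2) == 91.19
        assert round(100 * c["rework_rate"], 2) == 8.81

    def test_all_correct(self):
        c = compliance_rate(pd.DataFrame({"correct_first_assignment": [True] * 10}))
        assert c["rate"] == 1.0 and c["rework_rate"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compliance_rate(pd.DataFrame({"correct_first_assignment": []}))


class TestCostCoupling:
    def test_simulation_cost_decomposes_exactly(self, ruleset, spec):
        """On an all-eligible noise-free cohort, realized additional cost equals
        R x rework_rate plus one strip per reworked specimen, exactly."""
        ww = {w: 1 / 36 for w in range(5, 41)}
        cohort = generate_cohort(CohortConfig(
            n_samples=2000, seed=12, week_weights=ww,
            p_sample_error=0, p_missing_info=0, p_nonpregnant=0, p_week_missing=0,
        ))
        out = run_workflow(cohort, StrategyConfig(strategy="PRESET", seed=13),
                           ruleset, spec)
        rework_rate = compliance_rate(out)["rework_rate"]
        realized = cost_from_outcomes(out)
        expected = additional_cost_preset(rework_rate) + out["n_strips"].sum() / len(out)
        assert realized == pytest.approx(expected, abs=1e-12)
        # every reworked specimen used exactly one strip here
        assert out["n_strips"].sum() == out["rework"].sum()


class TestConfigValidation:
    def test_strip_error_rate_bounds(self):
        with pytest.raises(ValueError):
            StrategyConfig(strategy="STRIP", strip_error_rate=1.2)

    def test_schedule_must_start_at_one_and_increase(self):
        with pytest.raises(ValueError):
            StrategyConfig(strategy="RETEST", retest_factor_schedule=(10.0, 100.0))
        with pytest.raises(ValueError):
            StrategyConfig(strategy="RETEST", retest_factor_schedule=(1.0, 100.0, 50.0))

    def test_timing_medians_positive(self):
        with pytest.raises(ValueError):
            TimingProfile(pre_test=(0.0, 0.3))
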