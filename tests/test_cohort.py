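"""Cohort engine: closed-form oracles, conservation, microsimulation."""

from dataclasses import replace

import numpy as np
import pytest

import thyrocea as t
from thyrocea.scenarios import toy_geometric_model, _toy_spec


class TestClosedForms:
    def test_pure_discounting_geometric_sum(self):
        """Healthy immortal cohort: QALYs are the plain discount sum."""
        spec, expected = toy_geometric_model(0.0, 0.05, horizon=3)
        out = t.run_cohort(spec, t.SCREENING)
        assert expected == pytest.approx(1 + 1 / 1.05 + 1 / 1.05**2)
        assert out.total_qaly == pytest.approx(expected, abs=1e-9)

    def test_mortality_times_discount(self):
        spec, expected = toy_geometric_model(0.1, 0.0, horizon=3)
        assert expected == pytest.approx(1 + 0.9 + 0.81)
        out = t.run_cohort(spec, t.SCREENING)
        assert out.total_qaly == pytest.approx(expected, abs=1e-9)

    def test_long_horizon_with_both(self):
        spec, expected = toy_geometric_model(0.1, 0.05, horizon=55)
        out = t.run_cohort(spec, t.SCREENING)
        assert out.total_qaly == pytest.approx(expected, abs=1e-9)

    def test_no_discount_no_death_gives_full_horizon(self):
        spec, _ = toy_geometric_model(0.0, 0.0, horizon=55)
        out = t.run_cohort(spec, t.SCREENING)
        assert out.total_qaly == pytest.approx(55.0, abs=1e-12)

    def test_zero_utilities_give_zero_qalys(self, paper_spec):
        numb = replace(paper_spec, utilities=t.UtilitySet(0, 0, 0, 0, 0, 0))
        out = t.run_cohort(numb, t.SCREENING, check=False)
        assert out.total_qaly == 0.0


class TestTraceInvariants:
    @pytest.mark.parametrize("strategy", t.STRATEGIES)
    def test_cohort_conservation(self, paper_spec, strategy):
        occ = t.run_cohort(paper_spec, strategy).trace.occupancy
        np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-10)
        assert occ.min() >= 0.0
        assert occ[0, t.HealthState.HEALTH] == 1.0

    def test_totals_are_sums_of_per_cycle_streams(self, base_case):
        _, sg, nsg = base_case
        for out in (sg, nsg):
            assert out.total_cost == pytest.approx(out.per_cycle_cost.sum())
            assert out.total_qaly == pytest.approx(out.per_cycle_qaly.sum())
            assert out.total_qaly <= 55.0

    def test_export_has_rewards_per_cycle(self, base_case):
        _, sg, _ = base_case
        df = sg.to_dataframe()
        assert len(df) == 55
        for col in ("cycle", "age", "health", "death", "cost", "qaly",
                    "discounted_cost", "discounted_qaly"):
            assert col in df.columns

    def test_invalid_spec_propagates(self, paper_spec):
        bad = t.with_parameter_values(paper_spec, {"utility.benign": 2.0})
        with pytest.raises(t.InvalidParameterError):
            t.run_cohort(bad, t.SCREENING)


class TestMonotonicity:
    @pytest.mark.parametrize("name, delta", [
        ("utility.benign", -0.05),
        ("utility.postop", -0.05),
        ("utility.recurrence", -0.05),
    ])
    def test_lower_utility_never_raises_qalys(self, paper_spec, name, delta):
        base = t.run_cohort(paper_spec, t.NON_SCREENING).total_qaly
        v = t.parameter_value(paper_spec, name) + delta
        lowered = t.with_parameter_values(paper_spec, {name: v})
        assert t.run_cohort(lowered, t.NON_SCREENING).total_qaly <= base

    @pytest.mark.parametrize("name", [
        "cost.nodule_followup", "cost.treatment", "cost.screening_exam",
    ])
    def test_higher_cost_never_lowers_total_cost(self, paper_spec, name):
        base = t.run_cohort(paper_spec, t.SCREENING).total_cost
        v = t.parameter_value(paper_spec, name) * 1.2
        raised = t.with_parameter_values(paper_spec, {name: v})
        assert t.run_cohort(raised, t.SCREENING).total_cost >= base


class TestMicrosimOracle:
    def test_degenerate_model_has_zero_variance(self):
        spec, expected = toy_geometric_model(0.0, 0.05, horizon=5)
        ms = t.microsim_oracle(spec, t.SCREENING, n_individuals=500, seed=3)
        assert ms.se_qaly == 0.0
        assert ms.total_qaly == pytest.approx(expected, abs=1e-12)

    def test_toy_mortality_model_within_three_se(self):
        spec, _ = toy_geometric_model(0.1, 0.05, horizon=20)
        cohort = t.run_cohort(spec, t.SCREENING)
        ms = t.microsim_oracle(spec, t.SCREENING, n_individuals=100_000, seed=7)
        assert abs(ms.total_qaly - cohort.total_qaly) <= 3 * ms.se_qaly
        assert abs(ms.total_cost - cohort.total_cost) <= 3 * max(ms.se_cost, 1e-12)

    def test_bundled_model_within_three_se(self, paper_spec, base_case):
        _, sg, _ = base_case
        ms = t.microsim_oracle(paper_spec, t.SCREENING, n_individuals=60_000, seed=11)
        assert abs(ms.total_qaly - sg.total_qaly) <= 3 * ms.se_qaly
        assert abs(ms.total_cost - sg.total_cost) <= 3 * ms.se_cost

    def test_requires_at_least_one_individual(self, paper_spec):
        with pytest.raises(t.InvalidParameterError):
            t.microsim_oracle(paper_spec, t.SCREENING, n_individuals=0, seed=0)


def test_half_cycle_correction_averages_boundaries():
    """With HCC, a cohort dying at rate p accrues the mid-cycle average."""
    spec, _ = toy_geometric_model(0.2, 0.0, horizon=2)
    hcc = replace(spec, calibration=replace(spec.calibration,
                                            half_cycle_correction=True))
    out = t.run_cohort(hcc, t.SCREENING)
    # survival 1, 0.8, 0.64 at the boundaries -> (1+0.8)/2 + (0.8+0.64)/2
    assert out.total_qaly == pytest.approx(0.9 + 0.72, abs=1e-12)


def test_discount_timing_end_shifts_weights_one_cycle():
    spec, start_value = toy_geometric_model(0.0, 0.05, horizon=10)
    end = replace(spec, calibration=replace(spec.calibration,
                                            discount_timing="end"))
    out = t.run_cohort(end, t.SCREENING)
    assert out.total_qaly == pytest.approx(start_value / 1.05, abs=1e-9)


def test_one_time_screening_charges_only_first_cycle():
    spec, _ = toy_geometric_model(0.0, 0.0, horizon=10)
    once = replace(spec, calibration=replace(spec.calibration,
                                             screening_per_cycle=False))
    per_cycle = t.run_cohort(spec, t.SCREENING)
    one_time = t.run_cohort(once, t.SCREENING)
    assert one_time.total_cost == pytest.approx(per_cycle.per_cycle_cost[0])
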