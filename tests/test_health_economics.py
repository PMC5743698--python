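"""Utilities, discounting, accumulation, ICER and threshold logic."""

import numpy as np
import pytest

from dfu_cea.health_economics import (
    CostDeck,
    DiscountSpec,
    UndefinedICERError,
    UtilityTable,
    accumulate_outcomes,
    classify_verdict,
    compute_icer,
    discount_factor,
    drug_course_cost,
    state_utility_per_year,
    threshold_unit_price,
    thresholds_from_salary,
)
from dfu_cea.markov_engine import CohortTrace, StateSpace
from dfu_cea.pipeline import run_cea


def _pinned_trace(label: str, weeks: int, space: StateSpace | None = None) -> CohortTrace:
    space = space or StateSpace(4)
    occ = np.zeros((weeks + 1, space.n_states))
    occ[:, space.index(label)] = 1.0
    return CohortTrace(occupancy=occ, space=space)


class TestStateUtility:
    space = StateSpace(4)
    u = UtilityTable()

    @pytest.mark.parametrize(
        "label, expected",
        [
            ("no_ulcer", 0.840),  # reference value
            ("ulcer", 0.840 * (0.9 * 0.890 + 0.1 * 0.820)),  # = 0.74172
            ("amp_tunnel_small_2", 0.840 * 0.500),
            ("amp_tunnel_leg_4", 0.840 * 0.500),
            ("post_amp_small_no_ulcer", 0.840 * 0.830),
            ("post_amp_leg_no_ulcer", 0.840 * 0.730),
            ("post_amp_small_ulcer", 0.840 * (0.9 * 0.830 * 0.890 + 0.1 * 0.715)),
            ("post_amp_leg_ulcer", 0.840 * (0.9 * 0.730 * 0.890 + 0.1 * 0.620)),
        ],
    )
    def test_multiplier_convention(self, label, expected):
        assert state_utility_per_year(label, self.u, self.space) == pytest.approx(
            expected, abs=1e-12
        )

    def test_zero_infection_collapses_the_mixture(self):
        u0 = UtilityTable(infected_fraction=0.0)
        assert state_utility_per_year("ulcer", u0, self.space) == pytest.approx(
            0.840 * 0.890, abs=1e-12
        )

    def test_unknown_state_rejected(self):
        with pytest.raises(KeyError):
            state_utility_per_year("limbo", self.u, self.space)

    def test_reference_state_dominates_all_states(self):
        for label in self.space.labels:
            assert state_utility_per_year(label, self.u, self.space) <= 0.840


class TestDiscounting:
    def test_first_week_undiscounted(self):
        assert discount_factor(1, DiscountSpec(0.05)) == 1.0

    def test_one_year_elapsed(self):
        assert discount_factor(53, DiscountSpec(0.05)) == pytest.approx(1 / 1.05, abs=1e-12)

    def test_zero_rate_never_discounts(self):
        assert discount_factor(1000, DiscountSpec(0.0)) == 1.0

    def test_annual_step_variant_constant_within_year(self):
        d = DiscountSpec(0.05, annual_steps=True)
        assert discount_factor(1, d) == discount_factor(52, d) == 1.0
        assert discount_factor(53, d) == pytest.approx(1 / 1.05, abs=1e-12)

    def test_week_below_one_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(0, DiscountSpec())


class TestAccumulateOutcomes:
    def test_pinned_cohort_undiscounted(self):
        trace = _pinned_trace("no_ulcer", 520)
        qaly, cost = accumulate_outcomes(
            trace, UtilityTable(), CostDeck(), DiscountSpec(0.0)
        )
        assert qaly == pytest.approx(10 * 0.840, abs=1e-9)
        assert cost == 0.0

    def test_pinned_cohort_discounted_matches_direct_summation(self):
        # independent oracle: explicit per-week loop
        trace = _pinned_trace("no_ulcer", 520)
        qaly, _ = accumulate_outcomes(
            trace, UtilityTable(), CostDeck(), DiscountSpec(0.05)
        )
        expected = sum(
            0.840 / 52 * 1.05 ** (-(w - 1) / 52) for w in range(1, 521)
        )
        assert qaly == pytest.approx(expected, abs=1e-9)
        assert qaly == pytest.approx(6.6502, abs=5e-4)

    def test_amputation_event_cost_charged_at_tunnel_entry(self):
        space = StateSpace(4)
        occ = np.zeros((2, space.n_states))
        occ[0, space.index("ulcer")] = 1.0
        occ[1, space.index("amp_tunnel_small_1")] = 0.25
        occ[1, space.index("ulcer")] = 0.75
        trace = CohortTrace(occupancy=occ, space=space)
        deck = CostDeck(amputation_event_cost_small=4000.0)
        _, cost = accumulate_outcomes(trace, UtilityTable(), deck, DiscountSpec(0.0))
        assert cost == pytest.approx(0.25 * 4000.0, abs=1e-9)

    def test_discount_monotonicity_in_rate(self, rd):
        from dfu_cea.markov_engine import run_cohort

        trace = run_cohort(rd.transition_model("gwc"), 260)
        u, c = rd.utility_table(), rd.cost_deck()
        results = [
            accumulate_outcomes(trace, u, c, DiscountSpec(rate))
            for rate in (0.0, 0.03, 0.05, 0.10)
        ]
        qalys = [q for q, _ in results]
        costs = [co for _, co in results]
        assert qalys == sorted(qalys, reverse=True)
        assert costs == sorted(costs, reverse=True)

    def test_prorated_drug_cost_below_full_course(self, rd):
        from dfu_cea.markov_engine import run_cohort

        trace = run_cohort(rd.transition_model("heberprot_gwc"), 260)
        u, d = rd.utility_table(), rd.discount_spec()
        full = rd.cost_deck()
        prorated = CostDeck(**{**rd.params["costs"], "prorate_drug_cost": True})
        _, cost_full = accumulate_outcomes(trace, u, full, d, treated=True)
        _, cost_pro = accumulate_outcomes(trace, u, prorated, d, treated=True)
        assert cost_pro < cost_full  # some of the cohort exits ulcer early


class TestDrugCourseCost:
    @pytest.mark.parametrize(
        "unit, per_week, weeks, expected",
        [(100, 3, 8, 2400), (500, 0, 8, 0), (273, 3, 8, 6552)],
    )
    def test_product_rule(self, unit, per_week, weeks, expected):
        deck = CostDeck(
            drug_unit_cost=unit, drug_units_per_week=per_week, drug_course_weeks=weeks
        )
        assert drug_course_cost(deck) == expected


class TestIcer:
    def test_ratio_case(self):
        icer = compute_icer(15440.0, 0.1709)
        assert icer.is_ratio
        assert icer.value == pytest.approx(15440 / 0.1709, rel=1e-12)

    def test_identity_holds(self):
        icer = compute_icer(12345.6, 0.234)
        assert icer.value * 0.234 == pytest.approx(12345.6, rel=1e-9)

    def test_dominant_when_cheaper_and_better(self):
        assert compute_icer(-1.0, 0.1).kind == "dominant"

    def test_dominated_when_dearer_and_worse(self):
        assert compute_icer(1.0, -0.1).kind == "dominated"

    def test_zero_qaly_gain_raises(self):
        with pytest.raises(UndefinedICERError):
            compute_icer(100.0, 0.0)


class TestThresholds:
    def test_salary_rule(self):
        assert thresholds_from_salary(858.0) == (20592.0, 30030.0)

    def test_scale_invariance(self):
        l1, l2 = thresholds_from_salary(1234.5)
        assert l2 / l1 == pytest.approx(35 / 24, rel=1e-12)

    def test_non_positive_salary_rejected(self):
        with pytest.raises(ValueError):
            thresholds_from_salary(0.0)

    @pytest.mark.parametrize(
        "icer_value, expected",
        [
            (90344.0, "not_cost_effective"),
            (20592.0, "reimbursable"),  # boundary inclusive
            (25000.0, "conditionally_reimbursable"),
            (30030.0, "conditionally_reimbursable"),
        ],
    )
    def test_verdict_bands(self, icer_value, expected):
        icer = compute_icer(icer_value, 1.0)
        assert classify_verdict(icer, 20592.0, 30030.0).value == expected


class TestThresholdUnitPrice:
    def test_closed_form_example(self):
        price = threshold_unit_price(
            delta_qaly=0.1709, delta_cost_nondrug=0.0,
            units_per_week=3, course_weeks=8, lam=30030.0,
        )
        assert price == pytest.approx(30030 * 0.1709 / 24, abs=1e-9)
        assert price == pytest.approx(213.84, abs=0.01)

    def test_fixed_point_at_current_price(self, rd):
        cea = run_cea(rd, 520)
        deck = rd.cost_deck()
        drug = deck.drug_unit_cost * deck.drug_units_per_week * deck.drug_course_weeks
        price = threshold_unit_price(
            delta_qaly=cea.delta_qaly,
            delta_cost_nondrug=cea.delta_cost - drug,
            units_per_week=deck.drug_units_per_week,
            course_weeks=deck.drug_course_weeks,
            lam=cea.icer.value,
        )
        assert price == pytest.approx(deck.drug_unit_cost, rel=1e-9)

    def test_unattainable_threshold_signalled(self):
        price = threshold_unit_price(0.1, 5000.0, 3, 8, lam=0.0)
        assert price is None

    def test_zero_qaly_gain_rejected(self):
        with pytest.raises(ValueError):
            threshold_unit_price(0.0, 0.0, 3, 8, 30030.0)
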