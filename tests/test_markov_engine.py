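"""Cohort engine: matrix construction, propagation, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dfu_cea.markov_engine import (
    CohortTrace,
    HealthState,
    StateSpace,
    TransitionModel,
    aggregate_trace,
    build_transition_matrix,
    run_cohort,
)

probs = st.floats(0.0, 0.3, allow_nan=False)


def _model(**kw) -> TransitionModel:
    return TransitionModel(**kw)


class TestBuildTransitionMatrix:
    def test_all_zero_probabilities_give_identity_outside_tunnels(self):
        m = _model()
        P = build_transition_matrix(m, week=1)
        space = m.space
        for lbl in ("no_ulcer", "ulcer", "post_amp_small_no_ulcer", "post_amp_leg_ulcer"):
            i = space.index(lbl)
            assert P[i, i] == 1.0

    def test_certain_heal_sends_ulcer_mass_to_no_ulcer(self):
        m = _model(p_heal_phase1=1.0)
        P = build_transition_matrix(m, week=1)
        s = m.space
        assert P[s.index("ulcer"), s.index("no_ulcer")] == 1.0

    def test_amputation_split_by_leg_fraction(self):
        # hand-enumerated ulcer row: 0.1 amputation mass split 12.08% leg
        m = _model(p_amp_phase1=0.1, leg_fraction=0.1208)
        P = build_transition_matrix(m, week=1)
        s = m.space
        row = P[s.index("ulcer")]
        assert row[s.index("amp_tunnel_leg_1")] == pytest.approx(0.01208, abs=1e-15)
        assert row[s.index("amp_tunnel_small_1")] == pytest.approx(0.08792, abs=1e-15)
        assert row[s.index("ulcer")] == pytest.approx(0.9, abs=1e-15)

    def test_tunnel_advances_and_exits(self):
        m = _model(t_tunnel=3)
        P = build_transition_matrix(m, week=1)
        s = m.space
        assert P[s.index("amp_tunnel_small_1"), s.index("amp_tunnel_small_2")] == 1.0
        assert P[s.index("amp_tunnel_small_3"), s.index("post_amp_small_no_ulcer")] == 1.0
        assert P[s.index("amp_tunnel_leg_3"), s.index("post_amp_leg_no_ulcer")] == 1.0

    def test_reamputation_flag_closes_the_route(self):
        m = _model(p_amp_post_amp=0.05, allow_reamputation=False)
        P = build_transition_matrix(m, week=1)
        s = m.space
        assert P[s.index("post_amp_small_ulcer"), s.index("amp_tunnel_small_1")] == 0.0

    def test_week_before_one_rejected(self):
        with pytest.raises(ValueError, match="week"):
            build_transition_matrix(_model(), week=0)

    def test_invalid_probability_pair_rejected(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            _model(p_heal_phase1=0.7, p_amp_phase1=0.4)

    @given(h=probs, a=probs, r=probs, lf=st.floats(0, 1))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_rows_stochastic_for_any_valid_model(self, h, a, r, lf):
        m = _model(p_heal_phase1=h, p_amp_phase1=a, p_rec=r, leg_fraction=lf,
                   p_heal_post_amp=h, p_amp_post_amp=a)
        P = build_transition_matrix(m, week=1)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert P.min() >= 0


class TestRunCohort:
    def test_identity_model_keeps_start_vector(self):
        trace = run_cohort(_model(), horizon_weeks=30)
        assert np.all(trace.column("ulcer") == 1.0)

    def test_two_state_reduction_matches_geometric_closed_form(self):
        # with only healing active, ulcer occupancy decays as (1-h)^w
        h = 0.03
        trace = run_cohort(_model(p_heal_phase1=h, p_heal_phase2=h), horizon_weeks=104)
        weeks = np.arange(105)
        assert np.allclose(trace.column("ulcer"), (1 - h) ** weeks, atol=1e-12)

    def test_start_row_places_cohort_in_ulcer(self, rd):
        trace = run_cohort(rd.transition_model("gwc"), horizon_weeks=52)
        assert trace.occupancy[0, trace.space.index("ulcer")] == 1.0
        assert trace.occupancy[0].sum() == 1.0

    def test_phase_switch_equalises_arms_after_phase1(self, rd):
        treated = rd.transition_model("heberprot_gwc")
        control = rd.transition_model("gwc")
        P_t = build_transition_matrix(treated, week=treated.phase1_weeks + 1)
        P_c = build_transition_matrix(control, week=treated.phase1_weeks + 1)
        assert np.array_equal(P_t, P_c)
        assert not np.array_equal(
            build_transition_matrix(treated, 1), build_transition_matrix(control, 1)
        )

    def test_horizon_below_one_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            run_cohort(_model(), horizon_weeks=0)

    @given(h=probs, a=probs, r=probs)
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_conservation_over_random_models(self, h, a, r):
        m = _model(p_heal_phase1=h, p_amp_phase1=a, p_rec=r,
                   p_heal_post_amp=h, p_amp_post_amp=a)
        trace = run_cohort(m, horizon_weeks=120)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)

    def test_cumulative_amputation_monotone_in_amputation_probability(self):
        def cum_amp(p_amp):
            m = _model(p_heal_phase1=0.02, p_amp_phase1=p_amp, p_amp_phase2=p_amp,
                       p_heal_phase2=0.02)
            trace = run_cohort(m, horizon_weeks=52)
            agg = aggregate_trace(trace)
            amputated = [HealthState.AMPUTATION, HealthState.NO_ULCER_AFTER_AMPUTATION,
                         HealthState.ULCER_AFTER_AMPUTATION]
            cols = [list(HealthState).index(s) for s in amputated]
            return agg[-1, cols].sum()

        values = [cum_amp(p) for p in (0.001, 0.005, 0.01, 0.05, 0.1)]
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestAggregateTrace:
    def test_tunnel_mass_reports_as_amputation(self):
        space = StateSpace(4)
        occ = np.zeros((1, space.n_states))
        occ[0, space.index("amp_tunnel_small_2")] = 1.0
        agg = aggregate_trace(CohortTrace(occupancy=occ, space=space))
        assert agg[0, list(HealthState).index(HealthState.AMPUTATION)] == 1.0

    def test_post_amp_split_reports_as_single_state(self):
        space = StateSpace(4)
        occ = np.zeros((1, space.n_states))
        occ[0, space.index("post_amp_small_no_ulcer")] = 0.3
        occ[0, space.index("post_amp_leg_no_ulcer")] = 0.7
        agg = aggregate_trace(CohortTrace(occupancy=occ, space=space))
        idx = list(HealthState).index(HealthState.NO_ULCER_AFTER_AMPUTATION)
        assert agg[0, idx] == pytest.approx(1.0, abs=1e-15)

    @given(h=probs, a=probs, r=probs)
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_aggregation_preserves_row_sums(self, h, a, r):
        m = _model(p_heal_phase1=h, p_amp_phase1=a, p_rec=r)
        agg = aggregate_trace(run_cohort(m, horizon_weeks=60))
        assert np.allclose(agg.sum(axis=1), 1.0, atol=1e-12)
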