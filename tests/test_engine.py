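"""Cohort engine: cascade probabilities, traces, and closed-form limits."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from dpydcea import states as S
from dpydcea.engine import (
    RunSettings,
    build_transition_matrix,
    cycle_event_probabilities,
    initial_occupancy,
    run_cohort,
)
from dpydcea.lifetable import gompertz_lifetable
from dpydcea.parameters import default_parameters
from dpydcea.treatment import Genotype, Strategy

NEGLIGIBLE_MORTALITY = gompertz_lifetable(a=1e-12, b=1e-9)


def immortal_params(**overrides):
    base = dict(
        p_trtdeath_variant_std=0.0,
        p_trtdeath_variant_red=0.0,
        p_trtdeath_wt_std=0.0,
        p_progress=0.0,
        p_death_progressed=0.0,
    )
    base.update(overrides)
    return default_parameters().replace(**base)


class TestCycleEventProbabilities:
    def test_single_active_event_cascade(self):
        """With only toxicity active, wild-type standard dose splits
        0.974 stay / 0.026 step-down."""
        p = immortal_params()
        state = S.pf_index(Genotype.WILD_TYPE, 0)
        probs, intensities = cycle_event_probabilities(
            state, 62.0, p, NEGLIGIBLE_MORTALITY
        )
        assert probs[state] == pytest.approx(0.974, abs=1e-9)
        assert probs[S.pf_index(Genotype.WILD_TYPE, 1)] == pytest.approx(0.026, abs=1e-9)
        assert intensities["toxicity"] == pytest.approx(0.026, abs=1e-9)
        assert intensities["hospitalization"] == pytest.approx(0.026 * 0.6, abs=1e-9)

    def test_progressed_death_split(self):
        p = default_parameters()
        probs, _ = cycle_event_probabilities(
            S.PROGRESSED, 62.0, p, NEGLIGIBLE_MORTALITY
        )
        assert probs[S.DEAD_PROGRESSION] == pytest.approx(0.051, abs=1e-9)
        assert probs[S.PROGRESSED] == pytest.approx(0.949, abs=1e-9)

    def test_all_zero_probabilities_self_loop(self):
        p = immortal_params(
            p_tox_variant_std=0.0, p_tox_variant_red=0.0, p_tox_wt_std=0.0
        )
        for state in list(range(6)) + [S.PROGRESSED]:
            probs, _ = cycle_event_probabilities(state, 62.0, p, NEGLIGIBLE_MORTALITY)
            assert probs[state] == pytest.approx(1.0, abs=1e-9)

    def test_dead_state_rejected(self):
        with pytest.raises(ValueError):
            cycle_event_probabilities(
                S.DEAD_BACKGROUND, 62.0, default_parameters(), NEGLIGIBLE_MORTALITY
            )


@st.composite
def random_parameters(draw):
    prob = lambda: st.floats(0.0, 0.5)
    return default_parameters().replace(
        p_variant=draw(st.floats(0.0, 1.0)),
        p_tox_variant_std=draw(prob()),
        p_tox_variant_red=draw(prob()),
        p_tox_wt_std=draw(prob()),
        p_trtdeath_variant_std=draw(prob()),
        p_trtdeath_variant_red=draw(prob()),
        p_trtdeath_wt_std=draw(prob()),
        p_progress=draw(prob()),
        p_death_progressed=draw(prob()),
    )


class TestTransitionMatrix:
    @hyp_settings(max_examples=100, deadline=None, derandomize=True)
    @given(params=random_parameters(), cycle=st.integers(0, 400))
    def test_rows_sum_to_one(self, params, cycle):
        M = build_transition_matrix(cycle, Strategy.GENOTYPING, params, gompertz_lifetable())
        assert np.all(M >= 0) and np.all(M <= 1)
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)

    def test_dead_rows_are_identity(self, params, lt):
        M = build_transition_matrix(0, Strategy.GENOTYPING, params, lt)
        for s in S.DEAD_STATES:
            expected = np.zeros(S.N_STATES)
            expected[s] = 1.0
            assert np.array_equal(M[s], expected)

    def test_floor_tier_toxicity_self_loops(self, lt):
        """At the 50% floor a toxicity event cannot reduce the dose further,
        so the destination of the toxicity flow is the state itself."""
        p = immortal_params()
        state = S.pf_index(Genotype.VARIANT, 2)
        M = build_transition_matrix(0, Strategy.GENOTYPING, p, lt)
        pf_row = M[state, : len(S.PF_STATES)]
        assert pf_row[state] > 0
        assert np.all(pf_row[np.arange(6) != state] == 0)

    def test_negative_cycle_rejected(self, params, lt):
        with pytest.raises(ValueError):
            build_transition_matrix(-1, Strategy.GENOTYPING, params, lt)


class TestRunCohort:
    def test_occupancy_conserved_and_death_monotone(self, params, lt):
        tr = run_cohort(Strategy.GENOTYPING, params, lt)
        sums = tr.occupancy.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-10)
        dead = tr.occupancy[:, list(S.DEAD_STATES)].sum(axis=1)
        assert np.all(np.diff(dead) >= -1e-12)

    def test_trace_matches_stepwise_matrix_product(self, params, lt):
        """The vectorized propagation agrees with cycle-by-cycle
        multiplication by build_transition_matrix."""
        tr = run_cohort(Strategy.NO_GENOTYPING, params, lt)
        occ = initial_occupancy(Strategy.NO_GENOTYPING, params)
        for t in range(24):
            occ = occ @ build_transition_matrix(t, Strategy.NO_GENOTYPING, params, lt)
            assert np.allclose(occ, tr.occupancy[t + 1], atol=1e-12)

    def test_qaly_le_ly_and_discounting_contracts(self, params, lt):
        for strategy in Strategy:
            r = run_cohort(strategy, params, lt).totals()
            assert r.total_qaly <= r.total_ly
            assert r.total_cost <= r.undiscounted_cost
            assert r.total_qaly <= r.undiscounted_qaly
            assert r.total_ly <= r.undiscounted_ly

    def test_prevalence_zero_identity(self, lt):
        """With no variant carriers the arms differ by exactly the test cost."""
        p = default_parameters().replace(p_variant=0.0)
        a = run_cohort(Strategy.NO_GENOTYPING, p, lt).totals()
        b = run_cohort(Strategy.GENOTYPING, p, lt).totals()
        assert b.total_cost - a.total_cost == pytest.approx(174.81, abs=1e-9)
        assert b.total_qaly == pytest.approx(a.total_qaly, abs=1e-12)
        assert b.total_ly == pytest.approx(a.total_ly, abs=1e-12)

    def test_immortal_cohort_annuity(self):
        """Immortal, non-progressing, toxicity-free cohort at utility one
        accrues the closed-form discounted annuity of the horizon."""
        p = immortal_params(
            p_tox_variant_std=0.0,
            p_tox_variant_red=0.0,
            p_tox_wt_std=0.0,
            u_pf=1.0,
        )
        tr = run_cohort(Strategy.NO_GENOTYPING, p, NEGLIGIBLE_MORTALITY)
        T = tr.n_cycles
        v = 1.03 ** (-1 / 12)
        annuity = (1 - v**T) / (1 - v) / 12.0
        r = tr.totals()
        assert T == 456  # (100 - 62) years of monthly cycles
        assert r.total_ly == pytest.approx(annuity, rel=1e-9)
        assert r.total_qaly == pytest.approx(annuity, rel=1e-9)

    def test_progressed_sojourn_geometric_mean(self):
        """Undiscounted: certain progression after one cycle then geometric
        death gives 1 + 1/p cycles of expected life."""
        p = immortal_params(
            p_progress=1.0,
            p_death_progressed=0.051,
            discount_rate_annual=0.0,
            p_tox_variant_std=0.0,
            p_tox_variant_red=0.0,
            p_tox_wt_std=0.0,
        )
        r = run_cohort(Strategy.NO_GENOTYPING, p, NEGLIGIBLE_MORTALITY).totals()
        expected_months = 1.0 + 1.0 / 0.051
        assert r.undiscounted_ly == pytest.approx(expected_months / 12.0, rel=1e-3)

    def test_genotyping_cost_breakdown_contains_test(self, base_fit):
        assert base_fit.genotyping.cost_breakdown["test"] == pytest.approx(174.81)
        assert base_fit.no_genotyping.cost_breakdown["test"] == 0.0

    def test_empty_horizon_rejected(self, params, lt):
        with pytest.raises(ValueError):
            run_cohort(Strategy.GENOTYPING, params, lt, RunSettings(max_age=60.0))


class TestScenarioFlags:
    def test_half_cycle_correction_shrinks_state_rewards(self, params, lt):
        base = run_cohort(Strategy.NO_GENOTYPING, params, lt).totals()
        hcc = run_cohort(
            Strategy.NO_GENOTYPING, params, lt, RunSettings(half_cycle_correction=True)
        ).totals()
        assert hcc.total_ly < base.total_ly
        assert hcc.total_qaly < base.total_qaly
        # roughly half an initial cycle is removed
        assert base.total_ly - hcc.total_ly == pytest.approx(1 / 24, rel=0.15)

    def test_early_only_treatment_death_bounds_full_model(self, params, lt):
        always = run_cohort(Strategy.NO_GENOTYPING, params, lt).totals()
        early = run_cohort(
            Strategy.NO_GENOTYPING,
            params,
            lt,
            RunSettings(treatment_death_max_cycles=3),
        ).totals()
        assert early.total_ly > always.total_ly

    def test_disutility_overlap_flag(self, params, lt):
        both = run_cohort(Strategy.NO_GENOTYPING, params, lt).totals()
        no_overlap = run_cohort(
            Strategy.NO_GENOTYPING,
            params,
            lt,
            RunSettings(overlap_disutilities=False),
        ).totals()
        assert no_overlap.total_qaly > both.total_qaly
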