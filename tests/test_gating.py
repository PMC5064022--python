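"""Unit and property tests for the Markov gating core."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iksgate import (
    AC1_BOUND,
    DRUG_FREE,
    BindingSpec,
    ConfigurationError,
    DrugConfig,
    GatingScheme,
    NonUniqueSteadyStateError,
    PhysConstants,
    RateLaw,
    State,
    Transition,
    apply_drug_config,
    augment_with_binding,
    build_generator,
    evaluate_rate,
    iks_scheme,
    propagate,
    scheme_from_dict,
    scheme_to_dict,
    steady_state,
)
from conftest import two_state


class TestRateLaws:
    def test_zero_voltage_gives_amplitude(self, constants):
        assert evaluate_rate(RateLaw(1.0, 0.47), 0.0, constants) == 1.0

    def test_voltage_independent_rate_is_constant(self, constants):
        gamma = RateLaw(10.0, 0.0)
        for v in (-120.0, -80.0, 0.0, 40.0, 200.0):
            assert evaluate_rate(gamma, v, constants) == 10.0

    def test_exponential_voltage_dependence(self, constants):
        # independent scalar evaluation of amplitude*exp(z*V*F/(R*T))
        expected = math.exp(0.47 * 0.040 * 96485.33212 / (8.31446261815324 * 293.15))
        got = evaluate_rate(RateLaw(1.0, 0.47), 40.0, constants)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(2.105, abs=5e-4)

    def test_invalid_inputs_raise(self, constants):
        with pytest.raises(ValueError):
            evaluate_rate(RateLaw(1.0, 0.5), float("nan"), constants)
        with pytest.raises(ValueError):
            PhysConstants(T=-1.0)
        with pytest.raises(ValueError):
            RateLaw(-1.0, 0.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        amplitude=st.floats(0.0, 1e3),
        charge=st.floats(-1.0, 1.0),
        v=st.floats(-200.0, 200.0),
    )
    def test_rates_nonnegative_and_finite(self, amplitude, charge, v):
        rate = evaluate_rate(RateLaw(amplitude, charge), v, PhysConstants())
        assert rate >= 0.0 and math.isfinite(rate)


class TestGenerator:
    def test_two_state_matrix(self, toy_scheme):
        q = build_generator(toy_scheme, 0.0)
        assert np.allclose(q, [[-2.0, 2.0], [1.0, -1.0]])

    @pytest.mark.parametrize("v", [-120.0, -80.0, 0.0, 40.0, 60.0])
    def test_rows_sum_to_zero(self, free_scheme, v):
        q = build_generator(free_scheme, v)
        assert q.shape == (6, 6)
        assert np.abs(q.sum(axis=1)).max() < 1e-12
        off = q[~np.eye(6, dtype=bool)]
        assert (off >= 0).all()

    def test_bound_config_slows_closed_state_exit(self, bound_scheme):
        q = build_generator(bound_scheme, 0.0)
        i, j = bound_scheme.index("C2s"), bound_scheme.index("C2")
        assert q[i, j] == 0.1

    def test_duplicate_transition_rejected(self):
        with pytest.raises(ConfigurationError):
            GatingScheme(
                "dup",
                states=(State("A"), State("B")),
                transitions=(
                    Transition("A", "B", RateLaw(1.0)),
                    Transition("A", "B", RateLaw(2.0)),
                ),
            )

    def test_unknown_state_rejected(self):
        with pytest.raises(ConfigurationError):
            GatingScheme(
                "bad",
                states=(State("A"), State("B")),
                transitions=(Transition("A", "X", RateLaw(1.0)),),
            )


class TestSteadyState:
    def test_two_state_closed_form(self, toy_scheme):
        # stationary occupancy b/(a+b), a/(a+b) for A->B rate a, B->A rate b
        p = steady_state(toy_scheme, 0.0)
        assert np.allclose(p, [1.0 / 3.0, 2.0 / 3.0], atol=1e-12)

    @pytest.mark.parametrize("drug", ["free", "bound"])
    @pytest.mark.parametrize("v", [-120.0, -80.0, 0.0, 40.0])
    def test_stationarity_residual(self, drug, v):
        scheme = iks_scheme(drug)
        p = steady_state(scheme, v)
        q = build_generator(scheme, v)
        assert abs(p.sum() - 1.0) < 1e-10
        assert np.abs(p @ q).max() < 1e-10
        assert (p >= 0).all()

    def test_matches_long_relaxation_from_uniform(self, free_scheme):
        p_inf = steady_state(free_scheme, -80.0)
        trace = propagate(free_scheme, np.full(6, 1.0 / 6.0), -80.0, 60.0, 1.0)
        assert np.abs(trace.probabilities[-1] - p_inf).max() < 1e-6

    def test_disconnected_chain_rejected(self):
        scheme = GatingScheme(
            "disconnected",
            states=(State("A"), State("B"), State("C"), State("D")),
            transitions=(
                Transition("A", "B", RateLaw(1.0)),
                Transition("B", "A", RateLaw(1.0)),
                Transition("C", "D", RateLaw(1.0)),
                Transition("D", "C", RateLaw(1.0)),
            ),
        )
        with pytest.raises(NonUniqueSteadyStateError):
            steady_state(scheme, 0.0)


class TestPropagate:
    def test_zero_duration_returns_initial(self, free_scheme):
        p0 = steady_state(free_scheme, -80.0)
        trace = propagate(free_scheme, p0, 40.0, 0.0, 1e-3)
        assert trace.probabilities.shape == (1, 6)
        assert np.array_equal(trace.probabilities[0], p0)

    def test_two_state_analytic_relaxation(self):
        # from (1,0) with a=b=1: p_A(t) = 0.5 + 0.5*exp(-2t)
        scheme = two_state(1.0, 1.0)
        trace = propagate(scheme, [1.0, 0.0], 0.0, 2.0, 1e-2)
        expected = 0.5 + 0.5 * np.exp(-2.0 * trace.time_s)
        assert np.abs(trace.probabilities[:, 0] - expected).max() < 1e-9

    def test_probability_conserved(self, free_scheme):
        p0 = steady_state(free_scheme, -80.0)
        trace = propagate(free_scheme, p0, 40.0, 5.0, 1e-3)
        assert np.abs(trace.probabilities.sum(axis=1) - 1.0).max() < 1e-9
        assert trace.probabilities.min() >= 0.0

    def test_invalid_inputs_raise(self, free_scheme):
        p0 = steady_state(free_scheme, -80.0)
        with pytest.raises(ValueError):
            propagate(free_scheme, p0, 40.0, -1.0, 1e-3)
        with pytest.raises(ValueError):
            propagate(free_scheme, p0 * 0.5, 40.0, 1.0, 1e-3)
        with pytest.raises(ValueError):
            propagate(free_scheme, p0, 40.0, 1.0, 0.0)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        rates=st.lists(st.floats(1e-3, 1e2), min_size=4, max_size=4),
        v=st.sampled_from([-80.0, 0.0, 40.0]),
    )
    def test_conservation_on_random_three_state_chains(self, rates, v):
        scheme = GatingScheme(
            "random-chain",
            states=(State("A"), State("B"), State("C", conducting=True)),
            transitions=(
                Transition("A", "B", RateLaw(rates[0], 0.3)),
                Transition("B", "A", RateLaw(rates[1], -0.3)),
                Transition("B", "C", RateLaw(rates[2], 0.2)),
                Transition("C", "B", RateLaw(rates[3], -0.2)),
            ),
        )
        trace = propagate(scheme, [1.0, 0.0, 0.0], v, 1.0, 1e-2)
        assert np.abs(trace.probabilities.sum(axis=1) - 1.0).max() < 1e-9


class TestDrugConfig:
    def test_empty_config_is_identity(self, free_scheme):
        assert apply_drug_config(free_scheme, DrugConfig()) is free_scheme

    def test_bound_preset_slows_exit_100_fold(self, free_scheme):
        bound = apply_drug_config(free_scheme, AC1_BOUND)
        assert bound.transition("C2s", "C2").law.amplitude == 0.1
        ratio = (
            apply_drug_config(free_scheme, DRUG_FREE).transition("C2s", "C2").law.amplitude
            / bound.transition("C2s", "C2").law.amplitude
        )
        assert ratio == 100.0
        # original untouched
        assert free_scheme.transition("C2s", "C2").law.amplitude == 10.0

    def test_unknown_transition_rejected(self, free_scheme):
        with pytest.raises(ConfigurationError):
            apply_drug_config(free_scheme, DrugConfig((("O1", "C1", RateLaw(1.0)),)))


class TestBindingExpansion:
    def test_doubles_state_space(self, free_scheme):
        spec = BindingSpec(1e4, 1e-3, 1e-6, competent=("C1", "C2", "C3", "C2s"))
        aug = augment_with_binding(free_scheme, spec)
        assert aug.n_states == 12
        assert aug.transition("C2s:AC", "C2:AC").law.amplitude == 0.1
        assert aug.transition("C1", "C1:AC").law.amplitude == pytest.approx(1e4 * 1e-6)
        assert aug.transition("C1:AC", "C1").law.amplitude == 1e-3

    def test_zero_concentration_reproduces_unbound_dynamics(self, free_scheme):
        spec = BindingSpec(1e4, 1e-3, 0.0, competent=("C1", "C2", "C3", "C2s"))
        aug = augment_with_binding(free_scheme, spec)
        p0 = np.zeros(12)
        p0[:6] = steady_state(free_scheme, -80.0)
        tr_aug = propagate(aug, p0, 40.0, 2.0, 1e-2)
        tr_ref = propagate(free_scheme, p0[:6], 40.0, 2.0, 1e-2)
        assert np.abs(tr_aug.probabilities[:, 6:]).max() <= 1e-12
        assert np.abs(tr_aug.probabilities[:, :6] - tr_ref.probabilities).max() < 1e-9

    def test_single_state_equilibrium_at_kd_is_half_bound(self):
        scheme = GatingScheme("one", states=(State("S", conducting=True),), transitions=())
        kd = 1e-7
        spec = BindingSpec(1e5, 1e5 * kd, kd, competent=("S",), bound_config=DrugConfig())
        aug = augment_with_binding(scheme, spec)
        p = steady_state(aug, 0.0)
        assert p[1] == pytest.approx(0.5, abs=1e-12)

    def test_bound_occupancy_rises_monotonically_at_hold(self, free_scheme):
        spec = BindingSpec(1e4, 1e4 * 78.4e-9, 1e-6, competent=("C1", "C2", "C3", "C2s"))
        aug = augment_with_binding(free_scheme, spec)
        p0 = np.zeros(12)
        p0[:6] = steady_state(free_scheme, -80.0)
        trace = propagate(aug, p0, -80.0, 600.0, 1.0)
        bound_frac = trace.probabilities[:, 6:].sum(axis=1)
        assert (np.diff(bound_frac) > -1e-12).all()
        assert bound_frac[-1] > 0.9  # C = 1 uM >> Kd

    def test_empty_competent_set_with_drug_rejected(self, free_scheme):
        with pytest.raises(ConfigurationError):
            augment_with_binding(free_scheme, BindingSpec(1e4, 1e-3, 1e-6, competent=()))


def test_scheme_json_round_trip(free_scheme):
    rebuilt = scheme_from_dict(scheme_to_dict(free_scheme))
    assert rebuilt == free_scheme
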