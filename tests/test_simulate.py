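"""Integrator, oracle and classification tests.

The adaptive solver is validated three ways: against closed forms in the
uncoupled (beta = 0) limits, against the independent fixed-step RK4
reference, and through the event-correctness invariants at detected
events.
"""

import math

import numpy as np
import pytest

from clonaldyn.errors import AnalyticLimitError, ConfigurationError
from clonaldyn.model_core import (
    CloneParameters,
    DimensionalParameters,
    InitialState,
    ReducedParameters,
    SimulationControls,
)
from clonaldyn.simulate import (
    CONTRACTION_END,
    ELIMINATION,
    HORIZON_REACHED,
    PATHOGEN_CONTROLLED,
    TOLERANCE,
    UNRESOLVED,
    classify,
    closed_form_uncoupled,
    integrate,
    integrate_multi,
    rk4_reference,
    rk4_reference_multi,
    uncoupled_parameters,
)

HARMONIC_CONTROLS = SimulationControls(t_max=20.0, p_min=1e-12, dt_out=0.05)


def rel_maxnorm(a, b):
    return np.max(np.abs(a - b)) / np.max(np.abs(b))


class TestAnalyticLimits:
    def test_harmonic_oscillator_limit(self):
        """lam = beta = 0, k = 1, T0 = 1: the T equation is a pure
        oscillator, T(t) = cos t."""
        p = uncoupled_parameters(k=1.0, lam=0.0, alpha=1.0)
        traj = integrate(p, InitialState(1.0, 0.0, 1e-8), HARMONIC_CONTROLS)
        assert rel_maxnorm(traj.states[:, 0], np.cos(traj.times)) < 1e-6

    def test_exponential_pathogen_limit(self):
        """beta = 0: the pathogen grows unchecked, P(t) = P0 e^(alpha t)."""
        p = uncoupled_parameters(k=1.0, lam=1.0, alpha=0.7)
        traj = integrate(p, InitialState(0.0, 0.0, 1.0), HARMONIC_CONTROLS)
        assert rel_maxnorm(traj.P, np.exp(0.7 * traj.times)) < 1e-6

    @pytest.mark.parametrize(
        "k, lam, alpha",
        [(1.0, 1.0, 1.0), (2.5, 0.8, 0.4), (0.6, 2.0, 1.3)],
    )
    def test_forced_oscillator_matches_closed_form(self, k, lam, alpha):
        p = uncoupled_parameters(k, lam, alpha)
        init = InitialState(0.0, 0.0, 1.0)
        controls = SimulationControls(t_max=12.0, p_min=1e-12, dt_out=0.05)
        traj = integrate(p, init, controls)
        T_exact, P_exact = closed_form_uncoupled(p, init, traj.times)
        assert rel_maxnorm(traj.states[:, 0], T_exact) < 1e-6
        assert rel_maxnorm(traj.P, P_exact) < 1e-6

    def test_closed_form_homogeneous_solution(self):
        p = uncoupled_parameters(1.0, 0.0, 1.0)
        T, _ = closed_form_uncoupled(p, InitialState(1.0, 0.0, 1.0),
                                     np.array([0.0, math.pi]))
        assert T[0] == pytest.approx(1.0)
        assert T[1] == pytest.approx(-1.0)

    def test_closed_form_pure_particular_solution(self):
        """Starting on the particular solution (T0 = C, dT0 = C alpha) the
        oscillatory part vanishes and T = C e^(alpha t) exactly."""
        k, lam, alpha = 1.0, 1.0, 0.5
        p = uncoupled_parameters(k, lam, alpha)
        C = lam * 1.0 / (alpha**2 + k)
        t = np.linspace(0, 5, 40)
        T, _ = closed_form_uncoupled(p, InitialState(C, C * alpha, 1.0), t)
        assert np.allclose(T, C * np.exp(alpha * t), rtol=1e-12)

    def test_closed_form_initial_conditions(self):
        # k=1, lam=1, alpha=1 -> C = 1/2; T(0) = 0 and T'(0) = 0
        p = uncoupled_parameters(1.0, 1.0, 1.0)
        h = 1e-7
        t = np.array([0.0, h])
        T, _ = closed_form_uncoupled(p, InitialState(0.0, 0.0, 1.0), t)
        assert T[0] == pytest.approx(0.0, abs=1e-12)
        assert (T[1] - T[0]) / h == pytest.approx(0.0, abs=1e-6)

    def test_closed_form_rejects_nonzero_beta(self):
        p = DimensionalParameters(1.0, 1.0, 1.0, 1.0)
        with pytest.raises(AnalyticLimitError):
            closed_form_uncoupled(p, InitialState(), np.array([0.0]))


class TestRK4Reference:
    def test_order_four_on_harmonic_limit(self):
        p = uncoupled_parameters(1.0, 0.0, 1.0)
        init = InitialState(1.0, 0.0, 1e-8)
        errs = []
        for h in (2e-3, 1e-3):
            traj = rk4_reference(p, init, HARMONIC_CONTROLS, h=h)
            errs.append(np.max(np.abs(traj.states[:, 0] - np.cos(traj.times))))
        assert errs[0] / errs[1] >= 14.0

    def test_order_four_on_exponential_limit(self):
        p = uncoupled_parameters(1.0, 1.0, 1.0)
        init = InitialState(0.0, 0.0, 1.0)
        controls = SimulationControls(t_max=10.0, p_min=1e-12, dt_out=0.05)
        errs = []
        for h in (2e-3, 1e-3):
            traj = rk4_reference(p, init, controls, h=h)
            errs.append(np.max(np.abs(traj.P - np.exp(traj.times))))
        assert errs[0] / errs[1] >= 14.0

    def test_agreement_with_adaptive_on_acute_preset(self, controls):
        rp = ReducedParameters(2.5, 1.0)
        tr_a = integrate(rp, controls=controls)
        tr_r = rk4_reference(rp, controls=controls, h=1e-3)
        n = min(tr_a.times.size, tr_r.times.size) - 1
        np.testing.assert_allclose(tr_a.times[:n], tr_r.times[:n], atol=1e-12)
        scale = np.abs(tr_a.states[:n]).max()
        assert np.abs(tr_a.states[:n] - tr_r.states[:n]).max() / scale < 1e-4

    def test_step_must_not_exceed_output_interval(self, controls):
        with pytest.raises(ConfigurationError):
            rk4_reference(ReducedParameters(1.0, 1.0), controls=controls, h=0.5)


class TestEventsAndClassification:
    def test_acute_point_is_elimination(self, controls):
        out = classify(integrate(ReducedParameters(2.0, 1.0), controls=controls),
                       controls)
        assert out.label == ELIMINATION
        assert out.t_control is not None

    def test_tolerated_preset_is_tolerance_with_residual_pathogen(self, controls):
        traj = integrate(ReducedParameters(0.3, 0.5), controls=controls)
        out = classify(traj, controls)
        assert out.label == TOLERANCE
        assert out.t_control is None
        assert out.residual_P > controls.p_min

    def test_horizon_below_first_event_is_unresolved(self):
        controls = SimulationControls(t_max=0.5)
        out = classify(integrate(ReducedParameters(2.5, 1.0), controls=controls),
                       controls)
        assert out.label == UNRESOLVED
        assert out.t_control is None and out.t_contraction_end is None

    def test_pathogen_event_state_sits_on_threshold(self, controls):
        traj = integrate(ReducedParameters(2.5, 1.0), controls=controls)
        ev = traj.first_event(PATHOGEN_CONTROLLED)
        assert ev is not None
        assert abs(ev.state_at_event[-1] - controls.p_min) <= 1e-9

    def test_contraction_event_returns_to_baseline_after_excursion(self, controls):
        traj = integrate(ReducedParameters(0.3, 0.5), controls=controls)
        ev = traj.first_event(CONTRACTION_END)
        assert ev is not None
        assert abs(ev.state_at_event[0] - traj.baseline_T) <= 1e-9
        assert traj.total_T().max() > traj.baseline_T + controls.peak_guard_eps

    def test_trajectory_invariants(self, controls):
        for rp in (ReducedParameters(2.5, 1.0), ReducedParameters(0.3, 0.5)):
            traj = integrate(rp, controls=controls)
            assert traj.times[0] == 0.0
            assert np.all(np.diff(traj.times) > 0)
            assert traj.states.shape[0] == traj.times.size
            terminal = traj.events[-1]
            assert terminal.kind in (CONTRACTION_END, HORIZON_REACHED)
            assert traj.times[-1] <= terminal.time + 1e-12

    def test_initial_pathogen_below_threshold_rejected(self):
        controls = SimulationControls(p_min=2.0)
        with pytest.raises(ConfigurationError):
            integrate(ReducedParameters(1.0, 1.0), controls=controls)

    def test_determinism_bitwise(self, controls):
        a = integrate(ReducedParameters(1.3, 0.9), controls=controls)
        b = integrate(ReducedParameters(1.3, 0.9), controls=controls)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.states, b.states)
        assert a.events == b.events


class TestMultiClone:
    def test_single_clone_bit_compatible_with_integrate(self, controls):
        params = DimensionalParameters(1.0, 1.4, 1.2, 0.8)
        clone = CloneParameters("only", k=1.0, lam=1.4, beta=0.8)
        tr1 = integrate(params, InitialState(), controls)
        trn = integrate_multi([clone], alpha=1.2, controls=controls)
        assert np.array_equal(tr1.times, trn.times)
        assert np.array_equal(tr1.states, trn.states)
        assert [e.kind for e in tr1.events] == [e.kind for e in trn.events]

    def test_duplicate_labels_rejected(self, controls):
        clones = [CloneParameters("x", 1, 1, 1), CloneParameters("x", 1, 2, 1)]
        with pytest.raises(ConfigurationError):
            integrate_multi(clones, alpha=1.0, controls=controls)

    def test_two_identical_half_clearance_clones_reproduce_single_P(self, controls):
        single = integrate(DimensionalParameters(1.0, 1.0, 1.0, 1.0),
                           InitialState(), controls)
        halves = [CloneParameters("a", 1.0, 1.0, 0.5),
                  CloneParameters("b", 1.0, 1.0, 0.5)]
        multi = integrate_multi(halves, alpha=1.0, controls=controls)
        n = min(single.times.size, multi.times.size) - 1
        # the 5- and 3-dimensional systems are mathematically identical but
        # the adaptive solver steps them differently; agreement is at the
        # integrator-tolerance level, not bitwise
        np.testing.assert_allclose(multi.P[:n], single.P[:n], rtol=1e-5, atol=1e-9)

    def test_higher_affinity_clone_expands_more(self, controls):
        clones = [CloneParameters("hi", 1.0, 2.0, 1.0),
                  CloneParameters("lo", 1.0, 1.2, 1.0)]
        traj = integrate_multi(clones, alpha=1.0, controls=controls)
        assert traj.states[:, 0].max() > traj.states[:, 2].max()

    def test_removed_dominant_clone_boosts_survivor(self, controls):
        clones = [CloneParameters("hi", 1.0, 2.0, 1.0),
                  CloneParameters("lo", 1.0, 1.2, 1.0)]
        full = integrate_multi(clones, alpha=1.0, controls=controls)
        alone = integrate_multi([clones[1]], alpha=1.0, controls=controls)
        assert alone.states[:, 0].max() > full.states[:, 2].max()

    def test_multi_rk4_agrees_with_adaptive(self, controls):
        clones = [CloneParameters("hi", 1.0, 2.0, 1.0),
                  CloneParameters("lo", 1.0, 1.2, 1.0)]
        tr_a = integrate_multi(clones, alpha=1.0, controls=controls)
        tr_r = rk4_reference_multi(clones, alpha=1.0, controls=controls, h=1e-3)
        n = min(tr_a.times.size, tr_r.times.size) - 1
        scale = np.abs(tr_a.states[:n]).max()
        assert np.abs(tr_a.states[:n] - tr_r.states[:n]).max() / scale < 1e-4
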