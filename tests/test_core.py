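"""Unit and property tests of the deterministic model core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vmradapt import (
    CueWeights,
    LearningState,
    ModelParams,
    SensoryCues,
    cue_weights,
    perceived_hand,
    predicted_proprioceptive_bias,
    step_state,
    trial_errors,
    two_state_implicit_step,
    visual_uncertainty,
)

sigmas = st.floats(min_value=0.5, max_value=60.0)
angles = st.floats(min_value=-120.0, max_value=120.0)


class TestVisualUncertainty:
    @pytest.mark.parametrize(
        "k,b,ecc,expected",
        [
            (0.204, 1.853, 0.0, 1.853),   # intercept at zero eccentricity
            (0.204, 1.853, 30.0, 7.973),  # linear evaluation
            (0.0, 1.853, 90.0, 1.853),    # zero slope kills the dependence
        ],
    )
    def test_linear(self, k, b, ecc, expected):
        assert visual_uncertainty(k, b, ecc, "linear") == pytest.approx(expected)

    @pytest.mark.parametrize("form", ["linear", "exponential", "power_law"])
    def test_forms_anchor_at_intercept_and_increase(self, form):
        assert visual_uncertainty(0.2, 1.853, 0.0, form) == pytest.approx(1.853)
        grid = [visual_uncertainty(0.2, 1.853, e, form) for e in np.linspace(0, 90, 19)]
        assert all(b >= a for a, b in zip(grid, grid[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            visual_uncertainty(0.2, 1.853, -1.0)
        with pytest.raises(ValueError):
            visual_uncertainty(0.2, 0.0, 10.0)
        with pytest.raises(ValueError):
            visual_uncertainty(-0.1, 1.853, 10.0)


class TestCueWeights:
    def test_equal_reliabilities(self):
        w = cue_weights(5.0, 5.0, 5.0)
        assert (w.W_u, w.W_p, w.W_v) == pytest.approx((1 / 3,) * 3)

    def test_fixed_sensory_values(self):
        # inverse-variance normalization at the fixed sigma_u/sigma_p and
        # the zero-eccentricity visual uncertainty
        w = cue_weights(5.05, 11.12, 1.853)
        assert w.W_u == pytest.approx(0.11583, abs=1e-4)
        assert w.W_p == pytest.approx(0.02389, abs=1e-4)
        assert w.W_v == pytest.approx(0.86029, abs=1e-4)

    def test_unreliable_cue_vanishes(self):
        w = cue_weights(5.05, 11.12, 1e9)
        assert w.W_v == pytest.approx(0.0, abs=1e-12)
        ref = cue_weights(5.05, 11.12, 1e300)
        two = 1 / 5.05**2 + 1 / 11.12**2
        assert ref.W_u == pytest.approx((1 / 5.05**2) / two)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            cue_weights(0.0, 1.0, 1.0)

    @given(su=sigmas, sp=sigmas, sv=sigmas)
    @settings(max_examples=200, deadline=None)
    def test_normalization_property(self, su, sp, sv):
        w = cue_weights(su, sp, sv)
        assert abs(w.W_u + w.W_p + w.W_v - 1.0) < 1e-12
        assert 0.0 <= min(w.W_u, w.W_p, w.W_v)


class TestPerceivedHand:
    def test_identical_cues(self):
        w = cue_weights(5.0, 10.0, 2.0)
        assert perceived_hand(SensoryCues(10, 10, 10, 2.0), w) == pytest.approx(10.0)

    def test_worked_example_matches_ppe_chain(self):
        sv = visual_uncertainty(0.204, 1.853, 30.0)
        w = cue_weights(5.05, 11.12, sv)
        est = perceived_hand(SensoryCues(0.0, 0.0, -30.0, sv), w)
        assert est == pytest.approx(-7.4874, abs=1e-3)

    def test_single_cue_dominance(self):
        w = CueWeights(0.0, 0.0, 1.0)
        assert perceived_hand(SensoryCues(3.0, 5.0, -11.0, 1.0), w) == -11.0

    @given(xu=angles, xp=angles, xv=angles, su=sigmas, sp=sigmas, sv=sigmas)
    @settings(max_examples=200, deadline=None)
    def test_convexity(self, xu, xp, xv, su, sp, sv):
        w = cue_weights(su, sp, sv)
        est = perceived_hand(SensoryCues(xu, xp, xv, sv), w)
        assert min(xu, xp, xv) - 1e-9 <= est <= max(xu, xp, xv) + 1e-9


class TestTrialErrors:
    def test_onset_of_30deg_rotation(self, ppe_params):
        e = trial_errors(LearningState(), 30.0, ppe_params)
        assert e.e_pe == pytest.approx(-30.0)
        assert e.e_spe == pytest.approx(-30.0)
        assert e.e_ppe == pytest.approx(-7.4874, abs=1e-3)
        assert e.sigma_v == pytest.approx(7.973)

    def test_no_perturbation_no_errors(self, ppe_params):
        e = trial_errors(LearningState(), 0.0, ppe_params)
        assert (e.e_pe, e.e_spe, e.e_ppe, e.e_pe_reaim) == (0.0, 0.0, 0.0, 0.0)

    def test_instructed_reaiming_nullifies_pe(self, ppe_params):
        e = trial_errors(LearningState(), 45.0, ppe_params,
                         regime="instructed_reaiming", aim_reference=45.0)
        assert e.e_pe == pytest.approx(0.0)
        assert e.e_spe == pytest.approx(-45.0)
        assert e.e_pe_reaim == pytest.approx(-45.0)

    def test_no_feedback_reports_absent_errors(self, ppe_params):
        e = trial_errors(LearningState(5.0, 3.0), 30.0, ppe_params,
                         regime="no_feedback")
        assert e.e_pe is None and e.e_ppe is None

    def test_instructed_requires_reference(self, ppe_params):
        with pytest.raises(ValueError):
            trial_errors(LearningState(), 45.0, ppe_params,
                         regime="instructed_reaiming")

    @given(xe=angles, xi=angles, r=angles)
    @settings(max_examples=200, deadline=None)
    def test_spe_identity_free_aiming(self, xe, xi, r):
        params = ModelParams()
        e = trial_errors(LearningState(xe, xi), r, params)
        # cursor - aim == x_i - r, and equals the re-aiming error when the
        # reference is the participant's own aim
        assert e.e_spe == pytest.approx(xi - r, abs=1e-9)
        assert e.e_pe_reaim == pytest.approx(e.e_spe, abs=1e-12)


class TestStepState:
    def test_pe_single_step(self):
        p = ModelParams(model_kind="PE", Ai=1.0, Bi=0.151, Be=0.513)
        e = trial_errors(LearningState(), 30.0, p)
        new = step_state(LearningState(), e, p)
        assert new.x_i == pytest.approx(0.151 * 30.0)  # 4.53

    def test_ppe_single_step(self):
        p = ModelParams(model_kind="PPE", Ai=1.0, Bi=0.151, Be=0.513)
        e = trial_errors(LearningState(), 30.0, p)
        new = step_state(LearningState(), e, p)
        assert new.x_i == pytest.approx(1.1306, abs=1e-3)

    def test_origin_is_fixed_point(self, ppe_params):
        state = LearningState()
        for _ in range(5):
            e = trial_errors(state, 0.0, ppe_params)
            state = step_state(state, e, ppe_params)
        assert state.x_e == 0.0 and state.x_i == 0.0

    @given(xe=angles, xi=angles)
    @settings(max_examples=100, deadline=None)
    def test_retention_only_decay_without_feedback(self, xe, xi):
        p = ModelParams()
        e = trial_errors(LearningState(xe, xi), 30.0, p, regime="no_feedback")
        new = step_state(LearningState(xe, xi), e, p)
        assert new.x_e == pytest.approx(p.Ae * xe)
        assert new.x_i == pytest.approx(p.Ai * xi)

    def test_instructed_reaiming_clamps_explicit(self):
        p = ModelParams(model_kind="PPE")
        state = LearningState(x_e=45.0, x_i=0.0)
        e = trial_errors(state, 45.0, p, regime="instructed_reaiming",
                         aim_reference=45.0)
        new = step_state(state, e, p, regime="instructed_reaiming")
        assert new.x_e == 45.0  # no performance-error update while instructed


class TestTwoState:
    def test_zero_errors_fixed_point(self):
        p = ModelParams(model_kind="TWO_STATE", Af=0.6, Bf=0.2, As=0.98, Bs=0.05)
        new = two_state_implicit_step(LearningState(), 0.0, 0.0, p)
        assert new.x_i == 0.0

    def test_component_arithmetic(self):
        p = ModelParams(model_kind="TWO_STATE", Af=1.0, Bf=0.2, As=1.0, Bs=0.05)
        new = two_state_implicit_step(LearningState(), -30.0, -30.0, p)
        assert new.x_i_fast == pytest.approx(6.0)
        assert new.x_i_slow == pytest.approx(1.5)
        assert new.x_i == pytest.approx(7.5)

    def test_bs_zero_reduces_to_pe_update(self):
        p2 = ModelParams(model_kind="TWO_STATE", Af=0.9, Bf=0.2, As=0.97, Bs=0.0)
        pe = ModelParams(model_kind="PE", Ai=0.9, Bi=0.2)
        state = LearningState(x_i=4.0, x_i_fast=4.0, x_i_slow=0.0)
        e = trial_errors(state, 30.0, pe)
        assert two_state_implicit_step(state, e.e_pe, e.e_spe, p2).x_i == \
            pytest.approx(step_state(state, e, pe).x_i)

    def test_missing_parameters(self):
        with pytest.raises(ValueError):
            ModelParams(model_kind="TWO_STATE")


class TestProprioceptiveBias:
    def test_zero_rotation(self, ppe_params):
        assert predicted_proprioceptive_bias(LearningState(), 0.0, ppe_params) == 0.0

    def test_early_learning_bias_toward_perturbation(self, ppe_params):
        bias = predicted_proprioceptive_bias(LearningState(), 30.0, ppe_params)
        assert bias == pytest.approx(-7.4874, abs=1e-3)
        assert bias < 0  # toward the perturbation, opposite to learning


class TestModelLimits:
    def test_ppe_converges_to_spe_with_perfect_vision(self):
        # as the visual cue becomes infinitely reliable the perceived hand
        # collapses onto the cursor, so PPE -> SPE
        p = ModelParams(k=0.0, b=1e-9)
        e = trial_errors(LearningState(2.0, -1.0), 37.0, p)
        assert e.e_ppe == pytest.approx(e.e_spe, abs=1e-6)

    def test_single_trial_ppe_response_is_nonmonotone(self):
        p = ModelParams()
        grid = np.linspace(0.0, 90.0, 91)
        resp = []
        for r in grid:
            e = trial_errors(LearningState(), r, p)
            resp.append(-p.Bi * e.e_ppe)  # implicit change from rest
        resp = np.array(resp)
        peak = resp.argmax()
        assert 0 < peak < len(grid) - 1
        assert resp[-1] < resp[peak]  # rises then falls over [0, 90]

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ModelParams(Ae=0.99, Ai=0.9)  # explicit must retain less
        with pytest.raises(ValueError):
            ModelParams(Be=0.1, Bi=0.2)  # explicit must learn faster
        with pytest.raises(ValueError):
            ModelParams(sigma_u=0.0)
        with pytest.raises(ValueError):
            ModelParams(k=-0.1)
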