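"""Simulator tests: determinism, latent/observable separation, and
agreement between the trajectory engine and the per-trial core operations."""

import math

import numpy as np
import pandas as pd
import pytest

from vmradapt import (
    LearningState,
    ModelParams,
    NoiseSpec,
    build_schedule,
    extract_measures,
    run_model,
    simulate_group,
    simulate_participant,
    single_trial_learning,
    step_state,
    trial_errors,
)


def reference_trajectory(schedule, params):
    """Trial-by-trial reference built only from the pure core operations."""
    state = LearningState()
    frozen_ref = math.nan
    last_report = math.nan
    xe_out, xi_out = [], []
    for t in range(len(schedule)):
        tt = schedule.trial_type[t]
        instructed = schedule.instructed[t]
        if instructed:
            ref = schedule.aim_ref[t]
            if math.isnan(ref):
                if math.isnan(frozen_ref):
                    frozen_ref = last_report if not math.isnan(last_report) else state.x_e
                ref = frozen_ref
            xe_out.append(ref)
        else:
            xe_out.append(state.x_e)
        xi_out.append(state.x_i)

        feedback = tt in ("feedback", "aiming_report", "probe")
        if not feedback:
            errs = trial_errors(state, schedule.rotation[t], params,
                                regime="no_feedback")
            state = step_state(state, errs, params)
            continue
        if tt == "aiming_report":
            last_report = state.x_e
        regime = "instructed_reaiming" if instructed else "free_aiming"
        errs = trial_errors(state, schedule.rotation[t], params, regime=regime,
                            aim_reference=ref if instructed else None)
        if instructed:
            state.x_e = ref  # aim clamped to the instructed direction
        state = step_state(state, errs, params, regime=regime,
                           pe_reaim=bool(schedule.pe_reaim[t]))
    return np.array(xe_out), np.array(xi_out)


@pytest.mark.parametrize("design,condition", [
    ("exp1", 30), ("exp3", None), ("exp4", 45), ("exp5", None),
])
@pytest.mark.parametrize("kind", ["PPE", "PE", "SPE"])
def test_engine_matches_core_operations(design, condition, kind):
    params = ModelParams(model_kind=kind)
    schedule = build_schedule(design, condition)
    traj = run_model(schedule, params)
    xe_ref, xi_ref = reference_trajectory(schedule, params)
    np.testing.assert_allclose(traj.x_e, xe_ref, atol=1e-10)
    np.testing.assert_allclose(traj.x_i, xi_ref, atol=1e-10)


def test_engine_matches_core_two_state():
    params = ModelParams(model_kind="TWO_STATE", Af=0.7, Bf=0.2, As=0.98, Bs=0.05)
    schedule = build_schedule("exp1", 30)
    traj = run_model(schedule, params)
    xe_ref, xi_ref = reference_trajectory(schedule, params)
    np.testing.assert_allclose(traj.x_i, xi_ref, atol=1e-10)


def test_cwccw_antisymmetry():
    """Flipping the rotation sign mirrors the whole trajectory."""
    params = ModelParams()
    s = build_schedule("exp1", 30)
    flipped = build_schedule("exp1", 30)
    flipped.rotation = -flipped.rotation
    a, b = run_model(s, params), run_model(flipped, params)
    np.testing.assert_allclose(a.hand[s.moves], -b.hand[s.moves], atol=1e-10)
    np.testing.assert_allclose(a.x_i, -b.x_i, atol=1e-10)


class TestDeterminism:
    def test_same_seed_bit_identical(self, ppe_params):
        s = build_schedule("exp1", 30)
        a = simulate_participant(s, ppe_params, NoiseSpec(), seed=11)
        b = simulate_participant(s, ppe_params, NoiseSpec(), seed=11)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_participant(s, ppe_params, NoiseSpec(), seed=12)
        assert not np.allclose(a["hand_deg"], c["hand_deg"], equal_nan=True)

    def test_group_seeding(self, ppe_params):
        a = simulate_group("exp1", 30, ppe_params, NoiseSpec(), 3, seed=5)
        b = simulate_group("exp1", 30, ppe_params, NoiseSpec(), 3, seed=5)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        p1 = a.for_participant("p01")["hand_deg"].to_numpy()
        p2 = a.for_participant("p02")["hand_deg"].to_numpy()
        assert not np.allclose(p1, p2, equal_nan=True)


class TestNoiseFreeOracles:
    def test_zero_noise_group_mean_is_deterministic_trajectory(
        self, ppe_params, zero_noise
    ):
        ds = simulate_group("exp1", 30, ppe_params, zero_noise, 5, seed=0)
        traj = run_model(ds.schedule, ppe_params)
        mean = ds.trials.groupby("trial")["hand_deg"].mean()
        moves = ds.schedule.moves & (ds.schedule.trial_type != "prop_test")
        idx = np.flatnonzero(moves) + 1
        np.testing.assert_allclose(mean.reindex(idx), traj.hand[idx - 1], atol=1e-12)

    def test_implicit_measure_equals_latent(self, ppe_params, zero_noise):
        ds = simulate_group("exp1", 60, ppe_params, zero_noise, 2, seed=0)
        m = extract_measures(ds)
        traj = run_model(ds.schedule, ppe_params)
        idx = np.flatnonzero(ds.schedule.trial_type == "exclusion") + 1
        np.testing.assert_allclose(
            m.implicit_series.reindex(idx), traj.x_i[idx - 1], atol=1e-12
        )
        assert m.implicit_late == pytest.approx(traj.x_i[idx - 1].mean())

    def test_probe_ppe_equals_model_error(self, ppe_params, zero_noise):
        ds = simulate_group("exp6", 30, ppe_params, zero_noise, 2, seed=0)
        m = extract_measures(ds, require=("probe_ppe",))
        traj = run_model(ds.schedule, ppe_params)
        idx = np.flatnonzero(
            (ds.schedule.trial_type == "probe") & (ds.schedule.phase == "adaptation")
        ) + 1
        np.testing.assert_allclose(
            m.probe_series.reindex(idx), traj.e_ppe[idx - 1], atol=1e-12
        )

    def test_prop_bias_matches_preceding_misperception(self, ppe_params, zero_noise):
        ds = simulate_group("exp1", 30, ppe_params, zero_noise, 1, seed=0)
        m = extract_measures(ds, require=("prop_bias",))
        traj = run_model(ds.schedule, ppe_params)
        # bias carried from the feedback trial immediately before each test
        idx = np.flatnonzero(
            (ds.schedule.trial_type == "prop_test")
            & (ds.schedule.phase == "adaptation")
        )
        expected = [traj.perceived[i - 1] - traj.hand[i - 1] for i in idx]
        np.testing.assert_allclose(m.prop_series.to_numpy(), expected, atol=1e-12)
        assert m.prop_bias < 0  # toward the perturbation

    def test_baseline_movements_are_zero(self, ppe_params, zero_noise):
        ds = simulate_group("exp1", 30, ppe_params, zero_noise, 1, seed=0)
        n_base = int((ds.schedule.phase == "baseline").sum())
        base = ds.trials[ds.trials["trial"] <= n_base]
        reaches = base[base["trial_type"] != "prop_test"]["hand_deg"]
        assert np.allclose(reaches, 0.0)

    def test_extraction_does_not_mutate_records(self, ppe_params):
        ds = simulate_group("exp1", 30, ppe_params, NoiseSpec(), 2, seed=3)
        before = ds.trials.copy()
        extract_measures(ds)
        extract_measures(ds)
        pd.testing.assert_frame_equal(ds.trials, before)

    def test_missing_measure_raises(self, ppe_params, zero_noise):
        ds = simulate_group("exp4", 45, ppe_params, zero_noise, 1, seed=0)
        with pytest.raises(ValueError):
            extract_measures(ds, require=("prop_bias",))


def test_mean_standard_error_shrinks_with_group_size(ppe_params):
    """Monte-Carlo check that the condition-mean noise scales as 1/sqrt(n)."""
    trial = 60  # an adaptation feedback trial of exp4/45
    spread = {}
    for n in (4, 16):
        means = []
        for rep in range(30):
            ds = simulate_group("exp4", 45, ppe_params, NoiseSpec(4.0, 0.0),
                                n, seed=1000 * n + rep)
            means.append(ds.trials[ds.trials["trial"] == trial]["hand_deg"].mean())
        spread[n] = np.std(means, ddof=1)
    ratio = spread[4] / spread[16]
    assert ratio == pytest.approx(2.0, rel=0.5)


class TestSingleTrialLearning:
    def test_requires_exp3(self, ppe_params):
        ds = simulate_group("exp1", 30, ppe_params, NoiseSpec(), 1, seed=0)
        with pytest.raises(ValueError):
            single_trial_learning(ds)

    def test_table_shape_and_zero_row(self, zero_noise):
        p = ModelParams(model_kind="PE", Be=0.0, Ae=0.0)
        ds = simulate_group("exp3", None, p, zero_noise, 1, seed=0)
        table = single_trial_learning(ds)
        assert table.index.tolist() == [0, 4, 8, 16, 32, 64]
        # learning scales roughly linearly with size for the PE model
        assert table.loc[64, "learning"] > table.loc[16, "learning"] > 0
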