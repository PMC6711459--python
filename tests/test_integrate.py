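import numpy as np
import pytest
from scipy.linalg import expm

from dcmfmri import (ConditionTiming, Dataset, HaemoState, IntegrationError,
                     ModelSpec, ParameterSet, SystemState, build_input_matrix,
                     default_spec, default_timings, default_true_params,
                     integrate_model, mean_centre, neural_jacobian, step)


def single_region_spec(TR=1.0, TE=0.03, n_confounds=0):
    return ModelSpec(["r1"], ["stim"], np.eye(1), np.zeros((1, 1, 1)),
                     np.ones((1, 1)), TR=TR, TE=TE, slice_times=[0.0],
                     n_confounds=n_confounds)


def fig3_model(n_volumes=50):
    spec = default_spec()
    U = mean_centre(build_input_matrix(default_timings(n_volumes, spec.TR),
                                       n_volumes * spec.TR, spec.TR / 16))
    return spec, U, default_true_params(spec)


class TestIntegrateModel:
    def test_rest_stays_at_rest(self):
        spec = single_region_spec()
        U = build_input_matrix([ConditionTiming("stim", (), ())], 20.0, 1 / 16)
        p = ParameterSet.zeros(spec)
        pred = integrate_model(p, spec, U, 20)
        assert np.allclose(pred.y_hat, 0.0, atol=1e-12)

    def test_confound_pass_through(self):
        spec = single_region_spec(n_confounds=1)
        U = build_input_matrix([ConditionTiming("stim", (), ())], 20.0, 1 / 16)
        p = ParameterSet.zeros(spec)
        p.beta0[0, 0] = 5.0
        pred = integrate_model(p, spec, U, 20)
        assert np.allclose(pred.y_hat, 5.0)

    def test_bold_peak_between_five_and_six_seconds(self):
        spec = single_region_spec()
        p = ParameterSet.zeros(spec)
        p.c[0, 0] = 1.0
        U = build_input_matrix([ConditionTiming("stim", (2.0,), (0.0,))], 32.0, 1 / 16)
        pred = integrate_model(p, spec, U, 32, store_states=True)
        t = pred.states["t"]
        latency = t[np.argmax(pred.states["bold"][:, 0])] - 2.0
        assert 5.0 <= latency <= 6.0

    def test_time_invariance_under_one_TR_shift(self):
        spec = single_region_spec(TR=2.0)
        p = ParameterSet.zeros(spec)
        p.c[0, 0] = 1.0
        V = 40
        total = (V + 1) * spec.TR
        mk = lambda shift: build_input_matrix(
            [ConditionTiming("stim", (10.0 + shift, 30.0 + shift), (4.0, 4.0))],
            total, spec.TR / 16)
        y0 = integrate_model(p, spec, mk(0.0), V + 1).y_hat
        y1 = integrate_model(p, spec, mk(spec.TR), V + 1).y_hat
        assert np.allclose(y1[1:], y0[:-1], atol=1e-9)

    def test_slice_timing_shifts_only_that_region(self):
        spec, U, p = fig3_model(40)
        base = integrate_model(p, spec, U, 40).y_hat
        spec_late = default_spec()
        spec_late.slice_times = spec.slice_times.copy()
        spec_late.slice_times[2] = spec.TR  # sample rvF at the end of the volume
        shifted = integrate_model(p, spec_late, U, 40).y_hat
        same = [0, 1, 3]
        assert np.array_equal(shifted[:, same], base[:, same])
        assert not np.allclose(shifted[:, 2], base[:, 2])

    def test_prediction_continuous_in_parameters(self):
        spec, U, p = fig3_model(30)
        base = integrate_model(p, spec, U, 30).y_hat
        p2 = default_true_params(spec)
        p2.a[1, 0] += 1e-6
        pert = integrate_model(p2, spec, U, 30).y_hat
        assert 0 < np.abs(pert - base).max() < 1e-4

    def test_blow_up_reported_with_bin(self):
        spec, U, p = fig3_model(30)
        p.a[0, 1] = p.a[1, 0] = 40.0  # explosive excitatory loop
        with pytest.raises(IntegrationError, match="bin"):
            integrate_model(p, spec, U, 30)

    def test_insufficient_input_duration_rejected(self):
        spec = single_region_spec()
        U = build_input_matrix([ConditionTiming("stim", (), ())], 10.0, 1 / 16)
        with pytest.raises(ValueError, match="duration"):
            integrate_model(ParameterSet.zeros(spec), spec, U, 20)


class TestStep:
    def test_zero_flow_leaves_state_unchanged(self):
        spec = single_region_spec()
        p = ParameterSet.zeros(spec)
        state = SystemState.rest(1)
        out = step(state, [0.0], p, 0.1)
        assert np.allclose(out.z, 0.0)
        assert np.allclose(out.haemo.f, 1.0)
        assert np.allclose(out.haemo.v, 1.0)
        assert np.allclose(out.haemo.q, 1.0)

    def test_neural_subsystem_matches_matrix_exponential(self):
        # the neural states are linear at fixed input, so exp(J dt) is exact
        spec = default_spec()
        rng = np.random.default_rng(1)
        p = ParameterSet.zeros(spec)
        p.a = rng.normal(0, 0.3, (4, 4))
        u = np.zeros(3)
        z0 = rng.normal(0, 1, 4)
        dt = spec.TR / 16
        state = SystemState(z=z0, haemo=HaemoState.rest(4))
        out = step(state, u, p, dt)
        want = expm(neural_jacobian(p, u) * dt) @ z0
        assert np.abs(out.z - want).max() < 1e-8

    def test_single_region_closed_form_decay(self):
        # dz/dt = -0.5 z  =>  z(t) = exp(-0.5 t)
        spec = single_region_spec()
        p = ParameterSet.zeros(spec)
        state = SystemState(z=[1.0], haemo=HaemoState.rest(1))
        for _ in range(200):
            state = step(state, [0.0], p, 0.01)
        assert abs(state.z[0] - np.exp(-1.0)) < 1e-6

    def test_step_halving_converged(self):
        spec, U, p = fig3_model(40)
        y1 = integrate_model(p, spec, U, 40, n_substeps=4).y_hat
        y2 = integrate_model(p, spec, U, 40, n_substeps=8).y_hat
        rel = np.abs(y2 - y1).max() / np.abs(y2).max()
        assert rel < 1e-4

    def test_bad_dt_rejected(self):
        spec = single_region_spec()
        with pytest.raises(ValueError, match="dt"):
            step(SystemState.rest(1), [0.0], ParameterSet.zeros(spec), 0.0)


class TestDataset:
    def test_validation(self):
        U = build_input_matrix([ConditionTiming("c", (), ())], 10.0, 0.1)
        with pytest.raises(ValueError, match="finite"):
            Dataset(U=U, Y=np.array([[np.nan], [0.0]]), TR=1.0, slice_times=[0.5])
        with pytest.raises(ValueError, match="slice"):
            Dataset(U=U, Y=np.zeros((5, 1)), TR=1.0, slice_times=[2.0])
        d = Dataset(U=U, Y=np.zeros((5, 1)), TR=1.0, slice_times=[0.5])
        assert d.X0.shape == (5, 1)  # default constant confound column
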