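"""Forward-model tests: stimulus discretization, the bilinear state
equation, the balloon observation cascade, and the sampled simulator."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from gazedcm import _integrate, synth
from gazedcm.forward import (DCMParameters, InputChannel, StimulusDesign,
                             build_stimulus_inputs, effective_jacobian,
                             hemodynamic_bold, integrate_model,
                             neuronal_derivative, simulate_bold)

from conftest import simple_design, two_node_params


# ------------------------------------------------------------ inputs

class TestStimulusInputs:
    def test_boxcar_definition(self):
        des = StimulusDesign(
            (InputChannel("d", np.array([10.0]), np.array([4.0])),),
            dt=0.1, total_duration=30.0)
        U = build_stimulus_inputs(des)
        assert U.shape == (300, 1)
        assert U.sum() == pytest.approx(40.0)
        assert set(np.unique(U)) == {0.0, 1.0}
        assert np.all(U[100:140, 0] == 1.0)

    def test_mean_centering_identity(self):
        des = StimulusDesign(
            (InputChannel("d", np.array([5.0, 20.0]), np.array([4.0, 4.0]),
                          mean_center=True),),
            dt=0.125, total_duration=40.0)
        U = build_stimulus_inputs(des)
        assert abs(U[:, 0].mean()) < 1e-12

    def test_modulator_support_inside_driving_support(self):
        td = synth.make_task_design(n_scene_runs=1, n_scrambled_runs=0,
                                    seed=5)
        des = td.condition_design("scene")
        U = build_stimulus_inputs(des)
        # rebuild the driving channel without centering to get its support
        raw = StimulusDesign(
            (InputChannel("d", des.channels[0].onsets,
                          des.channels[0].durations),),
            des.dt, des.total_duration, des.run_boundaries)
        drive = build_stimulus_inputs(raw)[:, 0]
        assert np.all(drive[U[:, 1] > 0] == 1.0)

    def test_overlap_merges_with_warning(self):
        des = StimulusDesign(
            (InputChannel("d", np.array([5.0, 7.0]), np.array([4.0, 4.0])),),
            dt=0.1, total_duration=20.0)
        with pytest.warns(UserWarning, match="overlap"):
            U = build_stimulus_inputs(des)
        assert U[:, 0].max() == 1.0
        assert U[:, 0].sum() == pytest.approx(60.0)  # 5..11 s merged

    def test_onset_beyond_duration_errors(self):
        with pytest.raises(ValueError, match="beyond"):
            StimulusDesign(
                (InputChannel("d", np.array([25.0]), np.array([4.0])),),
                dt=0.1, total_duration=20.0)


# ------------------------------------------------------- state equation

class TestStateEquation:
    def test_jacobian_at_zero(self, regions3):
        p = DCMParameters(np.zeros((3, 3)), np.zeros((1, 3, 3)),
                          np.zeros((3, 2)))
        J = effective_jacobian(p, np.zeros(2))
        assert np.allclose(np.diag(J), -0.5)
        assert np.allclose(J - np.diag(np.diag(J)), 0.0)

    def test_self_connection_log_scale(self):
        # printed PPA self-connection 0.407 -> -0.5 e^0.407 Hz
        p = DCMParameters(np.diag([0.0, 0.407, 0.0]), np.zeros((1, 3, 3)),
                          np.zeros((3, 2)))
        J = effective_jacobian(p, np.zeros(2))
        assert J[1, 1] == pytest.approx(-0.5 * np.exp(0.407))
        assert J[1, 1] == pytest.approx(-0.7511, abs=1e-4)

    def test_modulation_is_additive_between_regions(self):
        # A OCP->PPA 0.747 plus free-viewing modulation 0.346 -> 1.093 Hz
        A = np.zeros((3, 3)); A[1, 0] = 0.747
        B = np.zeros((1, 3, 3)); B[0, 1, 0] = 0.346
        p = DCMParameters(A, B, np.zeros((3, 2)))
        J = effective_jacobian(p, np.array([0.3, 1.0]))
        assert J[1, 0] == pytest.approx(1.093)

    def test_derivative_decay(self):
        p = DCMParameters(np.zeros((3, 3)), np.zeros((1, 3, 3)),
                          np.zeros((3, 2)))
        dz = neuronal_derivative(np.array([1.0, 0, 0]), np.zeros(2), p)
        assert np.allclose(dz, [-0.5, 0, 0])

    def test_derivative_driving_input(self):
        # printed scene driving input 0.638 into the OCP
        C = np.zeros((3, 2)); C[0, 0] = 0.638
        p = DCMParameters(np.zeros((3, 3)), np.zeros((1, 3, 3)), C)
        dz = neuronal_derivative(np.zeros(3), np.array([1.0, 0.0]), p)
        assert np.allclose(dz, [0.638, 0, 0])

    def test_fixed_point(self):
        p = DCMParameters(np.random.default_rng(0).normal(0, 0.1, (3, 3)),
                          np.zeros((1, 3, 3)), np.zeros((3, 2)))
        assert np.allclose(
            neuronal_derivative(np.zeros(3), np.ones(2), p), 0.0)

    def test_dimension_mismatch(self):
        p = DCMParameters(np.zeros((3, 3)), np.zeros((1, 3, 3)),
                          np.zeros((3, 2)))
        with pytest.raises(ValueError):
            neuronal_derivative(np.zeros(2), np.zeros(2), p)
        with pytest.raises(ValueError):
            neuronal_derivative(np.zeros(3), np.zeros(3), p)

    def test_nonfinite_input_errors(self):
        p = DCMParameters(np.zeros((3, 3)), np.zeros((1, 3, 3)),
                          np.zeros((3, 2)))
        with pytest.raises(ValueError):
            effective_jacobian(p, np.array([np.nan, 0.0]))


# --------------------------------------------------------- hemodynamics

def balloon_oracle(z_of_t, t_end, dt_eval, kappa=0.64, tau=2.0, eps=1.0):
    """Independent fine-step integration of the balloon cascade in natural
    coordinates (scipy RK45), for one region."""
    E0, gamma, alpha = _integrate.E0, _integrate.GAMMA0, _integrate.ALPHA0

    def rhs(t, x):
        s, f, v, q = x
        fv = v ** (1 / alpha)
        ef = 1 - (1 - E0) ** (1 / f)
        return [z_of_t(t) - kappa * s - gamma * (f - 1), s,
                (f - fv) / tau, (f * ef / E0 - fv * q / v) / tau]

    sol = solve_ivp(rhs, (0, t_end), [0, 1, 1, 1], rtol=1e-9, atol=1e-11,
                    t_eval=np.arange(0, t_end, dt_eval), max_step=0.05)
    s, f, v, q = sol.y
    return 100 * _integrate.V0 * eps * (
        _integrate.K1 * (1 - q) + _integrate.K2 * (1 - q / v)
        + _integrate.K3 * (1 - v))


class TestHemodynamics:
    def test_rest_gives_zero(self):
        z = np.zeros((400, 2))
        bold = hemodynamic_bold(z, np.zeros((2, 3)), dt=0.125)
        assert np.allclose(bold, 0.0)

    def test_peak_latency_and_return(self):
        # 0.5 s unit excursion of z: BOLD peaks 3-7 s later, then decays
        dt = 0.125
        n = int(40 / dt)
        z = np.zeros((n, 1))
        z[:int(0.5 / dt), 0] = 1.0
        bold = hemodynamic_bold(z, np.zeros((1, 3)), dt=dt)[:, 0]
        t_peak = np.argmax(bold) * dt
        assert 3.0 <= t_peak <= 7.0
        assert abs(bold[-1]) < 0.2 * bold.max()
        # agree with the independent fine-step oracle
        oracle = balloon_oracle(lambda t: 1.0 * (t < 0.5), 40, dt)
        assert np.max(np.abs(bold - oracle)) < 1e-3

    def test_region_symmetry(self):
        rng = np.random.default_rng(3)
        z1 = rng.normal(0, 0.2, 300)
        z = np.column_stack([z1, z1])
        bold = hemodynamic_bold(z, np.zeros((2, 3)), dt=0.125)
        assert np.allclose(bold[:, 0], bold[:, 1])


# ------------------------------------------------------------ simulator

class TestSimulateBold:
    def test_no_input_no_signal(self, full_switch, design2):
        p = DCMParameters(np.zeros((3, 3)), np.zeros((1, 3, 3)),
                          np.zeros((3, 2)))
        b = simulate_bold(p, full_switch, design2, noise_sd=0.0)
        assert np.allclose(b.values, 0.0)

    def test_no_propagation_path(self, full_switch, design2):
        C = np.zeros((3, 2)); C[0, 0] = 0.6
        p = DCMParameters(np.zeros((3, 3)), np.zeros((1, 3, 3)), C)
        b = simulate_bold(p, full_switch, design2, noise_sd=0.0)
        assert np.abs(b.values[:, 0]).max() > 0
        assert np.allclose(b.values[:, 1:], 0.0)

    def test_determinism(self, full_switch, design2, mean_params):
        b1 = simulate_bold(mean_params, full_switch, design2, noise_sd=0.1,
                           seed=42)
        b2 = simulate_bold(mean_params, full_switch, design2, noise_sd=0.1,
                           seed=42)
        assert np.array_equal(b1.values, b2.values)

    def test_switch_masks_disabled_entries(self, full_switch, design2,
                                           mean_params):
        p = mean_params.copy()
        p.A[2, 0] = 5.0  # disabled HPC<-OCP entry must have no effect
        b1 = simulate_bold(p, full_switch, design2, noise_sd=0.0)
        b0 = simulate_bold(mean_params, full_switch, design2, noise_sd=0.0)
        assert np.allclose(b1.values, b0.values)


# ----------------------------------------------------------- properties

class TestDynamicalProperties:
    def test_linear_regime_homogeneity(self, design2):
        # no self-modulation, small drive: doubling C doubles the peak z
        U = build_stimulus_inputs(design2)
        reset = np.array([0], dtype=np.int64)
        peaks = []
        for c in (0.05, 0.1):
            p = two_node_params(c=c, b_forward=0.0)
            out = np.zeros((U.shape[0], 2))
            code = _integrate.integrate_neuronal(
                p.A, p.B, p.C, np.diag(p.A).copy(),
                np.diagonal(p.B, axis1=1, axis2=2).copy(),
                U, design2.dt, reset, out)
            assert code == 0
            peaks.append(np.abs(out).max())
        assert peaks[1] / peaks[0] == pytest.approx(2.0, rel=0.05)

    def test_stability_moderate_coupling(self, design2):
        rng = np.random.default_rng(7)
        A = rng.uniform(-0.4, 0.4, (3, 3))
        np.fill_diagonal(A, 0.0)
        p = DCMParameters(A, np.zeros((1, 3, 3)),
                          np.array([[0.638, 0], [0, 0], [0, 0]]))
        U = build_stimulus_inputs(design2)
        out = np.zeros((U.shape[0], 3))
        code = _integrate.integrate_neuronal(
            p.A, p.B, p.C, np.diag(p.A).copy(),
            np.diagonal(p.B, axis1=1, axis2=2).copy(),
            U, design2.dt, np.array([0], dtype=np.int64), out)
        assert code == 0
        assert np.abs(out).max() < 10.0

    def test_integrator_step_convergence(self, mean_params, full_switch):
        # onsets lie on both microtime grids so the comparison isolates
        # the integration scheme from input quantization
        vals = {}
        for dt in (0.125, 0.0625):
            des = simple_design(n_trials=30, gap=3.0, dur=4.0, dt=dt)
            vals[dt], _ = integrate_model(mean_params.masked(full_switch),
                                          des, 2.0)
        assert np.max(np.abs(vals[0.125] - vals[0.0625])) < 1e-3
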