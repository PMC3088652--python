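import math

import numpy as np
import pytest
from scipy.signal import lfilter

from spikethresh import (
    MembraneParams,
    voltage_ramp_current,
    NaChannelParams,
    NoiseThresholdParams,
    SimConfig,
    SimulationError,
    StimulusSpec,
    ThresholdModel,
    h_inf,
    measure_steady_state_threshold_empirical,
    simulate_ieif,
    simulate_ilif,
    simulate_ilif_vdep_tau,
    simulate_stochastic_threshold,
    slope_threshold,
    steady_state_threshold,
    threshold_from_h,
)

IEIF_CHANNEL = NaChannelParams(V_T=-58.0, V_i=-63.0, k_a=5.0, k_i=6.0, tau_i=5.0)


class TestIEIF:
    def test_rest_is_stable_without_input(self, membrane):
        cfg = SimConfig(dt=0.01, duration=200.0)
        tr = simulate_ieif(IEIF_CHANNEL, membrane, 0.0, cfg)
        assert tr.n_spikes == 0
        # rest sits a whisker above E_L because of the standing Na current
        assert np.all(np.abs(tr.V - membrane.E_L) < 1.0)

    def test_constant_suprathreshold_current_spikes_periodically(self, membrane):
        cfg = SimConfig(dt=0.01, duration=500.0)
        tr = simulate_ieif(IEIF_CHANNEL, membrane, 25.0, cfg)
        assert tr.n_spikes > 8
        isi = np.diff(tr.spike_times)
        # once h has equilibrated the orbit is periodic
        assert np.ptp(isi[5:]) < 0.05

    def test_deterministic_across_repeated_runs(self, membrane):
        cfg = SimConfig(dt=0.01, duration=500.0, seed=5)
        spec = StimulusSpec(kind="ou", mean=20.0, sigma=8.0, tau_c=2.0)
        a = simulate_ieif(IEIF_CHANNEL, membrane, spec, cfg)
        b = simulate_ieif(IEIF_CHANNEL, membrane, spec, cfg)
        np.testing.assert_array_equal(a.V, b.V)
        assert a.n_spikes == b.n_spikes

    def test_clamped_inactivation_relaxes_with_tau_i(self, membrane):
        # voltage clamp step: h decays exponentially toward h_inf(V0)
        cfg = SimConfig(dt=0.01, duration=60.0)
        V0 = -60.0
        n = int(round(cfg.duration / cfg.dt))
        tr = simulate_ieif(IEIF_CHANNEL, membrane, None, cfg,
                           h_init=1.0, V_clamp=np.full(n, V0))
        hinf = h_inf(V0, IEIF_CHANNEL)
        expected = hinf + (1.0 - hinf) * np.exp(-tr.t / IEIF_CHANNEL.tau_i)
        np.testing.assert_allclose(tr.h, expected, atol=2e-3)

    def test_blow_up_reported_not_clipped(self, membrane):
        cfg = SimConfig(dt=0.01, duration=50.0)
        with pytest.raises(SimulationError):
            simulate_ieif(IEIF_CHANNEL, membrane, -800.0, cfg)


class TestILIF:
    def test_subthreshold_input_never_spikes_and_theta_tracks(
        self, model_piecewise, membrane
    ):
        cfg = SimConfig(dt=0.01, duration=2000.0)
        ramp = StimulusSpec(kind="ramp", mean=0.0, slope=0.005)  # very slow
        tr = simulate_ilif(model_piecewise, membrane, ramp, cfg)
        assert tr.n_spikes == 0
        # quasi-static: theta close to theta_inf(V) for slow drive
        thinf = np.asarray(steady_state_threshold(tr.V, model_piecewise))
        assert np.max(np.abs(tr.theta - thinf)) < 0.1

    def test_ramp_threshold_matches_analytic_slope_threshold(
        self, model_piecewise, membrane
    ):
        for s in (2.0, 4.0, 8.0):
            dur = (20.0 + 80.0 / s) // 1
            cfg = SimConfig(dt=0.01, duration=dur)
            # prescribe the voltage ramp V = E_L + s t through the membrane
            I = voltage_ramp_current(s, membrane.tau_m, membrane.R, cfg.dt, dur)
            tr = simulate_ilif(model_piecewise, membrane, I, cfg)
            assert tr.n_spikes >= 1
            ana = slope_threshold(s, model_piecewise, E_L=membrane.E_L).theta_star
            assert tr.threshold_at_spike[0] == pytest.approx(ana, abs=0.2)

    def test_threshold_dynamics_never_alter_subthreshold_voltage(self, membrane):
        # V series identical regardless of threshold parameters (no spikes)
        cfg = SimConfig(dt=0.01, duration=500.0, seed=2)
        spec = StimulusSpec(kind="ou", mean=3.0, sigma=2.0, tau_c=5.0)
        traces = []
        for tau_theta, k_i in ((1.0, 6.0), (20.0, 3.0)):
            ch = NaChannelParams(V_T=-55, V_i=-63, k_a=6, k_i=k_i)
            m = ThresholdModel(channel=ch, tau_theta=tau_theta)
            traces.append(simulate_ilif(m, membrane, spec, cfg))
        assert all(t.n_spikes == 0 for t in traces)
        np.testing.assert_array_equal(traces[0].V, traces[1].V)

    def test_threshold_is_first_order_lowpass_of_steady_state_drive(
        self, model_piecewise, membrane
    ):
        # between spikes theta is exactly the AR(1) filter of theta_inf(V)
        cfg = SimConfig(dt=0.01, duration=300.0, seed=8)
        spec = StimulusSpec(kind="ou", mean=4.0, sigma=2.5, tau_c=5.0)
        tr = simulate_ilif(model_piecewise, membrane, spec, cfg)
        assert tr.n_spikes == 0
        alpha = cfg.dt / model_piecewise.tau_theta
        drive = np.asarray(steady_state_threshold(tr.V, model_piecewise))[:-1]
        ref = lfilter([alpha], [1.0, -(1.0 - alpha)], drive,
                      zi=[(1.0 - alpha) * tr.theta[0]])[0]
        np.testing.assert_allclose(tr.theta[1:], ref, atol=1e-10)

    def test_voltage_stays_below_threshold_between_spikes(
        self, model_piecewise, membrane
    ):
        cfg = SimConfig(dt=0.01, duration=2000.0, seed=3)
        spec = StimulusSpec(kind="ou", mean=15.0, sigma=12.0, tau_c=2.0)
        tr = simulate_ilif(model_piecewise, membrane, spec, cfg)
        assert tr.n_spikes > 5
        viol = tr.V >= tr.theta
        # violations only at reset samples (V back at E_L)
        assert np.all(tr.V[viol] == membrane.E_L) if viol.any() else True
        assert np.all(tr.theta >= model_piecewise.channel.V_T - 1e-12)

    def test_hold_refractory_pins_voltage_at_rest(self, model_piecewise, membrane):
        cfg = SimConfig(dt=0.01, duration=300.0, refractory_mode="hold",
                        hold_duration=5.0)
        tr = simulate_ilif(model_piecewise, membrane, 40.0, cfg)
        assert tr.n_spikes >= 1
        k = int(tr.spike_times[0] / cfg.dt) + 1
        hold = tr.V[k: k + int(5.0 / cfg.dt)]
        assert np.all(hold == membrane.E_L)

    def test_increment_refractory_bumps_threshold(self, model_piecewise, membrane):
        cfg = SimConfig(dt=0.01, duration=300.0, refractory_mode="increment",
                        increment=3.6)
        tr = simulate_ilif(model_piecewise, membrane, 40.0, cfg)
        assert tr.n_spikes >= 1
        k = int(tr.spike_times[0] / cfg.dt) + 1
        jump = tr.theta[k] - tr.theta[k - 1]
        assert jump == pytest.approx(3.6, abs=0.1)

    def test_spike_times_converge_when_halving_dt(self, membrane):
        # mild adaptation (slope ratio 1/2) sustains repetitive DC firing
        ch = NaChannelParams(V_T=-55, V_i=-63, k_a=6, k_i=12)
        m = ThresholdModel(channel=ch, tau_theta=5.0, steady_state_mode="piecewise")
        times = {}
        for dt in (0.02, 0.01):
            cfg = SimConfig(dt=dt, duration=400.0)
            tr = simulate_ilif(m, membrane, 30.0, cfg)
            times[dt] = tr.spike_times
        n = min(len(times[0.02]), len(times[0.01]))
        assert n >= 5
        assert np.max(np.abs(times[0.02][:n] - times[0.01][:n])) < 0.02 * 5

    def test_threshold_offset_hook_shifts_spiking(self, membrane):
        ch = NaChannelParams(V_T=-55, V_i=-63, k_a=6, k_i=12)
        base = ThresholdModel(channel=ch, tau_theta=5.0,
                              steady_state_mode="piecewise")
        lifted = ThresholdModel(channel=ch, tau_theta=5.0,
                                steady_state_mode="piecewise",
                                threshold_offset=lambda t: 5.0)
        cfg = SimConfig(dt=0.01, duration=300.0)
        tr0 = simulate_ilif(base, membrane, 30.0, cfg)
        tr1 = simulate_ilif(lifted, membrane, 30.0, cfg)
        assert tr1.spike_times[0] > tr0.spike_times[0]
        assert tr1.threshold_at_spike[0] > tr0.threshold_at_spike[0]


class TestChangeOfVariableOracle:
    def test_ilif_theta_matches_ieif_h_mapping_under_clamp(self, membrane):
        """Under a slowly varying clamped V, the iEIF inactivation gate mapped
        through theta = V_T - k_a ln(h) follows the iLIF threshold equation."""
        ch = NaChannelParams(V_T=-55.0, V_i=-63.0, k_a=6.0, k_i=6.0, tau_i=5.0)
        model = ThresholdModel(channel=ch, tau_theta=ch.tau_i)  # exact curve
        dt, dur = 0.01, 600.0
        t = np.arange(int(dur / dt)) * dt
        V = -70.0 + 5.0 * np.sin(2 * np.pi * t / 200.0) + 4.0 * (t / dur)
        cfg = SimConfig(dt=dt, duration=dur)
        tr = simulate_ieif(ch, membrane, None, cfg, V_clamp=V)
        theta_from_gate = np.asarray(threshold_from_h(tr.h, ch))
        # iLIF threshold under the same V trajectory (same Euler update)
        thinf = np.asarray(steady_state_threshold(V, model))
        theta = np.empty_like(V)
        theta[0] = theta_from_gate[0]
        alpha = dt / model.tau_theta
        for k in range(1, V.size):
            theta[k] = theta[k - 1] + alpha * (thinf[k - 1] - theta[k - 1])
        assert np.max(np.abs(theta - theta_from_gate)) < 0.1


class TestVoltageDependentTau:
    def test_constant_function_reduces_to_plain_ilif(self, model_piecewise, membrane):
        cfg = SimConfig(dt=0.01, duration=300.0, seed=4)
        spec = StimulusSpec(kind="ou", mean=10.0, sigma=5.0, tau_c=2.0)
        a = simulate_ilif(model_piecewise, membrane, spec, cfg)
        b = simulate_ilif_vdep_tau(model_piecewise, membrane, spec, cfg,
                                   tau_theta_of_V=lambda v: 5.0)
        np.testing.assert_allclose(a.V, b.V, atol=1e-12)
        np.testing.assert_allclose(a.theta, b.theta, atol=1e-12)
        assert a.n_spikes == b.n_spikes

    def test_depolarization_speeds_adaptation_when_tau_decreases_with_V(
        self, model_piecewise, membrane
    ):
        # step to two plateau levels; fit the threshold relaxation time
        def tau_of_V(v):
            return max(5.0 - 0.25 * (v + 70.0), 0.5)

        def relax_time(drive):
            cfg = SimConfig(dt=0.01, duration=200.0)
            tr = simulate_ilif_vdep_tau(model_piecewise, membrane, drive, cfg,
                                        tau_theta_of_V=tau_of_V)
            assert tr.n_spikes == 0
            th = tr.theta
            target = th[-1]
            amp = target - th[0]
            k = np.nonzero(th - th[0] >= (1 - math.exp(-1)) * amp)[0][0]
            return tr.t[k]

        assert relax_time(11.0) < relax_time(8.5)

    def test_nonpositive_tau_rejected(self, model_piecewise, membrane):
        cfg = SimConfig(dt=0.01, duration=50.0)
        with pytest.raises(SimulationError):
            simulate_ilif_vdep_tau(model_piecewise, membrane, 10.0, cfg,
                                   tau_theta_of_V=lambda v: -1.0)


class TestStochasticThresholdControl:
    def test_zero_noise_recovers_mean_threshold(self, membrane):
        noise = NoiseThresholdParams(theta0=-55.0, sigma_theta=0.0, tau_N=5.0)
        cfg = SimConfig(dt=0.01, duration=1.0, seed=1)
        out = simulate_stochastic_threshold(noise, membrane, [2.0], cfg, n_trials=20)
        np.testing.assert_allclose(out[2.0], -55.0, atol=1e-9)

    def test_fast_ramps_sample_the_stationary_distribution(self, membrane):
        noise = NoiseThresholdParams(theta0=-55.0, sigma_theta=2.0, tau_N=5.0)
        cfg = SimConfig(dt=0.01, duration=1.0, seed=2)
        out = simulate_stochastic_threshold(noise, membrane, [500.0], cfg,
                                            n_trials=400)
        assert np.mean(out[500.0]) == pytest.approx(-55.0, abs=3 * 2.0 / 20.0)

    def test_mean_sampled_threshold_increases_with_slope(self, membrane):
        noise = NoiseThresholdParams(theta0=-55.0, sigma_theta=2.0, tau_N=5.0)
        cfg = SimConfig(dt=0.01, duration=1.0, seed=3)
        out = simulate_stochastic_threshold(noise, membrane, [0.2, 2.0, 50.0],
                                            cfg, n_trials=300)
        means = [np.mean(out[s]) for s in (0.2, 2.0, 50.0)]
        assert means[0] < means[1] < means[2]


class TestClampAndRelease:
    def test_matches_analytic_steady_state_threshold(self, membrane):
        ch = IEIF_CHANNEL
        for V0 in (-80.0, -70.0, -63.0):
            measured = measure_steady_state_threshold_empirical(V0, ch, membrane)
            expected = threshold_from_h(h_inf(V0, ch), ch)
            assert measured == pytest.approx(expected, abs=0.5)

    def test_deep_hyperpolarization_recovers_minimum_threshold(self, membrane):
        measured = measure_steady_state_threshold_empirical(-100.0, IEIF_CHANNEL,
                                                            membrane)
        assert measured == pytest.approx(IEIF_CHANNEL.V_T, abs=0.5)

    def test_nondecreasing_in_clamp_level(self, membrane):
        vals = [
            measure_steady_state_threshold_empirical(v0, IEIF_CHANNEL, membrane)
            for v0 in (-85.0, -72.0, -62.0)
        ]
        assert vals[0] <= vals[1] + 0.1 <= vals[2] + 0.2
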