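"""Ground-truth simulators: waveform contracts, reproducibility, statistics."""

import numpy as np
import pytest

from dgephys.core import StimulusProtocol
from dgephys.simulate import (
    APShape,
    IVComponent,
    PSCShape,
    SynapseModel,
    biexp_peak_factor,
    psc_waveform,
    simulate_field_sweep,
    simulate_iv_family,
    simulate_spike_train,
    simulate_step_response,
    simulate_sweepset,
)

RATE = 20000.0
DT = 1000.0 / RATE


class TestPSCWaveform:
    def test_peak_normalization_inward(self):
        shape = PSCShape(amplitude_pa=100.0, tau_rise_ms=1.0, tau_decay_ms=10.0, polarity=-1)
        tr = psc_waveform(shape, duration_ms=100.0, rate_hz=RATE)
        assert tr.samples.min() == pytest.approx(-100.0, abs=0.1)
        assert tr.samples[0] == pytest.approx(0.0, abs=1e-9)

    def test_charge_closed_form(self):
        """Unnormalized kernel integral over [0, inf) equals taud - taur."""
        taur, taud = 1.0, 10.0
        shape = PSCShape(amplitude_pa=1.0, tau_rise_ms=taur, tau_decay_ms=taud, polarity=1)
        tr = psc_waveform(shape, duration_ms=400.0, rate_hz=RATE)
        # waveform = unnormalized kernel / peak_factor; undo the normalization
        charge = np.sum(tr.samples) * DT * biexp_peak_factor(taur, taud)
        assert charge == pytest.approx(taud - taur, rel=1e-3)

    def test_equal_taus_rejected(self):
        with pytest.raises(ValueError):
            PSCShape(amplitude_pa=1.0, tau_rise_ms=5.0, tau_decay_ms=5.0)


class TestSimulateSweepset:
    def test_all_failures_pure_noise(self, single_pulse_protocol, ipsc_shape):
        model = SynapseModel(
            shape=ipsc_shape, failure_prob=1.0, spont_rate_hz=0.0, noise_sd_pa=2.0
        )
        ss, gt = simulate_sweepset(model, single_pulse_protocol, n_sweeps=5, seed=0)
        assert gt.n_events == 0
        assert not gt.success.any()
        # pure noise: no sweep mean should deviate from 0 appreciably
        assert abs(ss.data().mean()) < 0.5

    def test_no_failures_all_success(self, single_pulse_protocol, ipsc_shape):
        model = SynapseModel(shape=ipsc_shape, failure_prob=0.0, noise_sd_pa=1.0)
        ss, gt = simulate_sweepset(model, single_pulse_protocol, n_sweeps=50, seed=1)
        assert gt.success.all()
        assert gt.n_events == 50
        assert all(e.label == "evoked" for e in gt.events)

    def test_failure_rate_binomial(self, single_pulse_protocol, ipsc_shape):
        """failure_prob 0.5 over 400 trials: success fraction ~Binomial."""
        in_band = 0
        for seed in range(30):
            model = SynapseModel(shape=ipsc_shape, failure_prob=0.5, noise_sd_pa=1.0)
            ss, gt = simulate_sweepset(
                model, single_pulse_protocol, n_sweeps=400, seed=seed, duration_ms=150.0
            )
            if 0.45 <= gt.success_fraction() <= 0.55:
                in_band += 1
        assert in_band >= 28  # ~96% binomial coverage of +-2 sigma

    def test_evoked_latency_bounds(self, single_pulse_protocol, ipsc_shape):
        model = SynapseModel(
            shape=ipsc_shape, failure_prob=0.0, latency_mean_ms=2.0,
            latency_jitter_sd_ms=0.3, noise_sd_pa=1.0,
        )
        _, gt = simulate_sweepset(model, single_pulse_protocol, n_sweeps=100, seed=2)
        lat = np.array([e.onset_ms for e in gt.events]) - 100.0
        assert (lat > 0).all() and (lat < 2.0 + 5 * 0.3).all()

    def test_spontaneous_rate_poisson(self, single_pulse_protocol, ipsc_shape):
        """Spontaneous count within 3 SD of the Poisson expectation."""
        model = SynapseModel(
            shape=ipsc_shape, failure_prob=1.0, spont_rate_hz=2.0, noise_sd_pa=1.0
        )
        _, gt = simulate_sweepset(
            model, single_pulse_protocol, n_sweeps=100, seed=3, duration_ms=500.0
        )
        expected = 2.0 * 0.5 * 100  # rate * duration_s * sweeps
        assert abs(gt.n_events - expected) <= 3 * np.sqrt(expected)

    def test_train_scale_reflected_in_truth(self, train_protocol, ipsc_shape):
        scale = (1.0, 0.8, 0.7, 0.6, 0.5)
        model = SynapseModel(
            shape=ipsc_shape, failure_prob=0.0, train_scale=scale, noise_sd_pa=1.0
        )
        _, gt = simulate_sweepset(model, train_protocol, n_sweeps=10, seed=4)
        for e in gt.events:
            assert e.amplitude_pa == pytest.approx(
                ipsc_shape.amplitude_pa * scale[e.pulse_index]
            )

    def test_seed_reproducibility(self, single_pulse_protocol, reliable_synapse):
        a, _ = simulate_sweepset(reliable_synapse, single_pulse_protocol, 5, seed=9)
        b, _ = simulate_sweepset(reliable_synapse, single_pulse_protocol, 5, seed=9)
        c, _ = simulate_sweepset(reliable_synapse, single_pulse_protocol, 5, seed=10)
        np.testing.assert_array_equal(a.data(), b.data())
        assert not np.array_equal(a.data(), c.data())


class TestIVFamily:
    def test_ohmic_peaks(self):
        shape = PSCShape(amplitude_pa=1.0, tau_rise_ms=1.0, tau_decay_ms=10.0)
        fam = simulate_iv_family(
            1.0, -30.0, [-70.0, -50.0, -30.0, -10.0], shape, noise_sd_pa=0.0, seed=0
        )
        # at holding = e_rev the driving force is zero
        assert np.max(np.abs(fam[-30.0].data())) == pytest.approx(0.0, abs=1e-9)
        # g=1 nS, V=-70, e_rev=-30 -> peak -40 pA
        assert fam[-70.0].sweeps[0].samples.min() == pytest.approx(-40.0, abs=0.1)
        assert fam[-10.0].sweeps[0].samples.max() == pytest.approx(20.0, abs=0.1)

    def test_two_component_biphasic(self):
        comps = [
            IVComponent(1.0, -30.0, PSCShape(1, 0.5, 4.0), latency_ms=1.5),
            IVComponent(0.8, -65.0, PSCShape(1, 5.0, 40.0), latency_ms=25.0),
        ]
        fam = simulate_iv_family(
            None, None, [-70.0, -50.0, -20.0], PSCShape(1, 1, 10),
            noise_sd_pa=0.0, seed=0, components=comps,
        )
        sweep = fam[-50.0].sweeps[0]
        t = sweep.times_ms - 20.0  # stim onset
        early = sweep.samples[(t > 0) & (t < 10)]
        late = sweep.samples[(t > 30) & (t < 100)]
        # proximal reverses above -50 (inward), distal below (outward)
        assert early.min() < 0 < late.max()

    def test_too_few_holdings_rejected(self):
        with pytest.raises(ValueError):
            simulate_iv_family(1.0, -30.0, [-70.0, -50.0], PSCShape(1, 1, 10), 0.0, 0)


class TestStepAndSpikes:
    def test_steady_state_ohms_law(self):
        tr = simulate_step_response(100.0, 20.0, step_mv=-10.0)
        t = tr.times_ms
        plateau = tr.samples[(t > 100.0) & (t < 119.0)]  # late in the step
        assert plateau.mean() == pytest.approx(-100.0, rel=0.02)

    def test_transient_time_constant(self):
        """tau = R*C = 2 ms: transient decays e-fold at t = tau."""
        tr = simulate_step_response(100.0, 20.0, step_mv=-10.0, step_start_ms=20.0)
        i = tr.samples
        t = tr.times_ms
        trans0 = i[np.argmin(np.abs(t - 20.0 - DT))] - (-100.0)
        trans_tau = i[np.argmin(np.abs(t - 22.0))] - (-100.0)
        assert trans_tau / trans0 == pytest.approx(np.exp(-1), rel=0.05)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            simulate_step_response(-1.0, 20.0)
        with pytest.raises(ValueError):
            simulate_step_response(100.0, 20.0, step_dur_ms=0.0)

    def test_spike_train_placement(self):
        tr, truth = simulate_spike_train([10.0, 10.0, 10.0])
        peaks = truth["peak_times_ms"]
        assert len(peaks) == 4
        np.testing.assert_allclose(np.diff(peaks), 10.0)
        # the trace really peaks there
        for p in peaks:
            i = tr.index_at(p)
            assert tr.samples[i] == pytest.approx(APShape().peak_mv, abs=0.5)


class TestFieldSweep:
    def test_full_suppression_removes_spike(self):
        full = simulate_field_sweep(0.2, 0.5, laser_suppression=1.0, laser_on=True)
        none = simulate_field_sweep(0.2, 0.5, laser_suppression=0.0, laser_on=True)
        off = simulate_field_sweep(0.2, 0.5, laser_suppression=1.0, laser_on=False)
        # laser off: suppression ignored; matches the unsuppressed laser-on case
        np.testing.assert_allclose(off.samples, none.samples)
        # fully suppressed sweep has no positive deflection
        assert full.samples.max() < 0.5 * none.samples.max()

    def test_bad_suppression_rejected(self):
        with pytest.raises(ValueError):
            simulate_field_sweep(0.2, 0.5, laser_suppression=1.5)
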