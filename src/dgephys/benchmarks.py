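"""Parameter-recovery benchmark suite.

Each function simulates a recording condition with known ground truth, runs
the corresponding analysis stage end to end, and reports how well the
programmed parameters are recovered.  The suite doubles as the package's
validation battery: the conditions (sample sizes, noise levels, rates) are
fixed study-like defaults, and every function is deterministic given its
seed (sub-streams are spawned from one ``numpy.random.SeedSequence``).
"""

from __future__ import annotations

import numpy as np

from dgephys.core import StimulusProtocol, Trace
from dgephys.events import Event, EventTable, detect_events
from dgephys.field import field_metrics, laser_change, locate_popspike_window, spike_delay_vs_popspike
from dgephys.psc import normalize_train, psc_kinetics, pulse_charges
from dgephys.responsive import classify_responsive, split_evoked, success_record
from dgephys.reversal import (
    ACSF,
    HIGH_CHLORIDE_INTERNAL,
    K_GLUCONATE_INTERNAL,
    iv_from_sweepsets,
    nernst_cl,
    separate_components,
)
from dgephys.simulate import (
    IVComponent,
    PSCShape,
    SynapseModel,
    simulate_field_sweep,
    simulate_iv_family,
    simulate_spike_train,
    simulate_sweepset,
)

RATE_HZ = 20000.0
NOISE_SD_PA = 2.0


def nernst_predictions() -> dict:
    """Chloride reversal potentials from the printed solution compositions.

    The high-chloride internal (43 mM Cl) against ACSF (134.1 mM Cl) at 23 C
    predicts the somatic E_GABA; the K-gluconate internal (9 mM Cl) predicts
    the holding potential at which IPSCs reverse and EPSCs are isolated.
    """
    e_high = nernst_cl(HIGH_CHLORIDE_INTERNAL, ACSF)
    e_kgluc = nernst_cl(K_GLUCONATE_INTERNAL, ACSF)
    return {
        "e_gaba_somatic_mv": e_high,
        "e_gaba_somatic_rounded_mv": round(e_high / 10.0) * 10.0,
        "epsc_isolation_holding_mv": e_kgluc,
        "epsc_isolation_holding_rounded_mv": round(e_kgluc / 10.0) * 10.0,
    }


def null_shuffle_calibration(
    seed: int, n_cells: int = 1000, n_shuffles: int = 2000
) -> dict:
    """Empirical type-I rate of the permutation test on uncoupled cells.

    Each null cell has Poisson spontaneous events over 20 sweeps of 2 s with
    16 stimulus onsets per sweep and no stimulus coupling; the fraction
    classified responsive at alpha = 0.05 should sit near alpha.

    The regime is deliberately event-dense (10 Hz spontaneous rate, many
    windows, expected null in-window count ~38): with large counts the
    discrete permutation null is nearly continuous and the test's exactness
    is checked sharply.  Sparser regimes are strictly more conservative
    (count ties inflate p-values), never anticonservative — see the sparse
    companion check in the unit suite.
    """
    protocol = StimulusProtocol(
        onsets_ms=100.0 + np.arange(16) * 115.0, width_ms=0.2
    )
    duration_ms, n_sweeps, rate_hz = 2000.0, 20, 10.0
    streams = np.random.SeedSequence(seed).spawn(n_cells)
    hits = 0
    for s in streams:
        rng = np.random.default_rng(s)
        events = []
        for sweep in range(n_sweeps):
            n = rng.poisson(rate_hz * duration_ms / 1000.0)
            events.extend(
                Event(onset_ms=float(t), peak_ms=float(t) + 2.0, amplitude_pa=20.0,
                      polarity=-1, sweep_index=sweep)
                for t in rng.uniform(0.0, duration_ms, n)
            )
        res = classify_responsive(
            EventTable(events=events), protocol, duration_ms, n_sweeps,
            n_shuffles=n_shuffles, seed=int(rng.integers(2**31)),
        )
        hits += res.responsive
    return {"responsive_fraction": hits / n_cells, "n_cells": n_cells}


def _isolated_event_protocol() -> StimulusProtocol:
    # 5 events per sweep, 100 ms apart: isolated by construction
    return StimulusProtocol(onsets_ms=50.0 + np.arange(5) * 100.0, width_ms=0.2)


def detector_recovery(seed: int, n_runs: int = 100, snr: float = 10.0) -> dict:
    """Detector sensitivity, false-positive rate and amplitude bias.

    Sensitivity and bias are measured on isolated evoked PSCs of amplitude
    ``snr x`` noise SD; false positives on pure-noise sweeps of the same
    noise level (events/second at the default 4-SD threshold).
    """
    protocol = _isolated_event_protocol()
    streams = np.random.SeedSequence(seed).spawn(n_runs)
    found = total = 0
    ratios: list[float] = []
    fp_events = 0
    fp_seconds = 0.0
    for s in streams:
        rng = np.random.default_rng(s)
        model = SynapseModel(
            shape=PSCShape(snr * NOISE_SD_PA, 1.0, 10.0, -1),
            failure_prob=0.0, spont_rate_hz=0.0, noise_sd_pa=NOISE_SD_PA,
        )
        ss, gt = simulate_sweepset(
            model, protocol, n_sweeps=2, seed=int(rng.integers(2**31))
        )
        for i, tr in enumerate(ss.sweeps):
            table = detect_events(tr, polarity=-1, sweep_index=i)
            for te in gt.events_in_sweep(i):
                total += 1
                match = [e for e in table.events if abs(e.onset_ms - te.onset_ms) < 3.0]
                if match:
                    found += 1
                    ratios.append(match[0].amplitude_pa / te.amplitude_pa)
        noise = Trace(
            samples=rng.normal(0.0, NOISE_SD_PA, int(RATE_HZ)), sampling_rate=RATE_HZ
        )
        fp_events += len(detect_events(noise, polarity=-1))
        fp_seconds += 1.0
    return {
        "sensitivity": found / total,
        "false_positive_rate_per_s": fp_events / fp_seconds,
        "amplitude_bias_fraction": float(np.median(ratios) - 1.0),
        "n_runs": n_runs,
    }


def kinetics_closed_form_errors(rate_hz: float = RATE_HZ) -> dict:
    """Rise/decay on noiseless closed-form kernels vs. analytic values.

    20-80% rise of a saturating exponential (tau = 5 ms) is 5 ln 4; 80->30%
    decay of a pure exponential (tau = 10 ms) is 10 ln(8/3).  Errors are
    reported in sample periods.
    """
    dt = 1000.0 / rate_hz
    t = np.arange(0.0, 150.0, dt)
    rise_trace = Trace(samples=-(1 - np.exp(-t / 5.0)), sampling_rate=rate_hz)
    k_rise = psc_kinetics(rise_trace, "EPSC", success=1.0)
    decay = -np.exp(-t / 10.0)
    decay[0] = 0.0
    k_decay = psc_kinetics(Trace(samples=decay, sampling_rate=rate_hz), "EPSC", 1.0)
    return {
        "rise_ms": k_rise.rise_ms,
        "rise_analytic_ms": 5.0 * np.log(4.0),
        "rise_error_samples": abs(k_rise.rise_ms - 5.0 * np.log(4.0)) / dt,
        "decay_ms": k_decay.decay_ms,
        "decay_analytic_ms": 10.0 * np.log(8.0 / 3.0),
        "decay_error_samples": abs(k_decay.decay_ms - 10.0 * np.log(8.0 / 3.0)) / dt,
    }


def success_probability_recovery(
    seed: int, n_runs: int = 100, failure_prob: float = 0.5, n_trials: int = 400
) -> dict:
    """Recover the programmed failure rate through detection + labeling.

    400 stimulus trials per run (80 sweeps x 5 well-separated pulses) at
    failure probability 0.5; the detected success fraction should land within
    binomial error ([0.45, 0.55]) for ~96% of runs (exact binomial coverage
    of +-2 sigma).  Also verifies the failure-weighted amplitude identity on
    every run.
    """
    protocol = _isolated_event_protocol()
    n_sweeps = n_trials // protocol.n_pulses
    streams = np.random.SeedSequence(seed).spawn(n_runs)
    fractions = []
    identity_ok = True
    for s in streams:
        rng = np.random.default_rng(s)
        model = SynapseModel(
            shape=PSCShape(20.0, 1.0, 10.0, -1), failure_prob=failure_prob,
            spont_rate_hz=0.2, noise_sd_pa=NOISE_SD_PA,
        )
        ss, _ = simulate_sweepset(
            model, protocol, n_sweeps=n_sweeps, seed=int(rng.integers(2**31))
        )
        table = EventTable()
        for i, tr in enumerate(ss.sweeps):
            table.extend(detect_events(tr, polarity=-1, sweep_index=i).events)
        labeled = split_evoked(table, protocol)
        rec = success_record(labeled, protocol, n_sweeps)
        fractions.append(rec.success_probability)
        # failure-weighted amplitude identity on the mean success response
        first_pulse_successes = [
            e.sweep_index for e in labeled.events
            if e.label == "evoked" and e.onset_ms < protocol.onsets_ms[1]
        ]
        if first_pulse_successes:
            mean = ss.mean_trace(first_pulse_successes)
            stim = float(protocol.onsets_ms[0])
            sel = (mean.times_ms >= stim) & (mean.times_ms < stim + 80.0)
            pre = mean.samples[mean.times_ms < stim]
            seg = Trace(
                samples=mean.samples[sel] - float(np.median(pre)),
                sampling_rate=mean.sampling_rate, t0=0.0,
            )
            kin = psc_kinetics(seg, "IPSC", rec)
            identity_ok &= np.isclose(
                kin.amplitude_pa,
                kin.mean_success_amplitude_pa * kin.success_probability,
            )
    fractions = np.asarray(fractions)
    lo, hi = 1 - failure_prob - 0.05, 1 - failure_prob + 0.05
    return {
        "mean_success_probability": float(fractions.mean()),
        "in_band_fraction": float(np.mean((fractions >= lo) & (fractions <= hi))),
        "amplitude_identity_exact": bool(identity_ok),
        "n_runs": n_runs,
    }


def train_plasticity_recovery(seed: int, n_runs: int = 20) -> dict:
    """Recover a programmed P5/P1 charge ratio of 0.5 at SNR 10."""
    protocol = StimulusProtocol(
        onsets_ms=50.0 + np.arange(5) * 50.0, width_ms=0.2, train_rate_hz=20.0
    )
    scale = (1.0, 0.8, 0.7, 0.6, 0.5)
    streams = np.random.SeedSequence(seed).spawn(n_runs)
    p5p1 = []
    ref_ok = True
    for s in streams:
        rng = np.random.default_rng(s)
        model = SynapseModel(
            shape=PSCShape(20.0, 1.0, 10.0, -1), failure_prob=0.0,
            train_scale=scale, noise_sd_pa=NOISE_SD_PA,
        )
        ss, _ = simulate_sweepset(
            model, protocol, n_sweeps=15, seed=int(rng.integers(2**31))
        )
        charges = pulse_charges(ss.mean_trace(), protocol)
        first = normalize_train(charges, "IN_to_GC")
        last = normalize_train(charges, "GC_to_IN")
        ref_ok &= first.ratios[0] == 1.0 and last.ratios[-1] == 1.0
        p5p1.append(first.ratios[-1])
    return {
        "p5_p1_ratio": float(np.mean(p5p1)),
        "programmed_ratio": 0.5,
        "reference_ratios_exactly_one": bool(ref_ok),
        "n_runs": n_runs,
    }


def reversal_recovery(seed: int, n_single: int = 100, n_two: int = 30) -> dict:
    """E_rev recovery: single conductance and proximal/distal separation."""
    shape = PSCShape(amplitude_pa=1.0, tau_rise_ms=1.0, tau_decay_ms=10.0)
    streams = np.random.SeedSequence(seed).spawn(n_single + n_two)
    single_err = []
    for s in streams[:n_single]:
        rng = np.random.default_rng(s)
        fam = simulate_iv_family(
            1.0, -65.0, [-95.0, -80.0, -65.0, -50.0, -35.0], shape,
            noise_sd_pa=5.0, seed=int(rng.integers(2**31)), n_sweeps=10,
        )
        single_err.append(iv_from_sweepsets(fam).e_rev_mv + 65.0)
    prox_err, dist_err = [], []
    components = [
        IVComponent(1.0, -30.0, PSCShape(1, 0.5, 4.0), latency_ms=1.5),
        IVComponent(0.8, -65.0, PSCShape(1, 5.0, 40.0), latency_ms=25.0),
    ]
    for s in streams[n_single:]:
        rng = np.random.default_rng(s)
        fam = simulate_iv_family(
            None, None, [-90.0, -75.0, -60.0, -45.0, -30.0, -15.0], shape,
            noise_sd_pa=2.0, seed=int(rng.integers(2**31)),
            components=components, n_sweeps=10,
        )
        pair = separate_components(fam)
        prox_err.append(pair.proximal_iv.e_rev_mv + 30.0)
        dist_err.append(pair.distal_iv.e_rev_mv + 65.0)
    return {
        "single_e_rev_max_abs_error_mv": float(np.max(np.abs(single_err))),
        "proximal_e_rev_max_abs_error_mv": float(np.max(np.abs(prox_err))),
        "distal_e_rev_max_abs_error_mv": float(np.max(np.abs(dist_err))),
    }


def field_pairing_recovery(
    seed: int, suppression: float = 0.75, n_trials: int = 40, noise_sd_mv: float = 0.05
) -> dict:
    """Recover programmed pop-spike suppression and spike-timing labels.

    40 trials per condition emulate a session of eight alternating 5-on /
    5-off blocks.  The pop-spike window is located once on the laser-off
    condition average and applied to every sweep, mirroring how a stable
    recording is analyzed.
    Spike-delay labels are checked on noiseless simultaneous sweeps with two
    spikes straddling the pop-spike plus a transmission-blocked condition.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    stim = 10.0
    off = [
        simulate_field_sweep(0.2, 0.5, suppression, False,
                             seed=int(rng.integers(2**31)), noise_sd_mv=noise_sd_mv)
        for _ in range(n_trials)
    ]
    on = [
        simulate_field_sweep(0.2, 0.5, suppression, True,
                             seed=int(rng.integers(2**31)), noise_sd_mv=noise_sd_mv)
        for _ in range(n_trials)
    ]
    mean_off = off[0].with_samples(np.mean([s.samples for s in off], axis=0))
    window = locate_popspike_window(mean_off, stim)
    a_off = [field_metrics(s, stim, popspike_window_ms=window).popspike_area_mv_ms
             for s in off]
    a_on = [field_metrics(s, stim, popspike_window_ms=window).popspike_area_mv_ms
            for s in on]
    change = laser_change(np.array(a_off), np.array(a_on))

    # spike timing vs. pop-spike on noiseless simultaneous sweeps
    control = simulate_field_sweep(0.2, 0.5, stim_onset_ms=stim)
    peak = field_metrics(control, stim).popspike_peak_ms
    cell, _ = simulate_spike_train([5.0], first_peak_ms=14.0,
                                   duration_ms=control.duration_ms)
    labels = [lab for _, lab in spike_delay_vs_popspike(cell, control, stim)]
    blocked = simulate_field_sweep(0.2, 0.0, stim_onset_ms=stim)
    cell1, _ = simulate_spike_train([], first_peak_ms=14.0,
                                    duration_ms=control.duration_ms)
    blocked_labels = [
        lab for _, lab in spike_delay_vs_popspike(
            cell1, blocked, stim, popspike_peak_ms=peak
        )
    ]
    labels_correct = labels == ["before", "after"] and blocked_labels == ["before"]
    return {
        "laser_induced_change_pct": float(change),
        "programmed_suppression_pct": 100.0 * suppression,
        "spike_delay_labels_correct": bool(labels_correct),
    }
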