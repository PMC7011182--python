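"""Passive-membrane and spike-train characterization.

Input resistance and membrane capacitance come from the current response to a
hyperpolarizing voltage step (10 mV, 100 ms): R from Ohm's law on the steady
state, C from the integrated transient charge (Q = C * dV), with a tau-fit
alternative.  Action-potential threshold is the point where dVm/dt reaches
5 mV/ms; AP amplitude is threshold to positive peak, after-hyperpolarization
threshold to the negative peak during repolarization; interspike intervals
are peak to peak and the adaptation ratio is the third ISI over the last.
Rheobase is the smallest step current that evokes a spike, and the full
spiking profile is read out at the step closest to three times rheobase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from dgephys.core import Trace, lowpass

__all__ = [
    "PassiveProps",
    "SpikeTrainMetrics",
    "passive_props",
    "detect_spikes",
    "spike_features",
    "rheobase_and_profile",
]


@dataclass(frozen=True)
class PassiveProps:
    """Passive membrane properties from a voltage-clamp step."""

    input_resistance_mohm: float
    capacitance_pf: float
    tau_ms: float
    capacitance_tau_fit_pf: float | None = None


@dataclass(frozen=True)
class SpikeTrainMetrics:
    """Spike-train features measured at a given current step."""

    threshold_mv: float | None
    ap_amplitude_mv: float | None
    ahp_amplitude_mv: float | None
    isis_ms: tuple[float, ...]
    instantaneous_freq_hz: tuple[float, ...]
    adaptation_ratio: float | None
    n_spikes: int
    rheobase_pa: float | None = None
    profile_step_pa: float | None = None


def passive_props(
    step_response: Trace,
    step_mv: float = -10.0,
    step_start_ms: float = 20.0,
    step_dur_ms: float = 100.0,
) -> PassiveProps:
    """Estimate R, C and tau from the current response to a voltage step.

    R = step / dI_steady-state (steady state from the last 20% of the step,
    baseline from the pre-step segment).  C (default estimator) integrates the
    transient charge above the steady-state plateau: Q = C * step, in
    pA*ms/mV = pF.  A single-exponential tau fit gives tau and the alternative
    C = tau / R.
    """
    if step_dur_ms <= 0:
        raise ValueError("step duration must be positive")
    x = step_response.samples
    t = step_response.times_ms
    dt = step_response.dt_ms
    pre = x[t < step_start_ms]
    if pre.size < 2:
        raise ValueError("no pre-step baseline available")
    baseline = float(np.median(pre))
    on = (t >= step_start_ms) & (t < step_start_ms + step_dur_ms)
    seg = x[on] - baseline
    tail = seg[int(0.8 * seg.size) :]
    di_ss = float(tail.mean())
    if abs(di_ss) < 1e-9:
        raise ValueError("no detectable steady-state plateau")
    r_mohm = step_mv / di_ss * 1000.0  # mV/pA = GOhm -> MOhm
    # charge-based capacitance: integral of the transient above steady state
    q_trans = float(np.sum(seg - di_ss) * dt)  # pA*ms = fC
    c_pf = q_trans / step_mv  # fC/mV = pF
    # tau fit on the transient (log-linear would amplify noise; use curve_fit)
    ts = t[on] - step_start_ms

    def model(tt, a, tau):
        return di_ss + a * np.exp(-tt / np.maximum(tau, 1e-6))

    a0 = seg[0] - di_ss if seg.size else di_ss
    try:
        popt, _ = optimize.curve_fit(
            model, ts, seg, p0=(a0, 2.0), maxfev=2000
        )
        tau_ms = float(abs(popt[1]))
    except RuntimeError:
        tau_ms = float("nan")
    c_tau = tau_ms / r_mohm * 1000.0 if np.isfinite(tau_ms) and r_mohm != 0 else None
    return PassiveProps(
        input_resistance_mohm=float(r_mohm),
        capacitance_pf=float(c_pf),
        tau_ms=tau_ms,
        capacitance_tau_fit_pf=c_tau,
    )


def detect_spikes(
    v: Trace,
    dvdt_thresh_mv_per_ms: float = 5.0,
    min_peak_mv: float = -10.0,
    min_separation_ms: float = 1.0,
    min_prominence_mv: float = 20.0,
    smooth_cutoff_hz: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect action potentials and their threshold crossings.

    Peaks are positive-going maxima of the lightly smoothed (1 kHz zero-phase
    low-pass) voltage above ``min_peak_mv``, separated by at least
    ``min_separation_ms`` and prominent by at least ``min_prominence_mv`` (an
    action potential spans tens of mV; sub-mV noise wrinkles do not).  For
    each peak, the threshold point is found by walking back on the smoothed
    centered-difference dV/dt to the first sample of the contiguous run where
    dV/dt >= ``dvdt_thresh_mv_per_ms``.

    Returns ``(peak_times_ms, threshold_times_ms)``.  A subthreshold trace
    (e.g. a slow ramp) yields empty arrays.
    """
    from scipy.signal import find_peaks

    dt = v.dt_ms
    smooth = (
        lowpass(v, smooth_cutoff_hz).samples
        if smooth_cutoff_hz < v.sampling_rate / 2
        else v.samples
    )
    dvdt = np.gradient(smooth, dt)
    distance = max(1, int(round(min_separation_ms / dt)))
    peaks, _ = find_peaks(
        smooth, height=min_peak_mv, distance=distance, prominence=min_prominence_mv
    )
    # require a fast upstroke before the peak; reject slow depolarizations
    peak_idx = []
    thresh_idx = []
    for p in peaks:
        lo = max(0, p - int(round(5.0 / dt)))
        fast = dvdt[lo : p + 1] >= dvdt_thresh_mv_per_ms
        if not np.any(fast):
            continue
        # first sample of the last contiguous fast run before the peak
        run_end = np.nonzero(fast)[0][-1]
        i = run_end
        while i > 0 and fast[i - 1]:
            i -= 1
        peak_idx.append(p)
        thresh_idx.append(lo + i)
    peak_times = v.t0 + np.asarray(peak_idx, dtype=float) * dt
    thresh_times = v.t0 + np.asarray(thresh_idx, dtype=float) * dt
    return peak_times, thresh_times


def spike_features(
    v: Trace,
    peak_times_ms: np.ndarray,
    threshold_times_ms: np.ndarray,
    step_end_ms: float | None = None,
) -> SpikeTrainMetrics:
    """Per-spike and train-level features.

    AP amplitude and AHP are taken from the first spike (threshold to positive
    peak; threshold to the most negative point before the next spike's
    threshold or the step end).  ISIs are peak-to-peak; instantaneous
    frequency is 1000/ISI; the adaptation ratio is ISI_3 / ISI_last and needs
    at least 4 spikes.
    """
    peaks = np.asarray(peak_times_ms, float)
    threshs = np.asarray(threshold_times_ms, float)
    if step_end_ms is not None:
        keep = peaks <= step_end_ms
        peaks, threshs = peaks[keep], threshs[keep]
    n = peaks.size
    if n == 0:
        return SpikeTrainMetrics(
            threshold_mv=None,
            ap_amplitude_mv=None,
            ahp_amplitude_mv=None,
            isis_ms=(),
            instantaneous_freq_hz=(),
            adaptation_ratio=None,
            n_spikes=0,
        )
    x = v.samples
    thresh_v = float(x[v.index_at(threshs[0])])
    peak_v = float(x[v.index_at(peaks[0])])
    ap_amp = peak_v - thresh_v
    # AHP: most negative point between this peak and the next threshold
    i0 = v.index_at(peaks[0])
    i1 = (
        v.index_at(threshs[1])
        if n > 1
        else (v.index_at(step_end_ms) if step_end_ms is not None else x.size - 1)
    )
    ahp_amp = thresh_v - float(np.min(x[i0 : max(i1, i0 + 1)]))
    isis = tuple(np.diff(peaks))
    freqs = tuple(1000.0 / i for i in isis)
    adaptation = isis[2] / isis[-1] if len(isis) >= 3 and n >= 4 else None
    return SpikeTrainMetrics(
        threshold_mv=thresh_v,
        ap_amplitude_mv=ap_amp,
        ahp_amplitude_mv=ahp_amp,
        isis_ms=isis,
        instantaneous_freq_hz=freqs,
        adaptation_ratio=adaptation,
        n_spikes=n,
    )


def rheobase_and_profile(
    step_family: list[tuple[float, Trace]],
    step_end_ms: float | None = None,
    dvdt_thresh_mv_per_ms: float = 5.0,
) -> SpikeTrainMetrics:
    """Rheobase and the spiking profile at ~3x rheobase.

    ``step_family`` pairs injected current (pA) with the recorded voltage
    trace, in increasing current order.  Rheobase is the smallest current that
    evokes at least one spike; the full feature set is computed on the
    available step closest to three times rheobase.  With no spiking at any
    step, rheobase is None and the returned metrics are empty.
    """
    currents = [c for c, _ in step_family]
    if any(b <= a for a, b in zip(currents, currents[1:])):
        raise ValueError("step currents must be strictly increasing")
    spike_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def spikes(i: int):
        if i not in spike_cache:
            spike_cache[i] = detect_spikes(
                step_family[i][1], dvdt_thresh_mv_per_ms=dvdt_thresh_mv_per_ms
            )
        return spike_cache[i]

    rheo_idx = None
    for i in range(len(step_family)):
        if spikes(i)[0].size > 0:
            rheo_idx = i
            break
    if rheo_idx is None:
        return SpikeTrainMetrics(
            threshold_mv=None,
            ap_amplitude_mv=None,
            ahp_amplitude_mv=None,
            isis_ms=(),
            instantaneous_freq_hz=(),
            adaptation_ratio=None,
            n_spikes=0,
            rheobase_pa=None,
            profile_step_pa=None,
        )
    rheobase = currents[rheo_idx]
    target = 3.0 * rheobase
    profile_idx = int(np.argmin([abs(c - target) for c in currents]))
    peak_t, thresh_t = spikes(profile_idx)
    metrics = spike_features(
        step_family[profile_idx][1], peak_t, thresh_t, step_end_ms=step_end_ms
    )
    return SpikeTrainMetrics(
        threshold_mv=metrics.threshold_mv,
        ap_amplitude_mv=metrics.ap_amplitude_mv,
        ahp_amplitude_mv=metrics.ahp_amplitude_mv,
        isis_ms=metrics.isis_ms,
        instantaneous_freq_hz=metrics.instantaneous_freq_hz,
        adaptation_ratio=metrics.adaptation_ratio,
        n_spikes=metrics.n_spikes,
        rheobase_pa=rheobase,
        profile_step_pa=currents[profile_idx],
    )
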