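"""Ground-truth-annotated simulators of the recording configurations analyzed
by this package.

Every generator returns both the synthetic recording and the ground truth used
to build it, so downstream detection and metric stages can be validated by
parameter recovery.  Synaptic currents are difference-of-exponentials kernels
with Bernoulli transmission failures, Gaussian latency jitter, per-pulse train
scaling (short-term plasticity), Poisson spontaneous events and additive white
Gaussian noise.  All randomness flows from a single seed per call; per-sweep
sub-streams are derived deterministically so output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from dgephys.core import StimulusProtocol, SweepSet, Trace

__all__ = [
    "PSCShape",
    "SynapseModel",
    "GroundTruth",
    "TrueEvent",
    "IVComponent",
    "psc_waveform",
    "biexp_kernel",
    "biexp_peak_factor",
    "simulate_sweepset",
    "simulate_iv_family",
    "simulate_step_response",
    "simulate_spike_train",
    "simulate_field_sweep",
    "popspike_window_ms",
]


@dataclass(frozen=True)
class PSCShape:
    """Biexponential postsynaptic-current waveform parameters.

    ``amplitude_pa`` is the peak magnitude (always positive); ``polarity`` is
    -1 for inward currents (EPSCs, or IPSCs below their reversal) and +1 for
    outward currents.
    """

    amplitude_pa: float
    tau_rise_ms: float
    tau_decay_ms: float
    polarity: int = -1

    def __post_init__(self) -> None:
        if self.amplitude_pa <= 0:
            raise ValueError("amplitude_pa must be positive (a magnitude)")
        if not 0 < self.tau_rise_ms < self.tau_decay_ms:
            raise ValueError("need 0 < tau_rise < tau_decay")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be -1 (inward) or +1 (outward)")


@dataclass(frozen=True)
class SynapseModel:
    """A stochastic synapse as seen from the recorded cell.

    ``train_scale`` multiplies the evoked amplitude per pulse position within a
    train (e.g. ``[1, .8, .7, .6, .5]`` programs depression with P5/P1 = 0.5);
    ``failure_prob`` is the per-pulse probability of transmission failure;
    spontaneous events arrive as a homogeneous Poisson process at
    ``spont_rate_hz``.
    """

    shape: PSCShape
    failure_prob: float = 0.0
    latency_mean_ms: float = 2.0
    latency_jitter_sd_ms: float = 0.3
    train_scale: tuple[float, ...] = (1.0,)
    spont_rate_hz: float = 0.0
    noise_sd_pa: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.failure_prob <= 1.0:
            raise ValueError("failure_prob must lie in [0, 1]")
        scale = tuple(float(x) for x in self.train_scale)
        object.__setattr__(self, "train_scale", scale)
        if any(x <= 0 for x in scale):
            raise ValueError("train_scale factors must be positive")
        if self.spont_rate_hz < 0:
            raise ValueError("spont_rate_hz must be non-negative")
        if self.noise_sd_pa < 0:
            raise ValueError("noise_sd_pa must be non-negative")


@dataclass(frozen=True)
class TrueEvent:
    """One programmed synaptic event (ground truth)."""

    sweep_index: int
    onset_ms: float
    amplitude_pa: float
    label: str  # "evoked" or "spontaneous"
    pulse_index: int | None = None


@dataclass
class GroundTruth:
    """Programmed events and per-pulse success flags for a simulated set."""

    events: list[TrueEvent] = field(default_factory=list)
    # success[sweep, pulse] = True when transmission succeeded
    success: np.ndarray | None = None

    def events_in_sweep(self, i: int) -> list[TrueEvent]:
        return [e for e in self.events if e.sweep_index == i]

    @property
    def n_events(self) -> int:
        return len(self.events)

    def success_fraction(self) -> float:
        if self.success is None or self.success.size == 0:
            return float("nan")
        return float(np.mean(self.success))


# ---------------------------------------------------------------------------
# Waveform primitives


def biexp_peak_factor(tau_rise_ms: float, tau_decay_ms: float) -> float:
    """Peak value of the unnormalized kernel exp(-t/taud) - exp(-t/taur).

    The kernel peaks at t* = taur*taud/(taud-taur) * ln(taud/taur); this factor
    rescales it so the normalized waveform peaks at exactly 1.
    """
    tr, td = tau_rise_ms, tau_decay_ms
    t_peak = tr * td / (td - tr) * np.log(td / tr)
    return float(np.exp(-t_peak / td) - np.exp(-t_peak / tr))


def biexp_kernel(
    shape: PSCShape, duration_ms: float, rate_hz: float
) -> np.ndarray:
    """Sampled PSC kernel with peak = polarity * amplitude, starting at 0."""
    dt = 1000.0 / rate_hz
    t = np.arange(0.0, duration_ms, dt)
    raw = np.exp(-t / shape.tau_decay_ms) - np.exp(-t / shape.tau_rise_ms)
    k = raw / biexp_peak_factor(shape.tau_rise_ms, shape.tau_decay_ms)
    return shape.polarity * shape.amplitude_pa * k


def psc_waveform(
    shape: PSCShape, duration_ms: float, rate_hz: float = 20000.0
) -> Trace:
    """One noiseless PSC as a :class:`Trace` (current, pA).

    The waveform is zero at t=0 and its extremum equals
    ``polarity * amplitude_pa`` to within the sampling resolution.
    """
    return Trace(
        samples=biexp_kernel(shape, duration_ms, rate_hz),
        sampling_rate=rate_hz,
        kind="voltage_clamped_current",
    )


def _add_kernel(samples: np.ndarray, kernel: np.ndarray, start: int) -> None:
    """Add a kernel in place, truncating at the sweep end."""
    if start >= samples.size or start < 0:
        return
    n = min(kernel.size, samples.size - start)
    samples[start : start + n] += kernel[:n]


# ---------------------------------------------------------------------------
# Voltage-clamp sweep simulation


def simulate_sweepset(
    model: SynapseModel,
    protocol: StimulusProtocol,
    n_sweeps: int,
    seed: int,
    duration_ms: float | None = None,
    rate_hz: float = 20000.0,
) -> tuple[SweepSet, GroundTruth]:
    """Simulate repeated voltage-clamp sweeps with ground truth.

    Per pulse, transmission succeeds with probability ``1 - failure_prob``; a
    success places one PSC kernel at the pulse onset plus a truncated-Gaussian
    latency, with amplitude scaled by the pulse's ``train_scale`` factor.
    Spontaneous PSCs arrive as a Poisson process over the whole sweep.  White
    Gaussian noise of ``noise_sd_pa`` is added throughout.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    if duration_ms is None:
        duration_ms = float(protocol.onsets_ms[-1]) + max(
            200.0, 8.0 * model.shape.tau_decay_ms
        )
    dt = 1000.0 / rate_hz
    n_samples = int(round(duration_ms / dt))
    kernel_len_ms = min(10.0 * model.shape.tau_decay_ms, duration_ms)
    kernel = biexp_kernel(model.shape, kernel_len_ms, rate_hz) / 1.0
    unit_kernel = kernel / model.shape.amplitude_pa  # polarity-signed, peak +-1

    n_pulses = protocol.n_pulses
    truth = GroundTruth(success=np.zeros((n_sweeps, n_pulses), dtype=bool))
    streams = np.random.SeedSequence(seed).spawn(n_sweeps)
    sweeps = []
    for i in range(n_sweeps):
        rng = np.random.default_rng(streams[i])
        x = rng.normal(0.0, model.noise_sd_pa, n_samples) if model.noise_sd_pa > 0 else np.zeros(n_samples)
        # evoked events
        for j, onset in enumerate(protocol.onsets_ms):
            if rng.random() < model.failure_prob:
                continue
            truth.success[i, j] = True
            scale = model.train_scale[min(j, len(model.train_scale) - 1)]
            latency = rng.normal(model.latency_mean_ms, model.latency_jitter_sd_ms)
            latency = max(latency, dt)
            amp = model.shape.amplitude_pa * scale
            t_event = float(onset) + latency
            _add_kernel(x, unit_kernel * amp, int(round(t_event / dt)))
            truth.events.append(
                TrueEvent(i, t_event, amp, "evoked", pulse_index=j)
            )
        # spontaneous events
        if model.spont_rate_hz > 0:
            n_spont = rng.poisson(model.spont_rate_hz * duration_ms / 1000.0)
            for t_event in np.sort(rng.uniform(0.0, duration_ms, n_spont)):
                _add_kernel(
                    x,
                    unit_kernel * model.shape.amplitude_pa,
                    int(round(t_event / dt)),
                )
                truth.events.append(
                    TrueEvent(i, float(t_event), model.shape.amplitude_pa, "spontaneous")
                )
        sweeps.append(
            Trace(samples=x, sampling_rate=rate_hz, kind="voltage_clamped_current")
        )
    sweepset = SweepSet(sweeps=tuple(sweeps), protocol=protocol)
    return sweepset, truth


# ---------------------------------------------------------------------------
# I-V families around a reversal potential


@dataclass(frozen=True)
class IVComponent:
    """One synaptic conductance for I-V simulation.

    Peak current at holding V is ``g_syn_ns * (V - e_rev_mv)`` (nS x mV = pA).
    ``shape.amplitude_pa`` is ignored; the driving force sets the amplitude.
    """

    g_syn_ns: float
    e_rev_mv: float
    shape: PSCShape
    latency_ms: float = 2.0


def simulate_iv_family(
    g_syn_ns: float | None,
    e_rev_mv: float | None,
    holdings_mv: Sequence[float],
    shape: PSCShape,
    noise_sd_pa: float,
    seed: int,
    n_sweeps: int = 5,
    components: Sequence[IVComponent] | None = None,
    stim_onset_ms: float = 20.0,
    duration_ms: float = 220.0,
    rate_hz: float = 20000.0,
) -> dict[float, SweepSet]:
    """Simulate evoked currents at several holding potentials.

    Either pass a single conductance (``g_syn_ns``, ``e_rev_mv``, ``shape``) or
    an explicit list of ``components`` — e.g. a fast proximal conductance
    reversing at -30 mV plus a slow distal one reversing at -65 mV, which
    yields biphasic sweeps at intermediate holdings.

    Returns a mapping holding potential -> :class:`SweepSet`.
    """
    holdings = [float(v) for v in holdings_mv]
    if len(holdings) < 3:
        raise ValueError("need at least 3 holding potentials")
    if components is None:
        if g_syn_ns is None or e_rev_mv is None:
            raise ValueError("pass g_syn_ns/e_rev_mv or explicit components")
        components = [IVComponent(g_syn_ns, e_rev_mv, shape)]
    dt = 1000.0 / rate_hz
    n_samples = int(round(duration_ms / dt))
    protocol = StimulusProtocol(
        onsets_ms=np.array([stim_onset_ms]), width_ms=0.2, modality="laser"
    )
    streams = np.random.SeedSequence(seed).spawn(len(holdings))
    out: dict[float, SweepSet] = {}
    for h_idx, v_hold in enumerate(holdings):
        rng = np.random.default_rng(streams[h_idx])
        sweeps = []
        for _ in range(n_sweeps):
            x = (
                rng.normal(0.0, noise_sd_pa, n_samples)
                if noise_sd_pa > 0
                else np.zeros(n_samples)
            )
            for comp in components:
                peak_pa = comp.g_syn_ns * (v_hold - comp.e_rev_mv)
                if peak_pa == 0.0:
                    continue
                unit = PSCShape(
                    amplitude_pa=abs(peak_pa),
                    tau_rise_ms=comp.shape.tau_rise_ms,
                    tau_decay_ms=comp.shape.tau_decay_ms,
                    polarity=int(np.sign(peak_pa)),
                )
                k = biexp_kernel(
                    unit, min(10.0 * unit.tau_decay_ms, duration_ms), rate_hz
                )
                _add_kernel(x, k, int(round((stim_onset_ms + comp.latency_ms) / dt)))
            sweeps.append(
                Trace(samples=x, sampling_rate=rate_hz, kind="voltage_clamped_current")
            )
        out[v_hold] = SweepSet(
            sweeps=tuple(sweeps), protocol=protocol, holding_potential_mv=v_hold
        )
    return out


# ---------------------------------------------------------------------------
# Passive step response and spike trains


def simulate_step_response(
    r_in_mohm: float,
    c_m_pf: float,
    step_mv: float = -10.0,
    step_start_ms: float = 20.0,
    step_dur_ms: float = 100.0,
    duration_ms: float = 200.0,
    noise_sd_pa: float = 0.0,
    seed: int = 0,
    rate_hz: float = 20000.0,
) -> Trace:
    """Voltage-clamp current response to a voltage step across a passive cell.

    The current relaxes single-exponentially with tau = R*C toward the steady
    state dI = step/R; the transient above steady state carries total charge
    C*step, which is what the charge-based capacitance estimator integrates.
    Units: MOhm, pF, mV -> current in pA (mV/MOhm = nA = 1000 pA).
    """
    if r_in_mohm <= 0 or c_m_pf <= 0:
        raise ValueError("r_in and c_m must be positive")
    if step_dur_ms <= 0:
        raise ValueError("step duration must be positive")
    dt = 1000.0 / rate_hz
    t = np.arange(0.0, duration_ms, dt)
    tau_ms = r_in_mohm * c_m_pf / 1000.0  # MOhm*pF = us -> ms
    di_ss_pa = step_mv / r_in_mohm * 1000.0
    # transient amplitude chosen so its integral equals C*step (pF*mV = fC = pA*ms)
    a_trans_pa = c_m_pf * step_mv / tau_ms
    x = np.zeros_like(t)
    on = (t >= step_start_ms) & (t < step_start_ms + step_dur_ms)
    x[on] = di_ss_pa + a_trans_pa * np.exp(-(t[on] - step_start_ms) / tau_ms)
    off = t >= step_start_ms + step_dur_ms
    x[off] = -a_trans_pa * np.exp(-(t[off] - (step_start_ms + step_dur_ms)) / tau_ms)
    if noise_sd_pa > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd_pa, x.size)
    return Trace(samples=x, sampling_rate=rate_hz, kind="voltage_clamped_current")


@dataclass(frozen=True)
class APShape:
    """Stereotyped action-potential waveform parameters (current clamp)."""

    baseline_mv: float = -70.0
    threshold_mv: float = -40.0
    peak_mv: float = 30.0
    ahp_mv: float = -75.0
    upstroke_ms: float = 0.5
    downstroke_ms: float = 0.8
    ahp_decay_ms: float = 8.0


def _ap_template(shape: APShape, rate_hz: float) -> tuple[np.ndarray, int, float]:
    """Build one AP waveform (relative to baseline).

    Returns (template, peak_index, true_threshold_voltage).  The template
    begins with a fast depolarization from a pre-threshold foot through
    threshold to the peak, then repolarizes to the AHP trough and decays back
    to baseline.  The true threshold voltage is where the template's
    centered-difference dV/dt first reaches 5 mV/ms.
    """
    dt = 1000.0 / rate_hz
    # foot: slow rise from baseline to threshold over 2 ms (below 5 mV/ms when
    # the threshold-baseline gap is modest); upstroke: exponential approach.
    foot_ms = 4.0
    t_foot = np.arange(0.0, foot_ms, dt)
    foot = shape.baseline_mv + (shape.threshold_mv - shape.baseline_mv) * (
        t_foot / foot_ms
    ) ** 3
    t_up = np.arange(dt, shape.upstroke_ms * 5, dt)
    up = shape.peak_mv + (shape.threshold_mv - shape.peak_mv) * np.exp(
        -t_up / shape.upstroke_ms
    )
    up = up[up < shape.peak_mv - 0.01]
    t_down = np.arange(dt, shape.downstroke_ms * 5, dt)
    down = shape.ahp_mv + (shape.peak_mv - shape.ahp_mv) * np.exp(
        -t_down / shape.downstroke_ms
    )
    down = down[down > shape.ahp_mv + 0.01]
    t_ahp = np.arange(dt, shape.ahp_decay_ms * 6, dt)
    ahp = shape.baseline_mv + (
        (down[-1] if down.size else shape.ahp_mv) - shape.baseline_mv
    ) * np.exp(-t_ahp / shape.ahp_decay_ms)
    v = np.concatenate([foot, up, [shape.peak_mv], down, ahp])
    peak_idx = int(np.argmax(v))
    dvdt = np.gradient(v, dt)
    crossing = np.nonzero(dvdt[: peak_idx + 1] >= 5.0)[0]
    v_thresh = float(v[crossing[0]]) if crossing.size else shape.threshold_mv
    return v - shape.baseline_mv, peak_idx, v_thresh


def simulate_spike_train(
    isis_ms: Sequence[float],
    ap_shape: APShape | None = None,
    seed: int = 0,
    noise_sd_mv: float = 0.0,
    first_peak_ms: float = 20.0,
    duration_ms: float | None = None,
    rate_hz: float = 20000.0,
) -> tuple[Trace, dict]:
    """Current-clamp voltage trace with stereotyped APs at cumulative ISIs.

    ``isis_ms`` of length n yields n+1 spikes whose *peaks* are spaced by the
    given intervals.  Returns the trace and a ground-truth dict with keys
    ``peak_times_ms`` and ``threshold_mv`` (the voltage at which the template's
    dV/dt first reaches 5 mV/ms).
    """
    shape = ap_shape or APShape()
    template, peak_idx, v_thresh = _ap_template(shape, rate_hz)
    peaks = first_peak_ms + np.concatenate([[0.0], np.cumsum(np.asarray(isis_ms, float))])
    if duration_ms is None:
        duration_ms = float(peaks[-1]) + 60.0
    dt = 1000.0 / rate_hz
    n = int(round(duration_ms / dt))
    x = np.full(n, shape.baseline_mv)
    for p in peaks:
        start = int(round(p / dt)) - peak_idx
        seg = template
        if start < 0:
            seg = seg[-start:]
            start = 0
        m = min(seg.size, n - start)
        if m > 0:
            # replace rather than add so overlapping AHPs do not sum
            x[start : start + m] = shape.baseline_mv + np.maximum(
                x[start : start + m] - shape.baseline_mv, seg[:m]
            )
    if noise_sd_mv > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd_mv, n)
    trace = Trace(samples=x, sampling_rate=rate_hz, kind="current_clamped_voltage")
    truth = {"peak_times_ms": peaks, "threshold_mv": v_thresh}
    return trace, truth


# ---------------------------------------------------------------------------
# Field potentials: fEPSP + pop-spike

POPSPIKE_LATENCY_MS = 6.0
POPSPIKE_SD_MS = 0.4
FEPSP_RISE_MS = 2.0
FEPSP_DECAY_MS = 12.0


def popspike_window_ms(stim_onset_ms: float) -> tuple[float, float]:
    """Window bracketing the simulated pop-spike (for analysis defaults)."""
    center = stim_onset_ms + POPSPIKE_LATENCY_MS
    return center - 4.0 * POPSPIKE_SD_MS, center + 4.0 * POPSPIKE_SD_MS


def simulate_field_sweep(
    fepsp_slope_true_mv_per_ms: float,
    popspike_area_true_mv_ms: float,
    laser_suppression: float = 0.0,
    laser_on: bool = False,
    seed: int = 0,
    noise_sd_mv: float = 0.0,
    stim_onset_ms: float = 10.0,
    duration_ms: float = 60.0,
    rate_hz: float = 20000.0,
) -> Trace:
    """One extracellular sweep: negative-going fEPSP with a positive pop-spike.

    The fEPSP is a smooth negative wave whose initial (20-80%) slope magnitude
    equals ``fepsp_slope_true_mv_per_ms``; the pop-spike is a narrow positive
    Gaussian deflection riding on it whose area above the fEPSP envelope is
    ``popspike_area_true_mv_ms``, scaled by ``1 - laser_suppression`` when
    ``laser_on`` is set (optogenetic recruitment of inhibitory interneurons
    suppresses granule-cell firing, hence the pop-spike, while leaving the
    synaptic fEPSP largely intact).
    """
    if not 0.0 <= laser_suppression <= 1.0:
        raise ValueError("laser_suppression must lie in [0, 1]")
    dt = 1000.0 / rate_hz
    t = np.arange(0.0, duration_ms, dt)
    x = np.zeros_like(t)
    ts = t - stim_onset_ms
    on = ts >= 0
    # fEPSP: difference of exponentials, negative-going
    wave = np.zeros_like(t)
    wave[on] = -(
        np.exp(-ts[on] / FEPSP_DECAY_MS) - np.exp(-ts[on] / FEPSP_RISE_MS)
    )
    peak_factor = np.max(-wave) if np.any(on) else 1.0
    # scale so the steepest 20-80% falling slope equals the requested value
    unit = wave / peak_factor  # trough = -1
    slope_unit = _steepest_slope(unit, dt)
    if slope_unit != 0:
        x += unit * (fepsp_slope_true_mv_per_ms / abs(slope_unit))
    area = popspike_area_true_mv_ms * ((1.0 - laser_suppression) if laser_on else 1.0)
    if area > 0:
        center = stim_onset_ms + POPSPIKE_LATENCY_MS
        g = np.exp(-0.5 * ((t - center) / POPSPIKE_SD_MS) ** 2)
        g_area = g.sum() * dt
        x += g * (area / g_area)
    if noise_sd_mv > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd_mv, x.size)
    return Trace(samples=x, sampling_rate=rate_hz, kind="field")


def _steepest_slope(wave: np.ndarray, dt_ms: float) -> float:
    """Steepest falling slope of the initial 20-80% descent (mV/ms)."""
    trough = int(np.argmin(wave))
    if trough == 0:
        return 0.0
    seg = wave[: trough + 1]
    amp = seg[-1]
    lo, hi = 0.2 * amp, 0.8 * amp  # amp negative
    mask = (seg <= lo) & (seg >= hi)
    idx = np.nonzero(mask)[0]
    if idx.size < 2:
        return float(np.min(np.diff(seg)) / dt_ms)
    coeffs = np.polyfit(idx * dt_ms, seg[idx], 1)
    return float(coeffs[0])
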