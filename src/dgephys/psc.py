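"""Formula-defined postsynaptic-current metrics.

Amplitude is failure-weighted: the product of the mean peak over success
trials and the probability of success.  Rise time runs from 20% to 80% of peak
for EPSCs, or 20% to 70% for IPSCs; decay time runs from 80% (EPSC) or 70%
(IPSC) down to 30%.  Threshold crossings are located by linear interpolation
between samples.  Train responses are quantified as per-pulse charges
integrated over one inter-pulse interval each (relative to the pre-train
baseline) and normalized to the first pulse for interneuron-to-granule-cell
synapses or to the last pulse for granule-cell-to-interneuron synapses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dgephys.core import StimulusProtocol, Trace
from dgephys.responsive import SuccessRecord

__all__ = [
    "PSCKinetics",
    "TrainResponse",
    "psc_kinetics",
    "pulse_charges",
    "normalize_train",
    "cv_amplitude",
    "unitary_synapse_count",
    "whole_train_charge",
    "KINETIC_FRACTIONS",
]

# (rise_low, rise_high, decay_high, decay_low) fractions of peak per PSC class
KINETIC_FRACTIONS = {
    "EPSC": (0.20, 0.80, 0.80, 0.30),
    "IPSC": (0.20, 0.70, 0.70, 0.30),
}


@dataclass(frozen=True)
class PSCKinetics:
    """Failure-weighted amplitude and kinetic measures of an evoked PSC."""

    amplitude_pa: float  # mean success amplitude x success probability
    mean_success_amplitude_pa: float
    success_probability: float
    rise_ms: float
    decay_ms: float
    half_width_ms: float
    onset_latency_ms: float
    cv_amplitude: float | None = None
    defined: bool = True  # False when the peak was below the noise floor


@dataclass(frozen=True)
class TrainResponse:
    """Per-pulse charges of a train response and their normalized ratios."""

    charges_pa_ms: tuple[float, ...]
    reference_index: int
    ratios: tuple[float, ...]
    truncated: bool = False

    @property
    def n_pulses(self) -> int:
        return len(self.charges_pa_ms)


def _interp_crossing_time(
    t: np.ndarray, x: np.ndarray, level: float, rising: bool
) -> float | None:
    """First time x crosses ``level`` (linearly interpolated).

    ``rising``: look for the first upward crossing; otherwise the first
    downward crossing.  ``x`` is expected positive-going (already flipped).
    """
    if rising:
        above = x >= level
    else:
        above = x <= level
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    if i == 0:
        return float(t[0])
    x0, x1 = x[i - 1], x[i]
    if x1 == x0:
        return float(t[i])
    frac = (level - x0) / (x1 - x0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def psc_kinetics(
    mean_success_trace: Trace,
    psc_class: str,
    success: SuccessRecord | float,
    noise_floor_pa: float = 0.0,
) -> PSCKinetics:
    """Kinetics of the mean success-trial PSC.

    ``mean_success_trace`` must be baseline-subtracted (zero before the
    response) and time-referenced so that ``t0`` marks the stimulus: the onset
    latency is then the 10%-of-peak crossing time.  The trace polarity is
    inferred from the signed extremum.

    ``success`` may be a :class:`SuccessRecord` or a bare probability.
    """
    if psc_class not in KINETIC_FRACTIONS:
        raise ValueError(f"psc_class must be one of {sorted(KINETIC_FRACTIONS)}")
    p_succ = (
        success.success_probability
        if isinstance(success, SuccessRecord)
        else float(success)
    )
    x = mean_success_trace.samples
    t = mean_success_trace.times_ms
    polarity = -1 if abs(x.min()) > abs(x.max()) else 1
    flipped = x * polarity
    peak_idx = int(np.argmax(flipped))
    peak = float(flipped[peak_idx])
    if peak <= noise_floor_pa or peak <= 0:
        return PSCKinetics(
            amplitude_pa=float("nan"),
            mean_success_amplitude_pa=float("nan"),
            success_probability=p_succ,
            rise_ms=float("nan"),
            decay_ms=float("nan"),
            half_width_ms=float("nan"),
            onset_latency_ms=float("nan"),
            defined=False,
        )
    f_rise_lo, f_rise_hi, f_dec_hi, f_dec_lo = KINETIC_FRACTIONS[psc_class]
    rise_seg_t, rise_seg_x = t[: peak_idx + 1], flipped[: peak_idx + 1]
    dec_seg_t, dec_seg_x = t[peak_idx:], flipped[peak_idx:]
    t_rise_lo = _interp_crossing_time(rise_seg_t, rise_seg_x, f_rise_lo * peak, True)
    t_rise_hi = _interp_crossing_time(rise_seg_t, rise_seg_x, f_rise_hi * peak, True)
    t_dec_hi = _interp_crossing_time(dec_seg_t, dec_seg_x, f_dec_hi * peak, False)
    t_dec_lo = _interp_crossing_time(dec_seg_t, dec_seg_x, f_dec_lo * peak, False)
    t_on = _interp_crossing_time(rise_seg_t, rise_seg_x, 0.10 * peak, True)
    rise = (
        t_rise_hi - t_rise_lo
        if t_rise_hi is not None and t_rise_lo is not None
        else float("nan")
    )
    decay = (
        t_dec_lo - t_dec_hi
        if t_dec_lo is not None and t_dec_hi is not None
        else float("nan")
    )
    # half-width: first 50% up-crossing to first 50% down-crossing after peak
    t_half_up = _interp_crossing_time(rise_seg_t, rise_seg_x, 0.5 * peak, True)
    t_half_down = _interp_crossing_time(dec_seg_t, dec_seg_x, 0.5 * peak, False)
    half_width = (
        t_half_down - t_half_up
        if t_half_down is not None and t_half_up is not None
        else float("nan")
    )
    return PSCKinetics(
        amplitude_pa=peak * p_succ,
        mean_success_amplitude_pa=peak,
        success_probability=p_succ,
        rise_ms=rise,
        decay_ms=decay,
        half_width_ms=half_width,
        onset_latency_ms=t_on if t_on is not None else float("nan"),
        defined=True,
    )


def pulse_charges(sweep: Trace, protocol: StimulusProtocol) -> TrainResponse:
    """Per-pulse charge of a train response (pA*ms, signed).

    Each pulse's charge is the baseline-subtracted integral over a window
    equal to the inter-pulse interval, starting at that pulse (the last pulse
    uses the same window length).  The baseline is the median of the pre-train
    segment, so currents that accumulate across the train are preserved in
    later pulses' charges.  A window extending past the sweep end is truncated
    and flagged.
    """
    onsets = np.asarray(protocol.onsets_ms, float)
    if onsets.size < 2:
        raise ValueError("pulse_charges requires a train of >= 2 pulses")
    ipi = protocol.inter_pulse_ms
    x = sweep.samples
    dt = sweep.dt_ms
    pre = x[: sweep.index_at(onsets[0])]
    baseline = float(np.median(pre)) if pre.size else 0.0
    charges = []
    truncated = False
    for onset in onsets:
        i0 = sweep.index_at(onset)
        i1 = int(round((onset + ipi - sweep.t0) / dt))
        if i1 > x.size:
            i1 = x.size
            truncated = True
        charges.append(float(np.sum(x[i0:i1] - baseline) * dt))
    return TrainResponse(
        charges_pa_ms=tuple(charges),
        reference_index=0,
        ratios=tuple(np.nan for _ in charges),
        truncated=truncated,
    )


def normalize_train(tr: TrainResponse, direction: str) -> TrainResponse:
    """Normalize per-pulse charges by the convention for the synapse direction.

    ``IN_to_GC`` (inhibitory input onto granule cells): divide by the first
    pulse's charge.  ``GC_to_IN`` (granule-cell output onto interneurons):
    divide by the last pulse's charge.  The reference pulse's ratio is exactly
    1 by construction.
    """
    if direction == "IN_to_GC":
        ref = 0
    elif direction == "GC_to_IN":
        ref = tr.n_pulses - 1
    else:
        raise ValueError("direction must be 'IN_to_GC' or 'GC_to_IN'")
    ref_charge = tr.charges_pa_ms[ref]
    if ref_charge == 0:
        raise ZeroDivisionError("reference pulse charge is zero; ratios undefined")
    ratios = tuple(c / ref_charge for c in tr.charges_pa_ms)
    return TrainResponse(
        charges_pa_ms=tr.charges_pa_ms,
        reference_index=ref,
        ratios=ratios,
        truncated=tr.truncated,
    )


def cv_amplitude(success_amplitudes) -> float:
    """Coefficient of variation (SD/mean) of success-trial amplitudes."""
    amps = np.asarray(success_amplitudes, dtype=float)
    if amps.size < 2:
        raise ValueError("cv_amplitude requires at least 2 success amplitudes")
    mean = amps.mean()
    if mean == 0:
        return float("nan")
    return float(amps.std(ddof=0) / mean)


def unitary_synapse_count(
    saturating_ipsc_pa: float, unitary_ipsc_pa: float
) -> tuple[float, int]:
    """Estimated number of synaptic contacts.

    The ratio between the IPSC amplitude at saturating stimulation and the
    unitary IPSC amplitude (minimal stimulation with >= 10% failures).
    Returns the raw ratio and its rounded companion.
    """
    if unitary_ipsc_pa <= 0:
        raise ValueError("unitary IPSC amplitude must be positive")
    if saturating_ipsc_pa <= 0:
        raise ValueError("saturating IPSC amplitude must be positive")
    ratio = saturating_ipsc_pa / unitary_ipsc_pa
    return ratio, int(round(ratio))


def whole_train_charge(
    sweep: Trace,
    first_onset_ms: float,
    peak_amplitude_pa: float,
    window_ms: float = 340.0,
) -> float:
    """Total charge over a fixed window from the first pulse, peak-normalized.

    Used for high-frequency (50 Hz) trains where individual responses fuse:
    the baseline-subtracted integral over ``window_ms`` (default 340 ms) is
    divided by the peak amplitude, yielding an effective duration in ms.
    """
    if peak_amplitude_pa <= 0:
        raise ValueError("peak_amplitude_pa must be positive")
    dt = sweep.dt_ms
    i0 = sweep.index_at(first_onset_ms)
    i1 = min(sweep.n_samples, int(round((first_onset_ms + window_ms - sweep.t0) / dt)))
    pre = sweep.samples[:i0]
    baseline = float(np.median(pre)) if pre.size else 0.0
    charge = float(np.sum(sweep.samples[i0:i1] - baseline) * dt)
    return charge / peak_amplitude_pa
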