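"""Field-potential analysis: fEPSP slope, population-spike area, laser-pairing
modulation and spike timing relative to the pop-spike.

The extracellular response to perforant-path stimulation is a negative-going
fEPSP (synaptic drive) with a superimposed positive population spike whose
area is proportional to the number of synchronously firing granule cells.
Pop-spike area is measured by the tangent-skim method: a straight envelope is
interpolated between the two local minima flanking the spike and the area of
the deflection above that envelope is integrated.  Laser-induced change of
field responses is 100 * (off - on) / off, computed on per-condition means of
alternating 5-on / 5-off trial blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dgephys.core import Trace, lowpass
from dgephys.intrinsic import detect_spikes

__all__ = [
    "FieldMetrics",
    "PairingResult",
    "field_metrics",
    "locate_popspike_window",
    "laser_change",
    "delay_curve",
    "spike_delay_vs_popspike",
]


@dataclass(frozen=True)
class FieldMetrics:
    """Per-sweep field-response measures."""

    fepsp_slope_mv_per_ms: float
    popspike_area_mv_ms: float
    popspike_peak_ms: float | None
    laser_on: bool = False
    delta_t_ms: float | None = None
    area_flagged: bool = False  # True when no deflection rose above noise


@dataclass(frozen=True)
class PairingResult:
    """Laser-pairing modulation across a grid of laser-electrical delays."""

    delta_t_ms: tuple[float, ...]
    percent_change: tuple[float, ...]
    mean_off: tuple[float, ...]
    mean_on: tuple[float, ...]
    n_off: tuple[int, ...]
    n_on: tuple[int, ...]
    omitted_delta_t: tuple[float, ...] = ()


def field_metrics(
    sweep: Trace,
    stim_onset_ms: float,
    analysis_window_ms: float = 30.0,
    laser_on: bool = False,
    delta_t_ms: float | None = None,
    noise_floor_mv: float = 0.0,
    smooth_cutoff_hz: float = 2000.0,
    popspike_window_ms: tuple[float, float] | None = None,
) -> FieldMetrics:
    """fEPSP slope and pop-spike area of one field sweep.

    The slope is a linear fit over the 20-80% segment of the initial
    negative-going descent (before any pop-spike).  The pop-spike area is the
    integral of the trace above the interpolated fEPSP envelope between the
    window edges; the envelope is a quadratic fit through short flanking
    segments just outside the window.  When ``popspike_window_ms`` is omitted
    it is located on this sweep by :func:`locate_popspike_window` — for noisy
    per-sweep measurements, locate the window once on a condition average and
    pass it in, which keeps the area estimate linear in the data and hence
    unbiased by noise.

    The sweep is zero-phase low-pass filtered (default 2 kHz) before
    measurement; the pop-spike is far slower than that, while unfiltered
    sample noise would bias the extremum searches.
    """
    dt = sweep.dt_ms
    t = sweep.times_ms
    if 0 < smooth_cutoff_hz < sweep.sampling_rate / 2:
        sweep = sweep.with_samples(lowpass(sweep, smooth_cutoff_hz).samples)
    sel = (t >= stim_onset_ms) & (t < stim_onset_ms + analysis_window_ms)
    x = sweep.samples[sel]
    tt = t[sel]
    if x.size < 5:
        raise ValueError("analysis window contains too few samples")
    trough = int(np.argmin(x))
    # --- slope: 20-80% of the initial descent toward the trough
    descent = x[: trough + 1]
    amp = descent[-1] - descent[0]
    slope = 0.0
    if amp < 0:
        lo = descent[0] + 0.2 * amp
        hi = descent[0] + 0.8 * amp
        mask = (descent <= lo) & (descent >= hi)
        idx = np.nonzero(mask)[0]
        if idx.size >= 2:
            slope = float(np.polyfit(tt[idx], descent[idx], 1)[0])
        elif descent.size >= 2:
            slope = float(np.min(np.diff(descent)) / dt)
    # --- pop-spike area above the interpolated fEPSP envelope
    peak_rel = None
    area = 0.0
    flagged = True
    if popspike_window_ms is None:
        window = locate_popspike_window(
            sweep, stim_onset_ms, analysis_window_ms, noise_floor_mv, 0.0
        )
    else:
        window = popspike_window_ms
    if window is not None:
        m1 = int(np.searchsorted(tt, window[0]))
        m2 = min(int(np.searchsorted(tt, window[1])), x.size - 1)
        if m2 > m1 + 1:
            envelope = _fepsp_envelope(x, m1, m2, dt)
            deflection = x[m1 : m2 + 1] - envelope
            if float(deflection.max()) > noise_floor_mv:
                # signed integral: rectifying would turn noise into area
                area = max(float(np.sum(deflection) * dt), 0.0)
                peak_rel = float(tt[m1 + int(np.argmax(deflection))])
                flagged = False
    return FieldMetrics(
        fepsp_slope_mv_per_ms=slope,
        popspike_area_mv_ms=area,
        popspike_peak_ms=peak_rel,
        laser_on=laser_on,
        delta_t_ms=delta_t_ms,
        area_flagged=flagged,
    )


def locate_popspike_window(
    sweep: Trace,
    stim_onset_ms: float,
    analysis_window_ms: float = 30.0,
    noise_floor_mv: float = 0.0,
    smooth_cutoff_hz: float = 2000.0,
) -> tuple[float, float] | None:
    """Locate the pop-spike window (flanking minima) on one sweep or average.

    The candidate peak is the most prominent positive deflection in the
    post-stimulus window; the window runs from the minimum before it to the
    minimum after it.  Returns None when no peak rises above the prominence
    floor (no pop-spike, e.g. fully suppressed or blocked transmission).
    """
    from scipy.signal import find_peaks

    t = sweep.times_ms
    if 0 < smooth_cutoff_hz < sweep.sampling_rate / 2:
        sweep = sweep.with_samples(lowpass(sweep, smooth_cutoff_hz).samples)
    sel = (t >= stim_onset_ms) & (t < stim_onset_ms + analysis_window_ms)
    x = sweep.samples[sel]
    tt = t[sel]
    if x.size < 5:
        return None
    fepsp_amp = abs(float(np.min(x) - x[0]))
    min_prominence = max(noise_floor_mv, 0.02 * fepsp_amp, 1e-12)
    cand, props = find_peaks(x, prominence=min_prominence)
    if cand.size == 0:
        return None
    p = int(cand[np.argmax(props["prominences"])])
    m1 = int(np.argmin(x[: p + 1]))
    m2 = p + int(np.argmin(x[p:]))
    if m2 <= m1 + 1:
        return None
    return float(tt[m1]), float(tt[m2])


def _fepsp_envelope(x: np.ndarray, m1: int, m2: int, dt: float) -> np.ndarray:
    """Interpolated fEPSP envelope under the pop-spike, over [m1, m2].

    A quadratic is fit through flanking segments just outside the spike
    (1.5 ms each side), which tracks the curvature of the underlying fEPSP far
    better than a straight chord while keeping the between-flank interpolation
    well conditioned under noise; with too few flank samples the chord is the
    fallback.
    """
    k = max(2, int(round(1.5 / dt)))
    left = np.arange(max(0, m1 - k), m1 + 1)
    right = np.arange(m2, min(x.size, m2 + k + 1))
    idx = np.concatenate([left, right])
    span = np.arange(m1, m2 + 1)
    if left.size >= 2 and right.size >= 2:
        coeffs = np.polyfit(idx.astype(float), x[idx], 2)
        return np.polyval(coeffs, span.astype(float))
    return np.interp(span, [m1, m2], [x[m1], x[m2]])


def laser_change(
    off_values: np.ndarray, on_values: np.ndarray, min_trials: int = 5
) -> float:
    """Laser-induced change of field responses, in percent.

    ``100 * (mean_off - mean_on) / mean_off`` applied to pop-spike areas (or
    any scalar field measure).  Positive values mean suppression by the laser.
    Requires at least ``min_trials`` sweeps per condition, matching the 5-on /
    5-off alternation of the acquisition protocol.
    """
    off = np.asarray(off_values, dtype=float)
    on = np.asarray(on_values, dtype=float)
    if off.size < min_trials or on.size < min_trials:
        raise ValueError(f"need at least {min_trials} trials per condition")
    mean_off = off.mean()
    if abs(mean_off) < 1e-12:
        raise ZeroDivisionError("baseline (laser-off) mean is ~0; change undefined")
    return float(100.0 * (mean_off - on.mean()) / mean_off)


def delay_curve(
    records: list[tuple[float, bool, float]], min_trials: int = 5
) -> PairingResult:
    """Percent change per laser-electrical delay (delta-T).

    ``records`` holds ``(delta_t_ms, laser_on, popspike_area)`` per sweep;
    negative delta-T means the laser precedes the electrical stimulus.
    Delays missing either condition (or with fewer than ``min_trials`` per
    condition) are omitted and reported in ``omitted_delta_t``.
    """
    by_dt: dict[float, dict[bool, list[float]]] = {}
    for dt_ms, on, area in records:
        by_dt.setdefault(float(dt_ms), {}).setdefault(bool(on), []).append(float(area))
    dts, changes, m_off, m_on, n_off, n_on, omitted = [], [], [], [], [], [], []
    for dt_ms in sorted(by_dt):
        conds = by_dt[dt_ms]
        off = conds.get(False, [])
        on = conds.get(True, [])
        if len(off) < min_trials or len(on) < min_trials:
            omitted.append(dt_ms)
            continue
        dts.append(dt_ms)
        changes.append(laser_change(np.array(off), np.array(on), min_trials))
        m_off.append(float(np.mean(off)))
        m_on.append(float(np.mean(on)))
        n_off.append(len(off))
        n_on.append(len(on))
    return PairingResult(
        delta_t_ms=tuple(dts),
        percent_change=tuple(changes),
        mean_off=tuple(m_off),
        mean_on=tuple(m_on),
        n_off=tuple(n_off),
        n_on=tuple(n_on),
        omitted_delta_t=tuple(omitted),
    )


def spike_delay_vs_popspike(
    cell_trace: Trace,
    field_trace: Trace,
    stim_onset_ms: float,
    analysis_window_ms: float = 30.0,
    popspike_peak_ms: float | None = None,
) -> list[tuple[float, str]]:
    """Signed delay of each cell spike relative to the pop-spike peak.

    The cell and field sweeps must share a time base.  Returns a list of
    ``(delay_ms, label)`` with label ``"before"`` (negative delay) or
    ``"after"``.  When the simultaneous field sweep has no pop-spike (e.g.
    granule-cell transmission blocked) pass ``popspike_peak_ms`` from a
    control sweep; otherwise a missing pop-spike raises, since the delays are
    undefined.
    """
    if popspike_peak_ms is None:
        fm = field_metrics(field_trace, stim_onset_ms, analysis_window_ms)
        if fm.popspike_peak_ms is None:
            raise ValueError("no pop-spike detected; spike delays undefined")
        popspike_peak_ms = fm.popspike_peak_ms
    if cell_trace.kind == "current_clamped_voltage":
        peaks, _ = detect_spikes(cell_trace)
    else:
        # loose-patch current: spikes are fast large transients of either sign
        from scipy.signal import find_peaks

        x = np.abs(cell_trace.samples - np.median(cell_trace.samples))
        height = 8.0 * float(np.median(x) / 0.6745 + 1e-12)
        idx, _ = find_peaks(x, height=height, distance=int(1.0 / cell_trace.dt_ms))
        peaks = cell_trace.t0 + idx * cell_trace.dt_ms
    out = []
    for p in np.atleast_1d(peaks):
        delay = float(p - popspike_peak_ms)
        out.append((delay, "before" if delay < 0 else "after"))
    return out
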