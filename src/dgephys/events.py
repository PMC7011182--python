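"""Postsynaptic-current event detection.

Events are identified as peaks in the low-pass (<250 Hz) filtered current that
exceed 4 standard deviations of the recording noise (SD of the >500 Hz
high-pass residual, computed per sweep).  The onset of an event is the time at
which 10% of its peak amplitude is reached in the *unfiltered* signal, and the
amplitude is measured on the unfiltered signal relative to a local baseline
(median of the 5 ms preceding the onset).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal as _signal

from dgephys.core import Trace, lowpass, noise_sd

__all__ = ["Event", "EventTable", "detect_events", "event_onset"]


@dataclass(frozen=True)
class Event:
    """One detected synaptic event."""

    onset_ms: float
    peak_ms: float
    amplitude_pa: float  # baseline-subtracted magnitude on the raw trace
    polarity: int
    sweep_index: int = 0
    label: str = "unassigned"  # evoked | spontaneous | unassigned
    onset_flagged: bool = False  # True when no 10% crossing was found

    def relabel(self, label: str) -> "Event":
        return replace(self, label=label)


@dataclass
class EventTable:
    """Detected events plus the detection parameters that produced them."""

    events: list[Event] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def extend(self, events: Iterable[Event]) -> None:
        self.events.extend(events)

    def in_sweep(self, i: int) -> list[Event]:
        return [e for e in self.events if e.sweep_index == i]

    def sweep_indices(self) -> np.ndarray:
        return np.array(sorted({e.sweep_index for e in self.events}), dtype=int)

    def onsets(self, sweep_index: int | None = None) -> np.ndarray:
        evs = self.events if sweep_index is None else self.in_sweep(sweep_index)
        return np.array([e.onset_ms for e in evs], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sweep": [e.sweep_index for e in self.events],
                "onset_ms": [e.onset_ms for e in self.events],
                "peak_ms": [e.peak_ms for e in self.events],
                "amplitude_pa": [e.amplitude_pa for e in self.events],
                "polarity": [e.polarity for e in self.events],
                "label": [e.label for e in self.events],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, params: dict | None = None) -> "EventTable":
        events = [
            Event(
                onset_ms=float(r.onset_ms),
                peak_ms=float(r.peak_ms),
                amplitude_pa=float(r.amplitude_pa),
                polarity=int(r.polarity),
                sweep_index=int(r.sweep),
                label=str(r.label),
            )
            for r in frame.itertuples()
        ]
        return cls(events=events, params=params or {})


BASELINE_WINDOW_MS = 5.0  # median window preceding the onset
PRE_PEAK_SEARCH_MS = 20.0  # how far before a peak the onset search extends


def detect_events(
    trace: Trace,
    polarity: int = -1,
    k_sd: float = 4.0,
    low_cutoff_hz: float = 250.0,
    noise_cutoff_hz: float = 500.0,
    refractory_ms: float = 2.0,
    sweep_index: int = 0,
) -> EventTable:
    """Detect PSC-like events in a voltage-clamp current sweep.

    The trace is sign-flipped according to ``polarity`` so detection always
    searches positive peaks; events are reported with the original polarity.
    Peaks closer than ``refractory_ms`` are merged (the larger wins, earliest
    sample of a plateau breaks ties, which is how ``scipy.signal.find_peaks``
    with ``distance`` behaves on flipped data).
    """
    if trace.duration_ms < 10.0:
        raise ValueError("trace must be at least 10 ms long")
    if polarity not in (-1, 1):
        raise ValueError("polarity must be -1 or +1")
    flipped = trace.samples * polarity
    sd = noise_sd(trace, noise_cutoff_hz)
    low = lowpass(trace, low_cutoff_hz).samples * polarity
    threshold = k_sd * sd
    distance = max(1, int(round(refractory_ms / trace.dt_ms)))
    if threshold <= 0:
        # noiseless trace: any structure is signal; use a tiny absolute floor
        threshold = 1e-9
    peaks, _ = _signal.find_peaks(low, height=threshold, distance=distance)
    events = []
    for p in peaks:
        ev = _measure_event(trace, flipped, int(p), polarity, sweep_index)
        if ev is not None:
            events.append(ev)
    params = {
        "polarity": polarity,
        "k_sd": k_sd,
        "low_cutoff_hz": low_cutoff_hz,
        "noise_cutoff_hz": noise_cutoff_hz,
        "refractory_ms": refractory_ms,
        "noise_sd_pa": sd,
    }
    return EventTable(events=events, params=params)


def _measure_event(
    trace: Trace,
    flipped: np.ndarray,
    p_low: int,
    polarity: int,
    sweep_index: int,
) -> Event | None:
    """Amplitude/onset measurement on the unfiltered trace around a peak.

    Two passes: a provisional baseline from the 5 ms window immediately before
    the filtered peak gives a provisional onset; the final baseline is the
    median of the 5 ms preceding that onset.
    """
    dt = trace.dt_ms
    p_raw = p_low  # zero-phase filtering leaves the peak time unbiased
    # amplitude from the raw trace averaged over a short window at the peak:
    # a raw argmax would ride the largest noise excursion and bias upward
    half_win = max(1, int(round(0.3 / dt)))
    lo = max(0, p_raw - half_win)
    hi = min(flipped.size, p_raw + half_win + 1)
    peak_value = float(np.mean(flipped[lo:hi]))

    b_n = max(1, int(round(BASELINE_WINDOW_MS / dt)))

    def _baseline(before_idx: int) -> float:
        a = max(0, before_idx - b_n)
        if before_idx <= a:
            return float(flipped[max(0, before_idx)])
        return float(np.median(flipped[a:before_idx]))

    base = _baseline(p_raw)
    onset_idx, flagged = _onset_index(flipped, p_raw, peak_value, base, dt)
    base = _baseline(onset_idx)
    onset_idx, flagged = _onset_index(flipped, p_raw, peak_value, base, dt)
    amplitude = peak_value - base
    if amplitude <= 0:
        return None
    return Event(
        onset_ms=trace.t0 + onset_idx * dt,
        peak_ms=trace.t0 + p_raw * dt,
        amplitude_pa=amplitude,
        polarity=polarity,
        sweep_index=sweep_index,
        label="unassigned",
        onset_flagged=flagged,
    )


def _onset_index(
    flipped: np.ndarray, p_raw: int, peak_value: float, base: float, dt: float
) -> tuple[int, bool]:
    """Latest pre-peak crossing of 10% of the baseline-subtracted amplitude.

    Linear search back from the peak for the last sample at or below the 10%
    level.  When no crossing exists in the search window the window start is
    returned, flagged.
    """
    amplitude = peak_value - base
    level = base + 0.1 * amplitude
    start = max(0, p_raw - int(round(PRE_PEAK_SEARCH_MS / dt)))
    seg = flipped[start : p_raw + 1]
    below = np.nonzero(seg <= level)[0]
    if below.size == 0:
        return start, True
    return start + int(below[-1]), False


def event_onset(trace: Trace, event: Event, search_ms: float = PRE_PEAK_SEARCH_MS) -> float:
    """Onset time (ms) of a detected event: 10%-of-peak crossing, unfiltered.

    The amplitude reference is the event's stored baseline-subtracted peak;
    the baseline is re-derived as ``peak - amplitude`` so the function can be
    applied to any trace/event pair measured consistently.
    """
    dt = trace.dt_ms
    p_raw = trace.index_at(event.peak_ms)
    flipped = trace.samples * event.polarity
    base = float(flipped[p_raw]) - event.amplitude_pa
    level = base + 0.1 * event.amplitude_pa
    start = max(0, p_raw - int(round(search_ms / dt)))
    seg = flipped[start : p_raw + 1]
    below = np.nonzero(seg <= level)[0]
    if below.size == 0:
        return trace.t0 + start * dt
    return trace.t0 + (start + int(below[-1])) * dt
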