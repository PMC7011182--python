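"""Shuffle-based classification of stimulus-locked (laser-evoked) responses.

A cell is classified as responsive when events accumulate within a 12 ms
window after stimulation more than expected by chance.  The null distribution
is built by a 2000-step shuffling procedure: each shuffle applies an
independent uniform circular time shift to every sweep's event train (which
preserves within-sweep event counts and inter-event structure) and recounts
in-window events.  The p-value uses the add-one permutation estimator,
``p = (1 + #{null >= observed}) / (1 + n_shuffles)``, so it is never zero and
is exact under the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dgephys.core import StimulusProtocol
from dgephys.events import EventTable

__all__ = [
    "ResponsivenessResult",
    "SuccessRecord",
    "classify_responsive",
    "split_evoked",
    "success_record",
    "connection_summary",
    "count_in_window",
]

RESPONSE_WINDOW_MS = 12.0
N_SHUFFLES = 2000
ALPHA = 0.05


@dataclass(frozen=True)
class ResponsivenessResult:
    """Outcome of the circular-shift permutation test for one cell."""

    observed_in_window: int
    window_ms: float
    n_shuffles: int
    p_value: float
    responsive: bool
    null_mean: float
    null_sd: float
    null_max: int

    def __post_init__(self) -> None:
        assert self.p_value >= 1.0 / (self.n_shuffles + 1.0)


@dataclass(frozen=True)
class SuccessRecord:
    """Per-trial success flags and the resulting success probability."""

    flags: tuple[bool, ...]

    @property
    def n_trials(self) -> int:
        return len(self.flags)

    @property
    def n_successes(self) -> int:
        return int(sum(self.flags))

    @property
    def success_probability(self) -> float:
        if not self.flags:
            return float("nan")
        return self.n_successes / self.n_trials


def _window_edges(onsets_ms: np.ndarray, window_ms: float) -> np.ndarray:
    """Flattened sorted edges of the (onset, onset+window] intervals."""
    edges = np.column_stack([onsets_ms, onsets_ms + window_ms]).ravel()
    return edges


def count_in_window(
    times_ms: np.ndarray, onsets_ms: np.ndarray, window_ms: float = RESPONSE_WINDOW_MS
) -> np.ndarray:
    """Membership of each time in any half-open window (onset, onset+w].

    Returns a boolean array.  Windows are assumed non-overlapping (stimuli are
    farther apart than the window, true for all protocols used here).
    """
    edges = _window_edges(np.asarray(onsets_ms, float), window_ms)
    idx = np.searchsorted(edges, np.asarray(times_ms, float), side="left")
    return (idx % 2) == 1


def classify_responsive(
    events: EventTable,
    protocol: StimulusProtocol,
    sweep_duration_ms: float,
    n_sweeps: int,
    window_ms: float = RESPONSE_WINDOW_MS,
    n_shuffles: int = N_SHUFFLES,
    alpha: float = ALPHA,
    seed: int = 0,
) -> ResponsivenessResult:
    """Permutation test for stimulus-locked event accumulation.

    ``protocol.onsets_ms`` are the stimulus times within each sweep (the same
    for every sweep); the observed statistic is the total number of detected
    events whose *onset* falls in ``(stimulus, stimulus + window_ms]`` across
    all sweeps.  At least 5 total stimulus presentations are required
    (``n_sweeps * protocol.n_pulses >= 5``).

    A cell with zero events yields ``p = 1`` and is not responsive.
    """
    if n_sweeps * protocol.n_pulses < 5:
        raise ValueError("need at least 5 stimulus presentations")
    if sweep_duration_ms <= 0:
        raise ValueError("sweep_duration_ms must be positive")
    onsets = np.asarray(protocol.onsets_ms, float)
    times = events.onsets()
    sweep_of = np.array([e.sweep_index for e in events.events], dtype=int)
    if times.size == 0:
        return ResponsivenessResult(
            observed_in_window=0,
            window_ms=window_ms,
            n_shuffles=n_shuffles,
            p_value=1.0,
            responsive=False,
            null_mean=0.0,
            null_sd=0.0,
            null_max=0,
        )
    observed = int(np.count_nonzero(count_in_window(times, onsets, window_ms)))

    rng = np.random.default_rng(seed)
    # offsets[shuffle, sweep]: independent uniform circular shift per sweep
    offsets = rng.uniform(0.0, sweep_duration_ms, size=(n_shuffles, n_sweeps))
    shifted = (times[None, :] + offsets[:, sweep_of]) % sweep_duration_ms
    edges = _window_edges(onsets, window_ms)
    idx = np.searchsorted(edges, shifted, side="left")
    null_counts = ((idx % 2) == 1).sum(axis=1)

    p = (1.0 + np.count_nonzero(null_counts >= observed)) / (1.0 + n_shuffles)
    return ResponsivenessResult(
        observed_in_window=observed,
        window_ms=window_ms,
        n_shuffles=n_shuffles,
        p_value=float(p),
        responsive=bool(p < alpha),
        null_mean=float(null_counts.mean()),
        null_sd=float(null_counts.std()),
        null_max=int(null_counts.max()),
    )


def split_evoked(
    events: EventTable,
    protocol: StimulusProtocol,
    window_ms: float = RESPONSE_WINDOW_MS,
    responsive: bool = True,
) -> EventTable:
    """Label events as evoked or spontaneous.

    For a responsive cell, the *first* event whose onset falls in
    ``(stimulus, stimulus + window_ms]`` after each stimulus is labeled
    evoked; every other event (including later in-window events) is
    spontaneous.  For a non-responsive cell all events are spontaneous.
    """
    onsets = np.asarray(protocol.onsets_ms, float)
    labeled: list = []
    if not responsive:
        return EventTable(
            events=[e.relabel("spontaneous") for e in events.events],
            params=dict(events.params),
        )
    for sweep in sorted({e.sweep_index for e in events.events}):
        evs = sorted(events.in_sweep(sweep), key=lambda e: e.onset_ms)
        claimed: set[int] = set()
        for e in evs:
            # which stimulus window does this onset fall in, if any?
            k = int(np.searchsorted(onsets, e.onset_ms, side="left")) - 1
            if (
                k >= 0
                and onsets[k] < e.onset_ms <= onsets[k] + window_ms
                and k not in claimed
            ):
                claimed.add(k)
                labeled.append(e.relabel("evoked"))
            else:
                labeled.append(e.relabel("spontaneous"))
    return EventTable(events=labeled, params=dict(events.params))


def success_record(
    events: EventTable, protocol: StimulusProtocol, n_sweeps: int
) -> SuccessRecord:
    """Per-stimulus success flags from evoked labels.

    One flag per stimulus presentation (sweep x pulse); True when an evoked
    event was recorded for that presentation.  The success probability is the
    fraction of flagged trials.
    """
    onsets = np.asarray(protocol.onsets_ms, float)
    flags = np.zeros((n_sweeps, onsets.size), dtype=bool)
    for e in events.events:
        if e.label != "evoked":
            continue
        k = int(np.searchsorted(onsets, e.onset_ms, side="left")) - 1
        if k >= 0 and 0 <= e.sweep_index < n_sweeps:
            flags[e.sweep_index, k] = True
    return SuccessRecord(flags=tuple(bool(f) for f in flags.ravel()))


def connection_summary(
    single_pulse: list[ResponsivenessResult],
    train: list[ResponsivenessResult],
) -> dict:
    """Proportions of cells connected as judged by single pulses vs. trains.

    Facilitating synapses can appear silent under single-pulse stimulation yet
    reveal themselves during trains, so the two fractions are reported side by
    side (no ordering is assumed).  Empty cohorts yield ``None`` fractions.
    """
    out: dict = {
        "n_cells_single": len(single_pulse),
        "n_cells_train": len(train),
        "n_responsive_single": sum(r.responsive for r in single_pulse),
        "n_responsive_train": sum(r.responsive for r in train),
    }
    out["fraction_single"] = (
        out["n_responsive_single"] / out["n_cells_single"] if single_pulse else None
    )
    out["fraction_train"] = (
        out["n_responsive_train"] / out["n_cells_train"] if train else None
    )
    return out
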