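"""Data model, sweep I/O, band filtering and recording quality control.

Canonical units throughout the package: current in pA, voltage in mV, time in
ms, frequency in Hz.  Converters live only at I/O boundaries; everything in
memory is already in these units.

Recordings are modeled as :class:`Trace` objects (one sampled signal), grouped
into :class:`SweepSet` objects (repeated stimulus-aligned sweeps sharing one
:class:`StimulusProtocol` and holding potential).  Two on-disk layouts are
supported: an HDF5 container (lossless) and plain CSV tables with a protocol
sidecar (portable, fixed decimal precision).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "Trace",
    "StimulusProtocol",
    "QCRecord",
    "SweepSet",
    "QC_THRESHOLDS",
    "qc_pass",
    "lowpass",
    "highpass",
    "noise_sd",
    "read_sweepset",
    "write_sweepset",
    "FormatError",
]

TRACE_KINDS = ("voltage_clamped_current", "current_clamped_voltage", "field")


class FormatError(ValueError):
    """A sweep file does not match the documented layout."""


@dataclass(frozen=True)
class Trace:
    """One sampled signal with its rate, kind, and time origin.

    Parameters
    ----------
    samples
        Signal values: pA for ``voltage_clamped_current``, mV for
        ``current_clamped_voltage`` and ``field``.
    sampling_rate
        Acquisition rate in Hz (recordings here are 10-20 kHz).
    kind
        One of ``voltage_clamped_current``, ``current_clamped_voltage``,
        ``field``.
    t0
        Time of the first sample in ms (default 0).
    """

    samples: np.ndarray
    sampling_rate: float
    kind: str = "voltage_clamped_current"
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("samples must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if self.kind not in TRACE_KINDS:
            raise ValueError(f"unknown trace kind {self.kind!r}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def dt_ms(self) -> float:
        """Sample period in ms."""
        return 1000.0 / self.sampling_rate

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms, starting at ``t0``."""
        return self.t0 + np.arange(self.n_samples) * self.dt_ms

    def index_at(self, t_ms: float) -> int:
        """Nearest sample index for a time in ms (clipped to valid range)."""
        i = int(round((t_ms - self.t0) / self.dt_ms))
        return min(max(i, 0), self.n_samples - 1)

    def with_samples(self, samples: np.ndarray) -> "Trace":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered stimulus onsets with pulse width and modality.

    ``train_rate_hz`` describes within-train pulse frequency (e.g. 20 Hz for
    5-pulse trains); ``repetition_rate_hz`` the sweep-to-sweep repetition
    (0.07 Hz in the optogenetic protocols emulated here).
    """

    onsets_ms: np.ndarray
    width_ms: float
    modality: str = "laser"
    train_rate_hz: float | None = None
    repetition_rate_hz: float = 0.07

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets_ms, dtype=float)
        object.__setattr__(self, "onsets_ms", onsets)
        if onsets.ndim != 1 or onsets.size == 0:
            raise ValueError("onsets_ms must be a non-empty 1-D array")
        if onsets.size > 1 and not np.all(np.diff(onsets) > 0):
            raise ValueError("onsets_ms must be strictly increasing")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")
        if self.modality not in ("laser", "electrical"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.train_rate_hz is not None and self.train_rate_hz <= 0:
            raise ValueError("train_rate_hz must be positive when set")

    @property
    def n_pulses(self) -> int:
        return int(self.onsets_ms.size)

    @property
    def inter_pulse_ms(self) -> float | None:
        """Within-train inter-pulse interval in ms, if a train."""
        if self.train_rate_hz is not None:
            return 1000.0 / self.train_rate_hz
        if self.n_pulses > 1:
            return float(np.diff(self.onsets_ms).mean())
        return None


# Inclusion criteria per cell class: (max |leak| pA, max series resistance MOhm).
# Granule cells: leak < 100 pA, Rs <= 25 MOhm; interneurons: leak < 250 pA,
# Rs <= 15 MOhm.
QC_THRESHOLDS: dict[str, tuple[float, float]] = {
    "GC": (100.0, 25.0),
    "IN": (250.0, 15.0),
}


@dataclass(frozen=True)
class QCRecord:
    """Per-recording quality metadata used for inclusion decisions."""

    leak_current_pa: float
    series_resistance_mohm: float
    cell_class: str = "GC"

    def __post_init__(self) -> None:
        if not (
            np.isfinite(self.leak_current_pa)
            and np.isfinite(self.series_resistance_mohm)
        ):
            raise ValueError("QC values must be finite")


def qc_pass(
    q: QCRecord, thresholds: dict[str, tuple[float, float]] | None = None
) -> bool:
    """Apply the recording inclusion criteria.

    A recording passes when the absolute leak current is below the class limit
    (strict) and the series resistance does not exceed the class limit.
    Thresholds can be overridden per cell class via ``thresholds``.
    """
    table = thresholds if thresholds is not None else QC_THRESHOLDS
    if q.cell_class not in table:
        raise ValueError(f"unknown cell_class {q.cell_class!r}")
    max_leak, max_rs = table[q.cell_class]
    return abs(q.leak_current_pa) < max_leak and q.series_resistance_mohm <= max_rs


@dataclass(frozen=True)
class SweepSet:
    """Repeated stimulus-aligned traces sharing one protocol."""

    sweeps: tuple[Trace, ...]
    protocol: StimulusProtocol
    holding_potential_mv: float | None = None
    qc: QCRecord | None = None

    def __post_init__(self) -> None:
        sweeps = tuple(self.sweeps)
        object.__setattr__(self, "sweeps", sweeps)
        if not sweeps:
            raise ValueError("SweepSet requires at least one sweep")
        n = sweeps[0].n_samples
        rate = sweeps[0].sampling_rate
        for tr in sweeps:
            if tr.n_samples != n or tr.sampling_rate != rate:
                raise ValueError("all sweeps must share length and rate")
        duration = sweeps[0].duration_ms
        if np.any(self.protocol.onsets_ms < sweeps[0].t0) or np.any(
            self.protocol.onsets_ms >= sweeps[0].t0 + duration
        ):
            raise ValueError("protocol onsets must fall within sweep duration")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    @property
    def sampling_rate(self) -> float:
        return self.sweeps[0].sampling_rate

    @property
    def duration_ms(self) -> float:
        return self.sweeps[0].duration_ms

    def data(self) -> np.ndarray:
        """Stack sweeps into a (n_sweeps, n_samples) array."""
        return np.stack([tr.samples for tr in self.sweeps])

    def mean_trace(self, indices: Sequence[int] | None = None) -> Trace:
        """Average sweep, optionally over a subset (e.g. success trials)."""
        data = self.data()
        if indices is not None:
            data = data[np.asarray(indices, dtype=int)]
        return self.sweeps[0].with_samples(data.mean(axis=0))


# ---------------------------------------------------------------------------
# Filtering


def _butter_sos(trace: Trace, cutoff_hz: float, btype: str) -> np.ndarray:
    nyquist = trace.sampling_rate / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)"
        )
    return signal.butter(4, cutoff_hz, btype=btype, fs=trace.sampling_rate, output="sos")


def lowpass(trace: Trace, cutoff_hz: float = 250.0) -> Trace:
    """Zero-phase 4th-order Butterworth low-pass (forward-backward).

    The 250 Hz default is the band in which PSC peaks are detected.  Zero-phase
    filtering keeps evoked latencies unshifted; the DC level is preserved.
    """
    sos = _butter_sos(trace, cutoff_hz, "lowpass")
    return trace.with_samples(signal.sosfiltfilt(sos, trace.samples))


def highpass(trace: Trace, cutoff_hz: float = 500.0) -> Trace:
    """Zero-phase 4th-order Butterworth high-pass (forward-backward)."""
    sos = _butter_sos(trace, cutoff_hz, "highpass")
    return trace.with_samples(signal.sosfiltfilt(sos, trace.samples))


def noise_sd(trace: Trace, cutoff_hz: float = 500.0) -> float:
    """Recording-noise standard deviation from the >``cutoff_hz`` residual.

    PSCs are slow relative to 500 Hz, so the high-pass band contains almost
    pure instrument noise; its SD sets the event-detection threshold.
    """
    return float(np.std(highpass(trace, cutoff_hz).samples))


# ---------------------------------------------------------------------------
# I/O: HDF5 container

_H5_REQUIRED_SWEEP_ATTRS = ("sampling_rate_hz", "units")


def _write_hdf5(s: SweepSet, path: Path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("sweeps")
        g.create_dataset("data", data=s.data().astype(np.float64))
        g.attrs["sampling_rate_hz"] = s.sampling_rate
        g.attrs["units"] = _units_for_kind(s.sweeps[0].kind)
        g.attrs["kind"] = s.sweeps[0].kind
        g.attrs["t0_ms"] = s.sweeps[0].t0
        if s.holding_potential_mv is not None:
            g.attrs["holding_potential_mv"] = s.holding_potential_mv
        p = f.create_group("protocol")
        p.create_dataset("onsets_ms", data=np.asarray(s.protocol.onsets_ms))
        p.create_dataset("width_ms", data=float(s.protocol.width_ms))
        p.attrs["modality"] = s.protocol.modality
        if s.protocol.train_rate_hz is not None:
            p.attrs["train_rate_hz"] = s.protocol.train_rate_hz
        p.attrs["repetition_rate_hz"] = s.protocol.repetition_rate_hz
        if s.qc is not None:
            q = f.create_group("qc")
            q.attrs["leak_current_pa"] = s.qc.leak_current_pa
            q.attrs["series_resistance_mohm"] = s.qc.series_resistance_mohm
            q.attrs["cell_class"] = s.qc.cell_class


def _read_hdf5(path: Path) -> SweepSet:
    with h5py.File(path, "r") as f:
        if "sweeps" not in f or "data" not in f["sweeps"]:
            raise FormatError(f"{path}: missing /sweeps/data")
        g = f["sweeps"]
        for attr in _H5_REQUIRED_SWEEP_ATTRS:
            if attr not in g.attrs:
                raise FormatError(f"{path}: /sweeps missing attribute {attr!r}")
        data = np.asarray(g["data"], dtype=float)
        if data.ndim != 2:
            raise FormatError(f"{path}: /sweeps/data must be 2-D (sweeps x samples)")
        rate = float(g.attrs["sampling_rate_hz"])
        kind = str(g.attrs.get("kind", "voltage_clamped_current"))
        t0 = float(g.attrs.get("t0_ms", 0.0))
        holding = (
            float(g.attrs["holding_potential_mv"])
            if "holding_potential_mv" in g.attrs
            else None
        )
        if "protocol" not in f:
            raise FormatError(f"{path}: missing /protocol group")
        p = f["protocol"]
        if "onsets_ms" not in p or "width_ms" not in p:
            raise FormatError(f"{path}: /protocol missing onsets_ms/width_ms")
        protocol = StimulusProtocol(
            onsets_ms=np.asarray(p["onsets_ms"], dtype=float),
            width_ms=float(np.asarray(p["width_ms"])),
            modality=str(p.attrs.get("modality", "laser")),
            train_rate_hz=(
                float(p.attrs["train_rate_hz"]) if "train_rate_hz" in p.attrs else None
            ),
            repetition_rate_hz=float(p.attrs.get("repetition_rate_hz", 0.07)),
        )
        qc = None
        if "qc" in f:
            qa = f["qc"].attrs
            qc = QCRecord(
                leak_current_pa=float(qa["leak_current_pa"]),
                series_resistance_mohm=float(qa["series_resistance_mohm"]),
                cell_class=str(qa["cell_class"]),
            )
    sweeps = tuple(
        Trace(samples=row, sampling_rate=rate, kind=kind, t0=t0) for row in data
    )
    return SweepSet(
        sweeps=sweeps, protocol=protocol, holding_potential_mv=holding, qc=qc
    )


def _units_for_kind(kind: str) -> str:
    return "pA" if kind == "voltage_clamped_current" else "mV"


# ---------------------------------------------------------------------------
# I/O: CSV tables (main table + protocol sidecar)

CSV_DECIMALS = 6


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".protocol.csv")


def _write_csv(s: SweepSet, path: Path) -> None:
    data = s.data()
    table = pd.DataFrame(
        {"time_ms": s.sweeps[0].times_ms}
        | {f"sweep_{i:03d}": data[i] for i in range(s.n_sweeps)}
    )
    table.to_csv(path, index=False, float_format=f"%.{CSV_DECIMALS}f")
    side = pd.DataFrame(
        {
            "onset_ms": np.asarray(s.protocol.onsets_ms),
            "width_ms": s.protocol.width_ms,
            "modality": s.protocol.modality,
        }
    )
    side["train_rate_hz"] = (
        s.protocol.train_rate_hz if s.protocol.train_rate_hz is not None else ""
    )
    side["repetition_rate_hz"] = s.protocol.repetition_rate_hz
    side["kind"] = s.sweeps[0].kind
    side["holding_potential_mv"] = (
        s.holding_potential_mv if s.holding_potential_mv is not None else ""
    )
    if s.qc is not None:
        side["leak_current_pa"] = s.qc.leak_current_pa
        side["series_resistance_mohm"] = s.qc.series_resistance_mohm
        side["cell_class"] = s.qc.cell_class
    side.to_csv(_sidecar_path(path), index=False)


def _read_csv(path: Path) -> SweepSet:
    table = pd.read_csv(path)
    if "time_ms" not in table.columns:
        raise FormatError(f"{path}: missing time_ms column")
    sweep_cols = [c for c in table.columns if c.startswith("sweep_")]
    if not sweep_cols:
        raise FormatError(f"{path}: no sweep_* columns")
    t = table["time_ms"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise FormatError(f"{path}: time_ms must be uniformly sampled")
    rate = 1000.0 / dt[0]
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"{path}: missing protocol sidecar {sidecar.name}")
    side = pd.read_csv(sidecar)
    for col in ("onset_ms", "width_ms", "modality"):
        if col not in side.columns:
            raise FormatError(f"{sidecar}: missing column {col}")
    first = side.iloc[0]
    train_rate = first.get("train_rate_hz", np.nan)
    train_rate = None if pd.isna(train_rate) or train_rate == "" else float(train_rate)
    protocol = StimulusProtocol(
        onsets_ms=side["onset_ms"].to_numpy(dtype=float),
        width_ms=float(first["width_ms"]),
        modality=str(first["modality"]),
        train_rate_hz=train_rate,
        repetition_rate_hz=float(first.get("repetition_rate_hz", 0.07)),
    )
    kind = str(first.get("kind", "voltage_clamped_current"))
    holding = first.get("holding_potential_mv", np.nan)
    holding = None if pd.isna(holding) or holding == "" else float(holding)
    qc = None
    if "leak_current_pa" in side.columns and not pd.isna(first["leak_current_pa"]):
        qc = QCRecord(
            leak_current_pa=float(first["leak_current_pa"]),
            series_resistance_mohm=float(first["series_resistance_mohm"]),
            cell_class=str(first["cell_class"]),
        )
    sweeps = tuple(
        Trace(
            samples=table[c].to_numpy(dtype=float),
            sampling_rate=rate,
            kind=kind,
            t0=float(t[0]),
        )
        for c in sorted(sweep_cols)
    )
    return SweepSet(
        sweeps=sweeps, protocol=protocol, holding_potential_mv=holding, qc=qc
    )


def write_sweepset(s: SweepSet, path: str | Path, format: str = "hdf5") -> None:
    """Write a sweep set to disk.

    ``hdf5`` is lossless; ``csv`` stores samples to 6 decimals (sub-fA for
    currents) with the protocol in a ``<name>.protocol.csv`` sidecar.
    """
    path = Path(path)
    if format == "hdf5":
        _write_hdf5(s, path)
    elif format == "csv":
        _write_csv(s, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_sweepset(path: str | Path, format: str | None = None) -> SweepSet:
    """Read a sweep set written by :func:`write_sweepset`.

    ``format`` is inferred from the suffix when omitted (.h5/.hdf5 vs .csv).
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "hdf5"
    if format == "hdf5":
        return _read_hdf5(path)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {format!r}")
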