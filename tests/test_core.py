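"""Data model, filtering, noise estimation, QC and sweep I/O."""

import numpy as np
import pytest

from dgephys.core import (
    FormatError,
    QCRecord,
    StimulusProtocol,
    SweepSet,
    Trace,
    lowpass,
    noise_sd,
    qc_pass,
    read_sweepset,
    write_sweepset,
)

RATE = 20000.0
DT = 1000.0 / RATE


def _sweepset(n_sweeps=3, n_samples=2000, rate=RATE, seed=0):
    rng = np.random.default_rng(seed)
    sweeps = tuple(
        Trace(samples=rng.normal(0, 2, n_samples), sampling_rate=rate)
        for _ in range(n_sweeps)
    )
    protocol = StimulusProtocol(onsets_ms=np.array([10.0, 30.0, 50.0]), width_ms=0.2)
    qc = QCRecord(leak_current_pa=-40.0, series_resistance_mohm=18.0, cell_class="GC")
    return SweepSet(
        sweeps=sweeps, protocol=protocol, holding_potential_mv=-70.0, qc=qc
    )


class TestTraceModel:
    def test_invariants_rejected(self):
        with pytest.raises(ValueError):
            Trace(samples=np.array([1.0, 2.0]), sampling_rate=0.0)
        with pytest.raises(ValueError):
            Trace(samples=np.array([1.0]), sampling_rate=RATE)
        with pytest.raises(ValueError):
            Trace(samples=np.array([1.0, np.nan]), sampling_rate=RATE)

    def test_protocol_monotonicity(self):
        with pytest.raises(ValueError):
            StimulusProtocol(onsets_ms=np.array([10.0, 5.0]), width_ms=0.2)

    def test_sweepset_rejects_mismatched_sweeps(self):
        a = Trace(samples=np.zeros(100), sampling_rate=RATE)
        b = Trace(samples=np.zeros(50), sampling_rate=RATE)
        proto = StimulusProtocol(onsets_ms=np.array([1.0]), width_ms=0.2)
        with pytest.raises(ValueError):
            SweepSet(sweeps=(a, b), protocol=proto)

    def test_onsets_must_fit_sweep(self):
        a = Trace(samples=np.zeros(100), sampling_rate=RATE)  # 5 ms
        proto = StimulusProtocol(onsets_ms=np.array([50.0]), width_ms=0.2)
        with pytest.raises(ValueError):
            SweepSet(sweeps=(a,), protocol=proto)


class TestFiltering:
    def test_dc_preserved(self):
        tr = Trace(samples=np.full(4000, 5.0), sampling_rate=RATE)
        out = lowpass(tr, 250.0)
        assert np.allclose(out.samples, 5.0, rtol=1e-3)

    def test_stopband_attenuation(self):
        # 2 kHz sinusoid must be attenuated below 5% by the 250 Hz filter
        t = np.arange(8000) * DT / 1000.0
        tr = Trace(samples=np.sin(2 * np.pi * 2000 * t), sampling_rate=RATE)
        out = lowpass(tr, 250.0).samples[1000:-1000]
        assert np.max(np.abs(out)) < 0.05

    def test_passband_preserved(self):
        t = np.arange(20000) * DT / 1000.0
        slow = np.sin(2 * np.pi * 10 * t)
        fast = np.sin(2 * np.pi * 2000 * t)
        tr = Trace(samples=slow + fast, sampling_rate=RATE)
        out = lowpass(tr, 250.0).samples
        r = np.corrcoef(out, slow)[0, 1]
        assert r > 0.99

    def test_idempotent_in_passband(self):
        """Refiltering a pass-band-limited signal changes it <0.5% RMS."""
        t = np.arange(40000) * DT / 1000.0
        rng = np.random.default_rng(1)
        x = sum(
            a * np.sin(2 * np.pi * f * t + ph)
            for a, f, ph in zip(
                rng.uniform(0.5, 2, 8), rng.uniform(5, 150, 8), rng.uniform(0, 6, 8)
            )
        )
        once = lowpass(Trace(samples=x, sampling_rate=RATE), 250.0)
        twice = lowpass(once, 250.0)
        mid = slice(2000, -2000)  # exclude filter edge transients
        rms = np.sqrt(np.mean(once.samples[mid] ** 2))
        diff = np.sqrt(np.mean((twice.samples[mid] - once.samples[mid]) ** 2))
        assert diff < 0.005 * rms

    def test_cutoff_above_nyquist_rejected(self):
        tr = Trace(samples=np.zeros(100), sampling_rate=1000.0)
        with pytest.raises(ValueError):
            lowpass(tr, 600.0)


class TestNoiseSD:
    def test_white_noise_bandpower(self):
        """High-pass SD of white noise matches the ideal band-power split."""
        sd_true = 4.0
        ests = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            tr = Trace(samples=rng.normal(0, sd_true, 20000), sampling_rate=RATE)
            ests.append(noise_sd(tr, 500.0))
        expected = sd_true * np.sqrt((RATE / 2 - 500.0) / (RATE / 2))
        assert abs(np.mean(ests) - expected) / expected < 0.10

    def test_slow_signal_invisible(self):
        """A noiseless slow PSC contributes almost nothing above 500 Hz."""
        t = np.arange(0, 200, DT)
        psc = 100.0 * (np.exp(-t / 10.0) - np.exp(-t / 1.0))
        tr = Trace(samples=psc, sampling_rate=RATE)
        assert noise_sd(tr, 500.0) < 0.02 * 100.0

    def test_zero_trace(self):
        tr = Trace(samples=np.zeros(1000), sampling_rate=RATE)
        assert noise_sd(tr) == 0.0

    def test_invariant_under_slow_additions(self):
        """Adding band-limited (<250 Hz) signal changes the estimate <5%."""
        rng = np.random.default_rng(7)
        noise = rng.normal(0, 3, 40000)
        t = np.arange(40000) * DT / 1000.0
        slow = 50 * np.sin(2 * np.pi * 30 * t)
        a = noise_sd(Trace(samples=noise, sampling_rate=RATE))
        b = noise_sd(Trace(samples=noise + slow, sampling_rate=RATE))
        assert abs(a - b) / a < 0.05


class TestQC:
    @pytest.mark.parametrize(
        "leak,rs,cls,expected",
        [
            (-50.0, 20.0, "GC", True),
            (-50.0, 26.0, "GC", False),
            (-120.0, 20.0, "GC", False),
            (-200.0, 10.0, "IN", True),
            (-200.0, 16.0, "IN", False),
            (-260.0, 10.0, "IN", False),
        ],
    )
    def test_class_specific_thresholds(self, leak, rs, cls, expected):
        q = QCRecord(leak_current_pa=leak, series_resistance_mohm=rs, cell_class=cls)
        assert qc_pass(q) is expected

    def test_unknown_class_rejected(self):
        q = QCRecord(leak_current_pa=0, series_resistance_mohm=10, cell_class="PC")
        with pytest.raises(ValueError):
            qc_pass(q)


class TestIO:
    @pytest.mark.parametrize("fmt", ["hdf5", "csv"])
    def test_roundtrip(self, fmt, tmp_path):
        s = _sweepset()
        path = tmp_path / ("sweeps.h5" if fmt == "hdf5" else "sweeps.csv")
        write_sweepset(s, path, format=fmt)
        back = read_sweepset(path, format=fmt)
        assert back.n_sweeps == s.n_sweeps
        assert back.sampling_rate == pytest.approx(s.sampling_rate, rel=1e-6)
        np.testing.assert_array_equal(back.protocol.onsets_ms, s.protocol.onsets_ms)
        assert back.holding_potential_mv == pytest.approx(-70.0)
        assert back.qc is not None and back.qc.cell_class == "GC"
        tol = 0.0 if fmt == "hdf5" else 1.1e-6
        for a, b in zip(back.sweeps, s.sweeps):
            assert np.max(np.abs(a.samples - b.samples)) <= tol

    def test_hdf5_roundtrip_bit_identical(self, tmp_path):
        s = _sweepset()
        write_sweepset(s, tmp_path / "x.h5", format="hdf5")
        back = read_sweepset(tmp_path / "x.h5")
        for a, b in zip(back.sweeps, s.sweeps):
            np.testing.assert_array_equal(a.samples, b.samples)

    def test_csv_layout_duration(self, tmp_path):
        s = _sweepset(n_sweeps=3, n_samples=2000)
        write_sweepset(s, tmp_path / "x.csv", format="csv")
        back = read_sweepset(tmp_path / "x.csv")
        assert back.n_sweeps == 3
        assert back.duration_ms == pytest.approx(100.0, rel=1e-6)

    def test_missing_attribute_is_format_error(self, tmp_path):
        import h5py

        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as f:
            g = f.create_group("sweeps")
            g.create_dataset("data", data=np.zeros((2, 100)))
            # sampling_rate_hz deliberately missing
        with pytest.raises(FormatError, match="sampling_rate"):
            read_sweepset(path)

    def test_missing_sidecar_is_format_error(self, tmp_path):
        s = _sweepset()
        write_sweepset(s, tmp_path / "x.csv", format="csv")
        (tmp_path / "x.protocol.csv").unlink()
        with pytest.raises(FormatError, match="sidecar"):
            read_sweepset(tmp_path / "x.csv")
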