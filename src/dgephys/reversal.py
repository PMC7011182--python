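"""I-V curves, reversal potentials, chloride Nernst prediction and
proximal/distal synapse separation.

The reversal potential of GABA_A currents (E_GABA) is dominated by the
chloride Nernst potential, E_Cl = -(RT/F) ln([Cl]_out / [Cl]_in) for a
monovalent anion.  In whole-cell recordings the pipette imposes [Cl]_in at the
soma while distal dendrites keep near-physiological chloride, so synapses at
different distances from the soma reverse at different potentials — which is
what lets a fast proximal and a slow distal synaptic component be separated by
holding potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from dgephys.core import SweepSet, Trace, lowpass
from dgephys.psc import PSCKinetics, psc_kinetics

__all__ = [
    "IVCurve",
    "SolutionComposition",
    "ComponentPair",
    "fit_iv",
    "nernst_cl",
    "separate_components",
    "peak_current",
    "iv_from_sweepsets",
    "CL_STOICHIOMETRY",
    "ACSF",
    "HIGH_CHLORIDE_INTERNAL",
    "K_GLUCONATE_INTERNAL",
]

GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol


@dataclass(frozen=True)
class IVCurve:
    """Least-squares line through peak synaptic current vs. holding potential."""

    holdings_mv: tuple[float, ...]
    peak_currents_pa: tuple[float, ...]
    slope_ns: float
    e_rev_mv: float | None
    r_squared: float
    extrapolated: bool = False  # e_rev outside holdings +- 20 mV


# moles of chloride contributed per mole of salt
CL_STOICHIOMETRY: dict[str, int] = {
    "NaCl": 1,
    "KCl": 1,
    "choline-Cl": 1,
    "CaCl2": 2,
    "MgCl2": 2,
    # chloride-free salts commonly present
    "K-gluconate": 0,
    "NaH2PO4": 0,
    "NaHCO3": 0,
    "glucose": 0,
    "Na-ascorbate": 0,
    "Na-pyruvate": 0,
    "HEPES": 0,
    "EGTA": 0,
    "ATP-tris": 0,
    "phosphocreatine": 0,
    "kynurenic acid": 0,
}


@dataclass(frozen=True)
class SolutionComposition:
    """Salt concentrations (mM) of a recording solution, plus temperature."""

    salts_mm: dict[str, float] = field(default_factory=dict)
    temperature_c: float = 23.0

    def __post_init__(self) -> None:
        for name, conc in self.salts_mm.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {name}")

    def total_chloride_mm(self) -> float:
        total = 0.0
        for name, conc in self.salts_mm.items():
            stoich = CL_STOICHIOMETRY.get(name)
            if stoich is None:
                raise KeyError(f"unknown salt {name!r}: add it to CL_STOICHIOMETRY")
            total += conc * stoich
        return total


# Printed recording solutions (concentrations in mM).
ACSF = SolutionComposition(
    salts_mm={
        "NaCl": 125.0,
        "KCl": 2.5,
        "NaH2PO4": 2.0,
        "NaHCO3": 25.0,
        "CaCl2": 2.0,
        "MgCl2": 1.3,
        "Na-ascorbate": 1.3,
        "Na-pyruvate": 3.1,
        "glucose": 10.0,
    }
)
# Internal used to record IPSCs in granule cells (high chloride, E_GABA ~ -30 mV)
HIGH_CHLORIDE_INTERNAL = SolutionComposition(
    salts_mm={
        "K-gluconate": 110.0,
        "NaCl": 5.0,
        "KCl": 30.0,
        "MgCl2": 4.0,
        "EGTA": 0.1,
        "HEPES": 10.0,
        "ATP-tris": 4.0,
        "phosphocreatine": 10.0,
    }
)
# Internal used for interneurons / ChR2-GCs (low chloride, E_GABA ~ -70 mV)
K_GLUCONATE_INTERNAL = SolutionComposition(
    salts_mm={
        "K-gluconate": 150.0,
        "NaCl": 1.0,
        "MgCl2": 4.0,
        "EGTA": 0.1,
        "HEPES": 10.0,
        "ATP-tris": 4.0,
        "phosphocreatine": 10.0,
    }
)


def nernst_cl(
    internal: SolutionComposition, external: SolutionComposition
) -> float:
    """Chloride Nernst equilibrium potential in mV.

    E_Cl = -(RT/F) ln([Cl]_out / [Cl]_in) with z = -1; the temperature is
    taken from the internal solution (both are at bath temperature in
    practice).  The sign flips when internal and external are swapped and the
    magnitude scales linearly with absolute temperature.
    """
    cl_in = internal.total_chloride_mm()
    cl_out = external.total_chloride_mm()
    if cl_in <= 0 or cl_out <= 0:
        raise ValueError("both solutions must contain chloride")
    t_kelvin = internal.temperature_c + 273.15
    rt_over_f_mv = GAS_CONSTANT * t_kelvin / FARADAY * 1000.0
    return float(-rt_over_f_mv * np.log(cl_out / cl_in))


def fit_iv(holdings_mv, peak_currents_pa) -> IVCurve:
    """Least-squares I-V line: slope in nS (pA/mV), E_rev = -intercept/slope.

    With a near-zero slope (all currents indistinguishable from zero) the
    reversal potential is undefined and returned as None.  An E_rev more than
    20 mV outside the sampled holding range is flagged as extrapolated.
    """
    v = np.asarray(holdings_mv, dtype=float)
    i = np.asarray(peak_currents_pa, dtype=float)
    if v.size < 3 or np.unique(v).size < 3:
        raise ValueError("need at least 3 distinct holding potentials")
    res = stats.linregress(v, i)
    slope = float(res.slope)
    scale = max(float(np.max(np.abs(i))), 1e-12)
    if abs(slope) * (v.max() - v.min()) < 1e-9 * scale or slope == 0.0:
        return IVCurve(
            holdings_mv=tuple(v),
            peak_currents_pa=tuple(i),
            slope_ns=slope,
            e_rev_mv=None,
            r_squared=float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0,
            extrapolated=False,
        )
    e_rev = -float(res.intercept) / slope
    extrapolated = not (v.min() - 20.0 <= e_rev <= v.max() + 20.0)
    return IVCurve(
        holdings_mv=tuple(v),
        peak_currents_pa=tuple(i),
        slope_ns=slope,
        e_rev_mv=e_rev,
        r_squared=float(res.rvalue**2),
        extrapolated=extrapolated,
    )


@dataclass(frozen=True)
class ComponentPair:
    """Proximal (early, fast) and distal (late, slow) synaptic components."""

    proximal_iv: IVCurve
    distal_iv: IVCurve
    proximal_kinetics: PSCKinetics | None
    distal_kinetics: PSCKinetics | None
    proximal_measured_at_mv: float | None
    distal_measured_at_mv: float | None


def _window_extremum(
    mean: Trace, stim_onset_ms: float, window: tuple[float, float]
) -> float:
    """Signed extremum of the mean trace in a post-stimulus window (pA)."""
    t = mean.times_ms - stim_onset_ms
    sel = (t >= window[0]) & (t < window[1])
    seg = mean.samples[sel]
    if seg.size == 0:
        return 0.0
    return float(seg[np.argmax(np.abs(seg))])


def peak_current(
    sweepset: SweepSet,
    window_ms: tuple[float, float] = (0.0, 100.0),
    smooth_cutoff_hz: float = 250.0,
) -> float:
    """Signed peak synaptic current (pA) of one holding's average sweep.

    The average is low-pass filtered (detection band) before the extremum is
    taken, so a single noisy sample cannot masquerade as the peak — this keeps
    the I-V slope unbiased near the reversal potential where the true signal
    vanishes.
    """
    mean = sweepset.mean_trace()
    if smooth_cutoff_hz < mean.sampling_rate / 2:
        mean = lowpass(mean, smooth_cutoff_hz)
    stim = float(sweepset.protocol.onsets_ms[0])
    return _window_extremum(mean, stim, window_ms)


def iv_from_sweepsets(
    sweepsets: dict[float, SweepSet],
    window_ms: tuple[float, float] = (0.0, 100.0),
) -> IVCurve:
    """Build and fit an I-V curve from per-holding sweep sets."""
    holdings = sorted(sweepsets)
    peaks = [peak_current(sweepsets[v], window_ms) for v in holdings]
    return fit_iv(holdings, peaks)


def separate_components(
    sweepsets: dict[float, SweepSet],
    early_window_ms: tuple[float, float] = (0.0, 10.0),
    late_window_ms: tuple[float, float] = (20.0, 100.0),
    psc_class: str = "IPSC",
) -> ComponentPair:
    """Separate proximal and distal synaptic components by holding potential.

    Peak currents are measured on each holding's average sweep inside an early
    (proximal, fast-onset) and a late (distal, delayed) post-stimulus window;
    each window's currents define an I-V line whose zero crossing is that
    component's reversal potential.  Each component's kinetics are then read
    out from the sweeps held nearest the *other* component's reversal
    potential, where the alternate component is silent.
    """
    if late_window_ms[0] < early_window_ms[1]:
        raise ValueError("early and late windows must not overlap")
    holdings = sorted(sweepsets)
    if len(holdings) < 3:
        raise ValueError("need at least 3 holding potentials")
    early_peaks, late_peaks = [], []
    means: dict[float, Trace] = {}
    for v in holdings:
        s = sweepsets[v]
        stim = float(s.protocol.onsets_ms[0])
        mean = s.mean_trace()
        if 250.0 < mean.sampling_rate / 2:
            mean = lowpass(mean, 250.0)
        means[v] = mean
        early_peaks.append(_window_extremum(mean, stim, early_window_ms))
        late_peaks.append(_window_extremum(mean, stim, late_window_ms))
    proximal_iv = fit_iv(holdings, early_peaks)
    distal_iv = fit_iv(holdings, late_peaks)

    def _kinetics_at(target_mv: float | None, window: tuple[float, float]):
        if target_mv is None:
            return None, None
        v_meas = min(holdings, key=lambda v: abs(v - target_mv))
        s = sweepsets[v_meas]
        stim = float(s.protocol.onsets_ms[0])
        mean = means[v_meas]
        t_rel = mean.times_ms - stim
        sel = (t_rel >= window[0]) & (t_rel < window[1] + 100.0)
        seg = Trace(
            samples=mean.samples[sel] - float(np.median(mean.samples[t_rel < 0]))
            if np.any(t_rel < 0)
            else mean.samples[sel],
            sampling_rate=mean.sampling_rate,
            kind="voltage_clamped_current",
            t0=float(t_rel[sel][0]),
        )
        return psc_kinetics(seg, psc_class, success=1.0), v_meas

    # proximal kinetics measured while held at the distal reversal, and vice versa
    prox_kin, prox_at = _kinetics_at(distal_iv.e_rev_mv, early_window_ms)
    dist_kin, dist_at = _kinetics_at(proximal_iv.e_rev_mv, late_window_ms)
    return ComponentPair(
        proximal_iv=proximal_iv,
        distal_iv=distal_iv,
        proximal_kinetics=prox_kin,
        distal_kinetics=dist_kin,
        proximal_measured_at_mv=prox_at,
        distal_measured_at_mv=dist_at,
    )
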