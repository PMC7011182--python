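# Methods

This note documents the models, estimators and numerical choices behind
`dgephys`, and what the simulation-based validation does and does not
establish.

## Signal model and units

All in-memory signals use pA (current), mV (voltage/field), ms (time) and Hz
(rates); unit conversion happens only at I/O boundaries.  A `Trace` is one
uniformly sampled signal (10–20 kHz typical); a `SweepSet` groups repeated
stimulus-aligned sweeps under one `StimulusProtocol` and holding potential.
Recording quality control is class-specific: granule cells (GCs) require
|leak| < 100 pA and series resistance ≤ 25 MΩ, interneurons (INs) |leak| <
250 pA and ≤ 15 MΩ; thresholds are overridable per analysis.

Filtering uses 4th-order Butterworth sections applied forward-backward
(`scipy.signal.sosfiltfilt`), i.e. zero phase.  This matters because evoked
latencies (onset within 12 ms of a light pulse) must not be shifted by the
detection filter.  The noise SD that scales the detection threshold is the
standard deviation of the >500 Hz high-pass residual, computed per sweep:
per-sweep estimation is robust to slow drift between sweeps, at the cost of a
slightly noisier threshold (negligible at the sweep lengths used here).

## Event detection

Candidate events are peaks of the <250 Hz low-pass current exceeding
`k_sd` = 4 noise SDs, with peaks closer than 2 ms merged (the refractory
separation suppresses double counting of filter ripple on one synaptic
event).  Detection always runs on the polarity-flipped trace so peaks are
positive; events carry the original polarity.

Amplitude is measured on the *unfiltered* trace as the mean over a ±0.3 ms
window centered on the low-pass peak, minus a local baseline (median of the
5 ms preceding the onset; baseline and onset are refined once, since each
depends on the other).  The short window average rather than a raw maximum is
deliberate: the raw extremum near a peak rides the largest noise excursion
and overestimates amplitude by roughly two noise SDs (+16% at SNR 10 in our
recovery suite), while the windowed mean is unbiased to within 1% for
kernels with decay ≥ 5 ms.  The event onset is the latest pre-peak sample at
which the unfiltered signal is at or below 10% of the baseline-subtracted
peak ("maximum amplitude" is interpreted per event, not per sweep).

Measured performance under the synthetic conditions (biexponential kernels,
white noise): sensitivity 100% at SNR ≥ 6 for isolated events, false
positives < 0.05/s on pure noise, amplitude bias within ±5% for SNR ∈
{5, 10, 20}.

## Responsiveness: circular-shift permutation test

The observed statistic is the number of detected events whose *onset* falls
in the half-open window (stimulus, stimulus + 12 ms] over all sweeps.  The
null is built by 2000 shuffles; each shuffle applies an independent uniform
circular time shift to every sweep's event train (wrapping at the sweep
edge), which preserves per-sweep event counts and inter-event structure and
is exchangeable under the null of no stimulus coupling.  The p-value uses the
add-one estimator p = (1 + #{null ≥ obs}) / (1 + 2000), so p ≥ 1/2001 always,
and "responsive" requires strictly p < α = 0.05.  Cells with zero events get
p = 1 by definition.

Because the statistic is an integer count, the permutation test is exact but
conservative when expected counts are small: ties between the observed count
and the null discretize the attainable p-values and the realized type-I rate
falls below α (we measure ≈ 0.033–0.037 in sparse regimes, e.g. tens of
events against one 12 ms window per 2 s sweep).  The calibration benchmark
therefore uses an event-dense null (20 sweeps × 2 s, 16 stimuli per sweep,
10 Hz Poisson event rate; expected null in-window count ≈ 38), where ties are
negligible and the measured type-I rate is 0.043 ± 0.005 — a sharp check of
exactness.  Sparse regimes are only ever *more* conservative, never
anticonservative, which the unit suite asserts as an upper bound.

After classification, the first in-window event per stimulus is labeled
evoked and all others spontaneous, which caps the success probability at one
per trial; success probability is the fraction of stimulus presentations
with an evoked event.

## PSC metrics

Kinetics are measured on the average of success trials (single-trial
kinetics are available but not the default): rise 20→80% of peak for EPSCs
and 20→70% for IPSCs, decay 80→30% (EPSC) or 70→30% (IPSC), half-width as
the duration above 50%, all with linear interpolation between samples (the
closed-form checks recover τ·ln 4 and τ·ln(8/3) to ~10⁻³ sample periods).
Reported amplitude is mean-success amplitude × success probability — an
algebraic identity the suite asserts on every synthetic cell.

Train charges integrate the baseline-subtracted current over one inter-pulse
interval per pulse, using the *pre-train* baseline throughout so that
summation or depression carried across pulses is preserved.  Normalization
follows the synapse direction: IN→GC trains by pulse 1, GC→IN trains by the
last pulse; the reference ratio is exactly 1.  For 50 Hz trains whose
responses fuse, a variant integrates 340 ms from the first pulse and divides
by the peak amplitude.  Synapse counts are estimated as the ratio of the
saturating to the unitary IPSC amplitude (unitary = minimal stimulation with
≥10% failures).

## Reversal potentials and synapse localization

I-V lines are ordinary least squares on peak current vs. holding potential;
E_rev = −intercept/slope, with the peak taken as the signed extremum of the
250 Hz-filtered condition average in a post-stimulus window (filtering keeps
the I-V slope unbiased near reversal, where a raw extremum would rectify
noise).  Chloride Nernst potentials use E = −(RT/F)·ln([Cl]_out/[Cl]_in)
with stoichiometric chloride from the salt table (NaCl/KCl/choline-Cl 1,
CaCl₂/MgCl₂ 2; gluconate, phosphate, bicarbonate none) at 23 °C by default.
The two standard recording solutions give 43 mM (high-chloride internal) and
9 mM (K-gluconate internal) against 134.1 mM ACSF, predicting E_Cl ≈ −29 and
−69 mV — the somatic E_GABA and the IPSC-reversal holding potential used to
isolate EPSCs.

Proximal/distal separation measures per-holding peaks in an early (0–10 ms)
and a late (20–100 ms) post-stimulus window, fits one I-V per window, and
then reads each component's kinetics from the holding nearest the *other*
component's fitted reversal, where that component is silent.  Recovery error
grows with the kinetic overlap of the two components; with the defaults
(fast τ_decay 4 ms at −30 mV, slow τ_decay 40 ms delayed 25 ms at −65 mV)
both reversals are recovered within a fraction of a mV.

## Intrinsic properties

From the −10 mV/100 ms step: R = ΔV/ΔI_ss (steady state from the last 20% of
the step), C = Q_transient/ΔV by default (integrated charge above the steady
state; less model-dependent than a τ fit), with a single-exponential τ fit
(C = τ/R) as the alternative.  Spike threshold is the first sample of the
last contiguous run where the 1 kHz-smoothed dV/dt stays ≥ 5 mV/ms before a
peak; light smoothing stabilizes the derivative criterion without moving the
zero-phase peak.  AP peaks require ≥ 20 mV prominence and ≥ 1 ms separation
— action potentials span tens of mV, so this rejects noise wrinkles without
touching real spikes.  ISIs are peak-to-peak; the adaptation ratio is the
third ISI over the last ISI within the step.  Rheobase is the smallest
ladder current evoking ≥ 1 spike; the spiking profile is evaluated at the
available step closest to 3× rheobase.

## Field potentials

The simulated extracellular response is a negative-going fEPSP (difference
of exponentials) with a narrow positive Gaussian pop-spike riding on its
recovery phase; the pop-spike area is the generator's ground truth, scaled
by (1 − suppression) when the laser recruits inhibition.  The analyzer
measures the fEPSP slope by a linear fit over the 20–80% segment of the
initial descent, and pop-spike area as the integral of the (2 kHz zero-phase
smoothed) trace above an interpolated fEPSP envelope between the window
edges.  The envelope is a quadratic fit through 1.5 ms flanking segments
just outside the window: a straight chord systematically under-corrects the
fEPSP's curvature (5–10% area bias), and shorter flanks leave the
interpolation ill-conditioned under noise.  For repeated-trial analyses the
pop-spike window is located once on a condition average (most prominent
positive deflection and its flanking minima) and applied to every sweep,
keeping the per-sweep area estimate linear in the data and hence unbiased by
noise; the signed integral is clipped at zero only in the final report.

Laser-induced change is 100·(mean_off − mean_on)/mean_off on pop-spike
areas, per the alternating 5-on/5-off acquisition; the delay-curve analysis
reports this per laser-electrical delay ΔT (negative = laser first).  Spike
timing relative to the pop-spike peak classifies interneuron spikes as
feedforward ("before") or feedback ("after"); when transmission is blocked
and the same-sweep pop-spike vanishes, the reference peak from a control
average is passed explicitly.

## Synthetic data: scope and limits

The generators emulate the statistical structure the analyses rely on:
biexponential PSC kernels with Bernoulli failures, truncated-Gaussian
latency (mean 2 ms, SD 0.3 ms — evoked responses have short onset latency;
the exact jitter is configurable), multiplicative per-pulse train scaling,
homogeneous Poisson spontaneous events, linear superposition, white Gaussian
noise, Ohmic driving force in I-V families, single-exponential passive
steps, stereotyped AP templates, and fEPSP+pop-spike field waveforms.  The
spontaneous-event rate default (0.5–1 Hz in examples; 10 Hz in the dense
calibration regime) is a configuration choice, not an empirical claim about
granule cells.

Real recordings differ in ways the generators deliberately omit: colored
(1/f and line) noise, series-resistance and space-clamp filtering of fast
events, overlapping multiquantal events, release-dependent short-term
dynamics (no Tsodyks–Markram fitting), chloride-load dynamics during
recordings, and conductance-based spike generation.  Passing the recovery
suite therefore demonstrates that the estimators are correct and unbiased
under their stated assumptions — not that those assumptions hold in any
particular slice.

## Validation problem sizes

The benchmark battery (also run by `scripts/acceptance.py`) uses: 1000 null
cells × 2000 shuffles for calibration; 100 runs × 10 isolated events for
detector recovery at SNR 10; 100 runs × 400 trials at failure probability
0.5 for success recovery (the ±0.05 band captures ≈ 96% of runs by the exact
binomial, so the in-band fraction is expected near, and occasionally at,
0.95); 20 trains × 15 sweeps for P5/P1 recovery; 100 single-component and 30
two-component I-V families; and 40 trials per condition for the 75%
pop-spike suppression recovery.  Everything is deterministic given the seed:
each benchmark spawns independent `numpy.random.SeedSequence` sub-streams,
and identical configs reproduce byte-identical pipeline outputs.
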