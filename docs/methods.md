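# Methods

`odorpulse` analyses how olfactory-bulb projection neurons (mitral/tufted
cells, M/TCs) couple to temporally structured odour stimuli, and generates
the synthetic electrophysiology it is validated on.  This note documents
the models, the parameters that matter, the numerical choices, and what
the synthetic data does and does not emulate.

## The analysis chain

### Sniff-cycle detection (`respiration`)

Raw naris flow (inhalation = negative deflection) is high-pass filtered
(2nd-order Butterworth, 0.1 Hz corner, zero-phase with maximal reflection
padding), sign-flipped so inhalation is positive, median-subtracted and
clipped at zero.  Inhalation peaks come from `scipy.signal.find_peaks`
with relative thresholds (30% height, 25% prominence of the processed
maximum, 100 ms minimum separation), so detection is invariant to positive
rescaling of the input.  Each inhalation's onset and end are the crossings
of 5% *of that inhalation's own peak* before and after the peak — the
per-inhalation reading of the threshold rule, chosen for robustness to
slow amplitude drift.  The exhalation peak is the extremum of the
processed signal between successive inhalations; the final inhalation,
whose exhalation cannot be bounded, is dropped, so every returned cycle is
complete.  On noiseless synthetic breathing the onset error is under 5 ms
(one—four samples at 1 kHz, dominated by the 5% crossing geometry).

Respiration phase is defined on exhalation-peak-to-exhalation-peak
intervals mapped linearly to [0°, 360°), with 0° at peak exhalation.
Cycle boundaries for triggering and rate estimation use inhalation onsets.

### Stimulus metrics (`stimulus`)

*Fidelity* of a pulse train is, per pulse, (peak − trough)/(peak −
baseline), clipped to [0, 1]: 1 means the odour concentration fully
returns to baseline between pulses, ~0 means no temporal structure.
Pulse windows are one inter-onset interval; the trough is the minimum
between consecutive peaks.  Baseline is supplied by the caller (for
synthetic traces, 0; for measured traces, the median of a 500 ms
pre-trial segment is the recommended choice).  For a first-order sensor
of time constant τ driven by a square train with period T and on-time w,
the steady-state fidelity has the closed form 1 − exp(−(T − w)/τ), which
the implementation reproduces to <0.02.

The *odour-respiration convolution* estimates odour actually inhaled per
sniff: the inhalation-only flow signal (flipped, zero-clipped, zeroed
outside inhalation spans) is multiplied sample-wise with the PID trace
and summed per sniff, weighting odour by instantaneous inhaled flow.
Cross-frequency comparisons use pairwise Mann-Whitney U tests with
Bonferroni correction over the number of frequency pairs.

### Vm cleaning (`vm`)

Spike waveforms are clipped by linear interpolation over [−1, +3] ms
around each spike (overlapping windows merged).  The window covers a
somatic spike plus afterpotential onset; the operation itself is standard,
the window length is a package choice.

Sniff-locked background oscillations are removed by *phase-matched
baseline subtraction*: baseline sniff cycles are collated on a common
phase axis and averaged into a generic baseline trace, which is then
subtracted from every analysed window at each sample's respiration phase.
The template is stored as the set of per-cycle phase interpolants; its
value at a phase is the across-cycle mean of the per-cycle linear
interpolants (circular, period 360°).  A 360-bin grid summarises it for
inspection.  This representation cancels the sniff-locked component
*exactly* (machine precision) when evaluated on strictly periodic source
data — a property a fixed binned grid cannot achieve — and under noise the
per-bin template error scales as noise SD/√n_cycles.  Samples outside the
detected cycles are subtracted at the nearest covered phase and counted in
a flag.

Response metrics follow the fixed windows ΔVm = mean Vm in [onset,
onset + 500 ms) minus mean Vm in [onset − 2 s, onset) on the corrected
trace; ΔFR is the analogous rate difference on raw spike counts; PSTHs
use 50 ms bins.  Significance is a two-tailed unpaired t-test of per-trial
metrics against blank trials *at the same pulse frequency* (the same test
is applied to ΔVm and ΔFR).  Recordings with series resistance above
25 MΩ are excluded.

### The frequency-coupling coefficient (`coupling`)

For a cell-odour-frequency triple, every baseline-subtracted odour-trial
window is cross-correlated with the PID stimulus template and the peak
correlation kept (CC_odour, one per trial); blank (mineral-oil) trials
give CC_blank; then

    CpC = mean(CC_odour) / mean(CC_blank).

CpC > 1 indicates stimulus-locked coupling beyond residual
mechanical/flow artefacts.  Key numerical choices:

* **"Cross-correlation" is the Pearson correlation coefficient at each
  integer-sample lag.**  This is the single most consequential choice in
  the module: an unnormalised cross-correlation would make the CpC ratio
  depend on Vm scale, whereas the Pearson reading makes CpC invariant to
  affine rescaling of the recording.
* Lag search window ±500 ms (one full 2 Hz stimulus period); the peak is
  the maximum *signed* correlation.  Correlations are computed on the
  overlap only; lags with under 8 overlapping samples or zero variance
  are undefined.  The implementation (prefix sums + direct correlation
  for the cross term) agrees with a naive per-lag Pearson scan to 1e-12.
* Blank aggregation: each odour trial's peak is divided by the *mean* of
  the blank peaks at that frequency (blank and odour trial counts differ,
  so trial pairing is not generally possible).  A guard of 1e-3 on the
  blank aggregate flags degenerate ratios instead of letting them blow
  up; flagged triples are reported, never silently dropped.
* The reported lag is at the maximum of the across-trial *mean*
  correlation curve.  With periodic stimuli the peak lag is only defined
  modulo the stimulus period.

Significance uses a baseline-control null: the pre-onset window of every
trial (one trial-length each) is run through the identical computation
and normalised by the same blank aggregate; a two-tailed unpaired t-test
compares per-trial odour CpC values against this control distribution
(α = 0.05).  Under the zero-coupling null this test is calibrated: the
acceptance suite measures a false-positive rate of 0.05 ± 0.02 over 1000
synthetic cells.  Supporting comparisons — pulsed vs constant stimulus
(paired t), CpC against depth/R_in/RMP (Pearson), mixture prediction
(regression of CpC_mix on (CpC_A + CpC_B)/2) and pre/post-drug (paired t,
unpaired fallback flagged) — use the scipy implementations.

### Cell-type classification (`classify`)

Baseline activity of M/TCs is locked to the sniff cycle and the locking
phase predicts type: preferred phase in [0°, 160°] → putative tufted
(pTC); [190°, 350°] → putative mitral (pMC); otherwise unresolved
(boundaries inclusive; (350°, 360°) falls to unresolved).  The preferred
phase comes from a 36-bin phase profile of the spike-clipped Vm (binned
mean) or of the spiking probability, smoothed circularly over 3 bins.
The phase estimate is the argument of the first circular harmonic of the
mean-subtracted profile.  For sniff-locked (near-sinusoidal) profiles this
coincides with the profile peak, but it pools all bins: a raw argmax
carries half-bin (5°) quantisation error and local peak interpolation
amplifies per-bin noise, either of which misplaces cells whose true phase
lies near a class boundary.  The harmonic estimator recovers generator
phases to well under a bin.  Spike-based profiles additionally require a
Rayleigh test (Zar's approximation) to reject phase distributions
indistinguishable from uniform; flat Vm profiles fall back to a range
threshold.

### Unit responses and decoding (`units`, `decoding`)

Per unit and odour, blank responses are subtracted from odour responses
at the same frequency, averaged over repeats and z-scored across the five
frequencies (per-unit z-scoring); vectors are clustered hierarchically
(Euclidean, average linkage — the metric and linkage are package choices)
with optimal leaf ordering.  Frequency-discrimination screens use
Mann-Whitney U on 500 ms post-onset counts (α = 0.01 between frequencies,
α = 0.05 odour vs blank); fully tied counts yield p = 1.

The decoder is a linear support-vector classifier (scikit-learn
`LinearSVC`, C = 100) behind a `StandardScaler`: the weak margin penalty
leaves unit weightings essentially unrestricted, and standardisation
statistics are fitted on the training split only, so no test information
leaks.  Accuracy is the distribution over repeated random stratified
80/20 splits.  The shuffle control permutes labels per repetition and
stratifies the split *on the permuted labels*; stratifying on the
original labels instead leaves the permuted classes unbalanced between
the splits and biases shuffled accuracy measurably below 1/n_classes.
Features never include spikes beyond 4 s post-onset.  Single-unit
discrimination uses stratified 5-fold cross-validation (k is a package
choice), repeated with different shuffles.

## The synthetic data

The generators are phenomenological (no conductance-based modelling) and
emulate the recording conditions the analyses assume:

* **Respiration** — per-cycle templates (fast negative inhalation lobe,
  35% of the cycle; slower positive exhalation lobe, 40%; end-expiratory
  pause, 25%) with lognormal cycle-frequency jitter.  Defaults: 2.8 ±
  0.5 Hz (unit-recording animals) or 2.9 ± 1.3 Hz (whole-cell animals),
  mean ± SD.  Frequencies (not periods) are drawn with the target mean so
  the mean of 1/period matches the nominal rate.  The pause is what makes
  the median-subtraction step of detection behave as on real flow traces.
* **Stimuli** — square pulse trains at 2/5/10/15/20 Hz, 2 s duration, 50%
  duty, passed through a first-order sensor/valve stage (τ = 10 ms
  default) computed with an exact exponential integrator.  With equal
  duty and a fast sensor the total odour integral is frequency-
  independent.
* **Trials** — inhalation-triggered onsets, randomised condition order,
  ≥ 8 s inter-trial interval, blanks at every frequency.  The full unit
  design (4 odours + blank × 5 frequencies × 32 repeats) yields 800
  trials.  The emulated whole-cell design (2 odour mixtures × 2
  frequencies) uses 6 odour + 6 blank repeats per frequency by default;
  the per-condition repeat count of such recordings varies in practice,
  so this is a package choice.
* **Membrane potential** — RMP + sniff-locked oscillation peaking at the
  cell's preferred phase + per-trial odour-response envelope
  (difference of exponentials, rise 50 ms, decay 500 ms — the response
  kinetics are free parameters, not reported values) + a stimulus-coupled
  component (coupling gain × PID trace, exact at 2 and 20 Hz,
  log-interpolated between) + white Gaussian noise + stereotyped 2 ms
  triangular spike waveforms from an inhomogeneous rate process (rate =
  baseline × exp(ΔVm/5 mV), 3 ms refractory).  Blank trials carry a small
  residual mechanical coupling (0.05 mV default) standing in for the
  flow-compensation residue that blank trials exist to control for.
  The spike-free trace and all parameters are stored as ground truth.
* **Units** — thinned-Poisson spike trains with lognormal baseline rates
  (mean 11 Hz, SD 9 Hz), cosine sniff-phase modulation (depth 0.6,
  pTC-heavy phase mixture) and frequency-dependent odour-evoked rate
  changes (full effect in the first 500 ms, half thereafter); blanks
  evoke nothing.

Everything is reproducible bit-for-bit from (parameters, seed); a session
seed derives per-component seeds through `numpy` `SeedSequence` spawning.

Defaults are generated and analysed at 1 kHz rather than the 10–40 kHz
acquisition rates: all analyses involve ≤ 20 Hz content, so 1 kHz is
≥ 25× Nyquist, and every operation is sampling-rate-agnostic.

**What the synthetic data does not emulate** — correlated (pink) Vm
noise, respiration-odour mechanical interactions beyond a fixed blank
gain, bursting or adaptation in spike trains, non-sinusoidal sniff-locked
Vm shapes, electrode drift, and cross-cell correlations.  Passing the
suite therefore demonstrates correctness and calibration of the
*analyses* under the stated statistical structure, not robustness to
every pathology of in vivo recordings.

## Problem sizes in the test and acceptance runs

The validation suite uses desk-scale designs chosen once: single-odour,
single-frequency sessions with 6 + 6 trials for CpC calibration (1000
cells for the type-I check, 20 cells per point on a 0–4 mV gain grid for
monotonicity); 60 baseline-only cells for phase-classification recovery;
50-unit × 160-trial populations with 200 split repetitions for decoding
chance; 6 × 300 s traces for breathing statistics.  The acceptance script
uses the full 97-unit × 160-trial population.  Repetition counts (200 vs
1000 splits) trade runtime for standard-error-aware tolerances.

## Known limitations

* With periodic stimuli the reported peak lag is defined only modulo the
  stimulus period; comparisons of lags between cell classes inherit this
  ambiguity exactly as the underlying measure does.
* The baseline-control null reuses pre-trial windows that also feed the
  baseline template; with ≥ 30 s of dedicated baseline this overlap has
  no measurable effect on calibration (the 1000-cell check), but the two
  roles are not formally independent.
* `compare_integrals` assumes exchangeable trials within a frequency;
  animal identity is carried in the table but not modelled (no mixed
  effects), matching the original analysis.
* The pulsed-vs-constant comparison requires equal trial counts; there is
  no partial-pairing fallback.
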