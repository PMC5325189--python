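# Methods

This note documents the models, numerical choices and limitations behind
cerepulse: what the pipeline computes, what the synthetic generator
emulates, and what passing tests do and do not show about real recordings.

## Measurement model

A frequency-domain diffuse optical system samples AC light intensity per
source–detector channel at 39.0625 Hz (25.6 ms per point); lead-I EKG is
recorded at 1000 Hz.  The cardiac pressure wave distends cerebral arteries
once per beat, modulating the detected intensity by roughly 1% of the mean
channel level, with a raw single-beat pulse-to-noise ratio around 2:1.
Averaging more than 100 beats, time-locked to the EKG R wave, raises the
waveform SNR beyond 20:1 and produces one average pulse waveform per
channel.

### R-wave detection (`ekg`)

The EKG is band-passed 0.5–40 Hz with a 4th-order zero-phase Butterworth
filter (forward–backward, so the R-peak latency is not shifted), then
standardized to zero mean and unit SD — making detection invariant to any
positive gain.  Local maxima above a z-threshold (default 3.0, adjustable
per subject) and separated by a 100 ms refractory window become candidates.
Candidates producing interbeat intervals below the plausibility band
(default 0.4–2.0 s, i.e. 30–150 bpm) are removed iteratively — the
lower-amplitude peak of the offending pair is dropped — and logged with a
reason code, so accepted + rejected always reconciles with the candidate
count.  The refractory window is deliberately much shorter than the IBI
band's lower edge: its only job is deduplicating maxima within one QRS
complex, while closely spaced ectopic candidates (e.g. 150 ms after a true
beat) must reach the interval filter so they are *logged*, not silently
suppressed.  Manual overrides (add/drop) re-validate the interval
invariants and are recorded.

### Optical conditioning and epoching (`optics`)

1. **Normalization**: each channel is expressed as percent change about its
   own mean intensity ("percent change about the mean" is the chosen
   reading of intensity normalization; it makes channels with different DC
   gain directly comparable).  Channels with non-positive mean are dropped
   and logged.
2. **Artifact masking** runs on the *unfiltered* percent-change series,
   where boxcar baseline steps are still visible.  A sample is
   spike-flagged when its robust z-score (median/1.4826·MAD) exceeds 8 *and*
   its absolute deviation exceeds 5 percent-change units; the absolute floor
   exists because the robust scale of a nearly noise-free recording
   collapses until the ~1% pulse itself would look like an outlier, whereas
   genuine motion artifacts in this modality sit an order of magnitude above
   the pulse.  Epochs overlapping flagged samples, or whose mean level
   deviates from the other epochs' by more than 6 robust SDs (spread floored
   at 5% of the channel's robust sample SD), are masked.  A channel whose
   epochs are all masked raises an explicit unusable-channel signal.
   Artifact masking is an added, clearly separated stage; subject-level
   exclusion remains available for recordings that are unusable throughout.
3. **Band-pass** 0.5–5 Hz, 4th-order zero-phase Butterworth, isolating the
   cardiac band from drift and high-frequency noise.
4. **Epoch averaging**: epochs span 0–1000 ms post-R; epochs truncated by
   the next beat or the end of the recording are excluded.  Kept epochs are
   resampled onto a common post-R grid at the native 25.6 ms spacing by
   evaluating a cubic spline of the channel's full time series at
   beat-time + grid offsets, then averaged.  Cubic (not linear)
   interpolation is the package's numerical choice: the phase-averaged error
   of linear interpolation at 25.6 ms spacing is ~2% of the pulse peak for
   realistic diastolic curvatures, which would dominate the waveform
   recovery budget; the spline keeps it well below 1%.  Channels averaging
   fewer than 100 epochs are flagged, not dropped.
5. **Baselining** subtracts the waveform's mean over the fixed 128–256 ms
   post-R window (the first-peak-diastole period).  The window, not a
   detected peak, defines the baseline; the operation is exact and
   idempotent.

### Indices (`pulse`)

* **Pulse amplitude** = mean baselined percent-change over 384–538 ms, the
  window in which the systolic peak falls across subjects and regions.
  Linear in the waveform by construction.
* **Arterial compliance**: systole = argmax inside the systolic window;
  diastolic reference = minimum between the peak and a configurable search
  cap (default 900 ms post-R); ties break to the earliest sample.  The
  segment between the two is mapped onto the unit square (time and
  amplitude affine-normalized) and integrated with the trapezoid rule on
  the native grid; 0.5 is subtracted.  Values lie in [−0.5, +0.5] whenever
  the normalized segment stays inside [0, 1]; noisy segments exiting that
  range are integrated as-is but QC-flagged, and aggregates exclude flagged
  units by default.  Degenerate waveforms (flat, or inverted so the
  systolic value does not exceed the diastolic one) yield NaN with a QC
  flag rather than aborting the subject.
* **Aggregation**: unweighted mean over QC-passing units inside an ROI,
  computed per-unit first and then averaged (voxel-level-then-average,
  rather than averaging waveforms first).

### Geometry and ROIs (`spatial`)

Channels are source–detector pairs; only separations in the closed interval
[2, 6] cm are analyzed (shorter pairs see scalp, longer pairs detect too
little light).  A channel's representative location is the source–detector
midpoint — the standard banana-path heuristic, standing in for out-of-scope
diffusion-path modeling.  Standard-space (Talairach) X/Y coordinates come
from an affine placement declared in the geometry file; no MRI
co-registration is performed, and depth (Z) is ignored for box-ROI
membership since the global ROI is specified by X/Y ranges only.  The
global ROI is the axial box X ∈ [−45, 45], Y ∈ [−80, 50]; regional ROIs are
Brodmann-area label sets consumed from the geometry file (frontoparietal =
{BA9, BA7}, visual = {BA17, BA18}).  Surface maps are rendered by
inverse-distance-weighted interpolation with an influence radius — a
simplified projection, not a tomographic reconstruction.

### Statistics (`stats`)

* **eCRF**: a weighted linear combination of gender, age, BMI, resting
  heart rate and a physical-activity category plus a constant, in METs.
  The default weights implement the Jurca et al. (2005) non-exercise
  estimation equation (constant 18.07; male +2.77; age −0.10/yr; BMI −0.17;
  resting HR −0.03/bpm; activity-category points 0, 0.32, 1.06, 1.76,
  3.03); they are configuration data, not code.  Gender is residualized out
  of eCRF analyses.
* **Outlier exclusion**: single-pass standardization against the sample
  mean/SD, excluding |Z| > 2.5; no re-standardization after removal; a
  zero-SD sample excludes nothing.
* **Partial correlation**: both variables are residualized on the
  covariates plus intercept by least squares and the residuals correlated;
  df = n − 2 − k.  With no covariates this reduces exactly to Pearson.  A
  variable that is an exact linear function of the covariates leaves a
  numerically zero residual; its partial correlation is defined as 0.
* **Residual-variance (heteroscedasticity) test**: regress y on x, square
  the standardized residuals, correlate with x; a positive estimate means
  the spread of y grows with x.  One-tailed p-values follow the declared
  direction; p_one = p_two/2 when the estimate is in the hypothesized
  direction.
* **Mediation**: simple (single-mediator) model fit by OLS — a-path
  (mediator on predictor) and b-path (outcome on mediator controlling the
  predictor) — with the indirect effect a·b and a percentile bootstrap CI
  (default 5000 resamples, seeded; percentile rather than bias-corrected,
  configurable).  Covariates, when given, are residualized out of all three
  variables first.  Calibration caveat: under the *double* null
  (a = b = 0) the percentile CI of a·b is well known to be conservative
  (coverage well above 95%); the suite therefore checks ~95% coverage under
  the single-path null (a = 0 with a nonzero b), where the interval behaves
  regularly.
* **Analysis runner**: a declared plan (YAML) lists analyses with columns,
  covariates, tail and outlier rules; every exclusion and covariate is
  recorded in the tidy results table.  Missingness is handled per analysis
  (complete cases).  No multiple-comparison correction is applied by
  default.

## Synthetic cohort generator (`synthcohort`)

The generator is first-class, tested code; its defaults are the study
conditions the pipeline targets (360 s recordings, 39.0625 Hz optical,
1000 Hz EKG, resting heart rate 60 bpm with 5% lognormal interbeat
variability clipped to 0.4–2.0 s).

**Pulse kernel.**  Built on a 1 kHz internal grid: zero until the rise
onset, half-cosine rise (180 ms) to the systolic peak at 450 ms post-R (so
the peak falls inside the 384–538 ms window), a parametric diastolic decay
to a trough at 800 ms, then a small end-diastolic recovery (half-cosine to
a 0.06 plateau, tapering to zero at the end of the beat) so the diastolic
minimum is an isolated, well-conditioned trough.  The decay family maps
stiffness s ∈ [0, 1] to an exponential rate k = 7·|2s − 1|: s = 0.5 gives a
straight line (compliance 0), s > 0.5 the convex drop
(e^(−ku) − e^(−k))/(1 − e^(−k)), s < 0.5 its concave mirror.  The kernel is
convolved with a 41 ms Hann window so it is smooth enough for spline
resampling, and its peak renormalized to 1.  The curvature limit and
smoothing width were chosen together so that (a) the stored ground-truth
compliance spans beyond ±0.3 and brackets 0 monotonically, and (b) the
noiseless pipeline recovers the kernel to < 1% of peak and its compliance
to ≈ 0.01.  Ground-truth compliance and peak time are computed from the
smoothed kernel on the fine grid with the same peak/minimum/normalization
definitions the pipeline uses.

**Signals.**  Each channel carries its region group's kernel at every beat
time, scaled by the subject's pulse-pressure amplitude (default 1% of mean
intensity, growing 0.008%/yr with age), riding on a per-channel DC level
(800–1200 a.u.) with a slow sinusoidal drift (1%, 0.08 Hz), white noise
(0.5% — raw pulse SNR ≈ 2:1, so averaging ~150 epochs lands above 20:1),
and motion artifacts in declared windows (boxcar steps of 10% plus 25%
spikes; two 2 s windows per recording by default).  The EKG places a
QRS-like template (R peak exactly at the beat time) plus a T-wave bump,
baseline wander and noise; ectopic-beat injection (a 0.7-amplitude
template 150 ms after a host beat) is opt-in and labeled.

**Cohort.**  Ages are drawn evenly across the six decades of 18–77 (8 per
decade at n = 48).  Subject stiffness is 0.5 + 0.35·z_age − 0.10·z_activity
plus N(0, 0.05) noise, clipped to [0.02, 0.98]; activity is drawn
independently of age so that switching the age→stiffness slope off really
nulls the age association.  Regional scaling multiplies the stiffness
deviation from 0.5 by 1.25 (frontoparietal), 1.0 (other) and 0.25 (visual),
emulating faster frontoparietal vascular aging.  Covariates include BMI,
resting HR, blood pressures (pulse pressure = systolic − diastolic by
construction), eTIV and volume columns shrinking with age, an eCRF column
computed by the package's own equation, and cognition scores wired to the
truth (OSPAN falls with frontoparietal stiffness; WCST error counts rise
with global stiffness).  Per-subject randomness comes from independent
spawns of a single seed sequence, so any prefix of the cohort is
reproducible bit-for-bit; HDF5 outputs disable dataset timestamps so
identical runs are byte-identical.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: photon transport and partial-volume effects,
two-wavelength chromophore separation, realistic EKG morphology beyond peak
placement, physiological waveform variability (dicrotic notch, respiratory
modulation), subject-specific optode coupling drift, and any spatial
correlation structure of noise across channels.  Recovery results on the
synthetic cohort bound the *algorithmic* error of the chain, not the
physiological validity of the indices.

## Problem sizes in the verification suite

The acceptance checks scale the study conditions to desk size as the
package's own choice: noiseless recovery uses 10 subjects × 240 s (so over
100 epochs survive the next-beat exclusion at 60 bpm); detection quality
uses one 360 s subject (≈ 360 beats); stiffness recovery uses 50 subjects
at the full 360 s default-noise conditions; mediation coverage uses 500
simulations × 1000 bootstrap resamples at n = 200; the oracle-equivalence
check randomizes 1000 monotone decays with curvature up to k = 5 (the
curvature producing the ±0.3 span in closed form).  The whole suite runs in
well under a minute on one core.

## Known limitations

* The diastolic reference is a minimum search, not a physiological
  peak-diastole detector; on waveforms with long flat diastolic tails its
  position is intrinsically ill-conditioned (the generator avoids this by
  construction; real data may not).
* Compliance on the native 25.6 ms grid carries a trapezoid discretization
  error up to ~0.005 for strongly curved decays; a 10×-oversampled oracle
  bounds it in the suite.
* Band-pass filtering (0.5–5 Hz) systematically smooths the waveform and
  compresses compliance toward zero; rank ordering across subjects is
  preserved (Spearman ≈ −0.98 against injected stiffness), but absolute
  compliance values are pipeline-specific and should only be compared
  within a fixed configuration.
* The eCRF weights are population-calibrated external constants; treat the
  column as an estimate, not a measurement.
* The mediation CI is percentile-based; bias-corrected variants differ in
  small samples.
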