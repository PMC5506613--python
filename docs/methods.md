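# Methods

`eitsbt` implements the offline analysis of electrical impedance tomography
(EIT) recordings acquired around a spontaneous breathing trial (SBT): a
baseline on pressure support (t0), the end of a T-piece trial (t1), and the
return to pressure support (t2).  The input is a reconstructed movie of
relative impedance on a 32×32 pixel grid (row 0 ventral); the output is a
set of ventilation indices per session and, at cohort level, a ROC analysis
of the baseline global inhomogeneity index (GI) against subsequent
ventilatory deterioration.  Because bedside recordings of this kind are not
publicly available, the package ships a synthetic thorax phantom and a
virtual-cohort generator whose ground truth is known analytically; every
pipeline stage is validated by oracle equivalence or parameter recovery.

## Signal model and preprocessing

A recording is a uniform-rate stack of frames (arbitrary impedance units,
AU).  Cardiac-frequency content is removed with a low-pass filter at
50 min⁻¹, realized as a forward–backward Butterworth filter (default order
4): the double pass squares the magnitude response, has exactly zero phase
(breath landmarks do not move), and unit DC gain.  By default the filter is
applied to every pixel trace, so tidal images and regional delay maps are
computed from filtered signals as well; a curve-only mode is available
(`pixelwise_filter: false`) because it is unknown whether vendor tools
filter pixel-wise or globally.

The *global curve* is the per-frame sum of impedance over the analysis
mask.  Breaths are segmented on this curve: end-expirations are local
minima, end-inspiration is the maximum between consecutive minima.  Extrema
must reach a prominence of 10% of the curve's median peak-to-trough
excursion (suppresses noise-born wiggles); partial breaths at the edges are
discarded; breaths with outlying duration (outside 0.4–1.75× the median) or
amplitude (<0.5× the median) are flagged as artifacts; and the longest run
of consecutive clean breaths — earliest on ties — is selected.  A session
must provide at least 10 selected breaths or it is rejected.  The
respiratory rate is 60 over the mean selected breath duration.

## Index definitions

With selected breaths `(s, ei, ee)` (start end-expiration, end-inspiration,
end end-expiration):

* **Tidal image** `DI_xy`: frame(ei) − frame(s) per pixel, averaged over
  selected breaths.
* **Lung mask**: per-pixel maximum DI over all sessions of the study
  (maximum ventilated extent), thresholded at 20% of the global maximum,
  boundary inclusive.  The 20% fraction is a common functional-EIT
  convention; it is configurable.
* **TIV**: mean over selected breaths of the global-curve swing
  (end-inspiration minus breath-start end-expiration); expressed as % of the
  t0 session (= 100% by definition).
* **ΔEELI**: mean global-curve value at the selected end-expiration minima,
  minus the t0 value, divided by the t0 TIV (×100).  Impedance offsets are
  not comparable across sessions in absolute terms, so normalizing by the
  baseline tidal swing makes −65% read as "a loss of 0.65 baseline tidal
  swings".  The raw AU value is also emitted.
* **IR / IR_adapt**: ventral over dorsal tidal impedance,
  (ΣROI1+ΣROI2)/(ΣROI3+ΣROI4), with four horizontal bands.  Static bands
  are grid-row quartiles; adapted bands split the ventilated row extent of
  the shared lung mask into four equal-height bands, remainder rows assigned
  dorsally (a stable, documented rule).
* **GI**: Σ|DI_xy − median(DI_lung)| / Σ DI_xy over lung-mask pixels, with
  the median likewise over lung pixels only.  The raw value is ~0–1; the
  conventional reporting scale multiplies by 100, and both are emitted.
* **spRVD**: for each selected breath and lung pixel, the delay from the
  breath-start global minimum to the pixel's impedance rise reaching a
  threshold (40/60/80%) of that pixel's tidal amplitude, as a percentage of
  the global inspiration duration, clamped to [0, 100].  Crossing times are
  linearly interpolated between samples; a pixel's own end-expiration may
  precede the global minimum, so the per-pixel baseline is searched in a
  look-back window of a quarter breath.  Pixels that never reach the
  threshold are set to 100 and counted.  Across pixels the map is
  summarized by its standard deviation (the heterogeneity reading; default)
  and mean, both averaged over breaths and both emitted.
* **RSBI_EIT**: respiratory rate divided by normalized TIV (TIV%/100).
  This direction makes the index rise under rapid shallow breathing
  (higher rate, smaller swings), matching its clinical interpretation.

### Identifiability of spRVD

Only the *relative* structure of a delay field is observable.  A recording
in which every pixel is delayed by the same τ is sample-for-sample identical
to an undelayed recording started τ later, so no estimator can recover the
absolute offset; what the formula yields for a spatially uniform field is
the waveform's own threshold-crossing time (for the raised-cosine
inspiration, arccos(1−2q)/π of the inspiration time at threshold fraction
q).  The across-pixel SD and any between-region delay differences are
unaffected by this offset and are recovered to well under one percentage
point on noise-free phantoms.  This is why the SD is the default summary.

## Outcome labelling and ROC

Ventilatory deterioration is a tidal-volume decrease of at least 20 ml
(inclusive) between t0 and t2; smaller differences are treated as
measurement noise.  The ROC of baseline GI against this label uses an
explicit threshold sweep: candidate cutoffs are midpoints between sorted
distinct scores plus ±∞, the rule is score > cutoff (high GI predicts
deterioration; the direction is fixed, never auto-flipped), and the AUC is
the Mann–Whitney U statistic normalized by n_pos·n_neg with ties counting
½.  The sweep and the rank statistic are equal by construction; tests assert
the equality against exhaustive pair counting and an independent library
implementation.  Operating points at arbitrary cutoffs return exact
confusion counts.  Cohort tables report median and interquartile range
(linear-interpolation quantiles) per index and time point, optionally split
by outcome; a natural-log GI column can be added (the transformation
conventionally applied before parametric testing).  Omnibus testing across
the three time points is deliberately out of scope — the per-session tables
are emitted for use with any statistics package.

## Synthetic phantom

Each lung pixel oscillates as `A_xy · w(t − τ_xy)` where `w` is a periodic
raised-cosine breath waveform rising 0→1 over the inspiration fraction of
the cycle and returning to 0 over the remainder.  Amplitudes are non-zero
only inside two elliptical lung fields.  End-expiratory level (EELI)
offsets, piecewise-constant per breath, and a cardiogenic sinusoid (default
90 min⁻¹, above the filter cutoff) are distributed over lung pixels in
proportion to amplitude, so they appear on the lung-masked global curve
with exactly the programmed AU amplitude.  Gaussian pixel noise is added
last.  Ground truth (analytic TIV from a dense evaluation of the noiseless
superposition over one period, the analytic tidal map and its GI and IR,
the programmed delay-fraction map, the EELI trajectory) is computed from
the parameters, never from the rendered movie.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| grid | 32×32 | the device class's reconstruction grid |
| sampling rate | 20 Hz | typical frame rate of the device class |
| duration | 45 s | ≥12 full breaths at all simulated rates |
| respiratory rate | 23.5 min⁻¹ | reported cohort baseline |
| inspiration fraction | 0.5 | see below |
| cardiac rate / amplitude | 90 min⁻¹ / 5% of the global swing | above the 50 min⁻¹ cutoff by design |
| pixel noise SD | 5% of mean lung amplitude | recovery under noise is tested at this level |

The symmetric cycle (inspiration fraction 0.5) makes each breath a pure
sinusoid at the respiratory fundamental.  An asymmetric cycle (e.g. 0.4)
places its second harmonic at twice the breathing rate, which for T-piece
rates (26 min⁻¹ → 52 min⁻¹) lands essentially at the 50 min⁻¹ cutoff: the
mandated filter then truncates real respiratory content and tidal
amplitudes are distorted by a fraction of a percent in a rate-dependent
way.  The symmetric default keeps the phantom's spectrum inside the
passband so that amplitude recovery isolates the pipeline's own behaviour;
the remaining ~0.2% passband droop at 26 min⁻¹ is inherent to the
prescribed filter and visible in recovered TIV% as a ≈0.2-point deficit.

## Virtual cohort

A cohort draws, per patient: a latent deterioration label
(Bernoulli, default 13/31); baseline GI from a group-conditional lognormal
(non-deteriorating median 43, log-SD 0.55; the deteriorating group's
log-mean is offset so the binormal-on-log-scale AUC is exactly 0.73 — AUC
is invariant under the monotone exponential, so the closed form is exact
for GI itself); tidal volumes from group-conditional normal models
(baselines 531/425 ml, changes −57/+55 ml, SDs 20–60 ml) chosen so realized
labels (≥20 ml drop) agree with the latent group in ≈98.6% of draws; a
baseline respiratory rate N(23.5, 3) clipped to ≥17 min⁻¹ (so 45 s always
covers 12 breaths); and a per-patient amplitude scale (lognormal, σ=0.2).

Session effects transform t0 into t1 and t2: TIV factor 0.72 / 0.99, EELI
shift −0.65 / −0.01 baseline tidal swings, rate increment +2.5 / +0.5
min⁻¹, GI factor 1.37 / 0.96 (with mild lognormal jitter), and delay-spread
factor 1.35 / 1.01 — all taken from the reported cohort's session medians
and means.  Regional delays form a linear ventral→dorsal ramp over the
ventilated rows; over elliptical lungs the row weighting is semicircular,
so the across-pixel delay SD is ¼ of the ramp range, and the default range
of 0.50 inspiration times targets a baseline spRVD SD near 12.5.

Two constructions deserve note:

* **GI targeting.** The amplitude map realizes a target raw GI by raising a
  fixed 30% subset of lung pixels (drawn once per patient, so the mask is
  stable across sessions) to amplitude h with GI = f(h−1)/(1+f(h−1)).  The
  map is then renormalized to a fixed mean lung amplitude so the GI target
  and the TIV factor act independently.  A 20%-of-max lung mask imposes a
  ceiling: once the hot/cold ratio exceeds 5, poorly ventilated pixels
  leave the mask and measured GI collapses rather than saturates.  Movie
  targets are therefore clipped to raw GI ∈ [0.03, 0.50] (ratio ≤ 4.33,
  cold pixels at 23% of maximum).  The *drawn* scores remain the cohort's
  canonical baseline GI; movie-level GI saturates near 50–55 for patients
  drawn above the ceiling, which compresses the top of the movie-level ROC.
  This mask-threshold ceiling is a genuine property of threshold-masked GI,
  not an artifact of the phantom.
* **TIV calibration.** Widening the delay spread at t1 desynchronizes
  pixels and shrinks the global swing below the amplitude factor (an
  envelope effect of averaging phase-shifted waveforms).  Session amplitude
  maps are therefore calibrated against the analytic global swing so that
  the *analytic* t1 TIV is exactly 0.72 of t0; the pipeline then recovers
  72% up to filter droop and sampling quantization.

## What the phantom does and does not emulate

It reproduces the features the indices respond to: spatial amplitude
structure over two lung fields, regional inspiratory delays, breath-to-breath
EELI shifts, cardiogenic oscillation above the filter cutoff, and white
pixel noise.  It does not emulate electrode-level physics or reconstruction
artifacts, breath-to-breath variability of rate and depth, body-position
changes, non-stationary noise, or motion/suction artifacts.  Consequently,
passing recovery tests shows the *analysis* is correct under the stated
signal model; it does not certify behaviour on pathological real-world
recordings, where the artifact-screening rules (prominence threshold,
duration/amplitude outlier flags) would carry much more weight.

## Numerical choices and degenerate inputs

Extrema are detected on integer samples; RVD threshold crossings are
interpolated linearly between samples (at 20 Hz a sample is 2.5% of a 2 s
inspiration, so interpolation matters at the stated tolerances).  Breath
extrema falling between samples bias tidal amplitudes by <0.1% at the
default rates.  Quantiles use linear interpolation.  Division contracts are
explicit: an empty mask, a non-positive lung DI sum, a zero dorsal sum, a
non-positive tidal swing, single-class ROC labels, and cutoffs at/above
Nyquist all raise errors naming the violated quantity.  Sessions other than
t0 require baseline references and fail loudly without them.  All
randomness flows from explicit integer seeds through `numpy` generators;
two runs with equal configuration are bit-identical, and every CSV the
pipeline writes carries the configuration hash and seed.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run phantoms of 45–60 s at 20 Hz
on the 32×32 grid, a movie-level cohort of 31 patients × 3 sessions, and a
score-level Monte-Carlo cohort of 2000 patients (movies are not rendered at
that size; the ROC check concerns the generator's score model, for which
the movie stage is irrelevant).  These sizes keep the full suite under a
minute while leaving every estimate's sampling error well inside the
asserted tolerances.

## Known limitations

* Movie-level GI saturates near the mask-threshold ceiling (above), so
  cohort GI means are lower than the drawn-score means and the movie-level
  AUC at n=31 is mildly attenuated relative to the score-level value.
* The spRVD mean carries the waveform threshold-crossing offset (see
  identifiability); comparisons between patients or sessions are meaningful
  for the SD and for differences, not for the absolute mean.
* ΔEELI recovery in the cohort carries a ≈1% bias from session-to-session
  changes of the delay-mixture trough (the global minimum of a sum of
  phase-shifted waveforms moves with the spread).
* No absolute volume calibration (AU → ml), no confidence intervals on the
  ROC, no multivariable prediction — out of scope by design.
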