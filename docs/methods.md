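# Methods

## Problem and approach

Coarctation of the aorta (COA) narrows the aorta distal to the vessels
supplying the head and arms. Lower-extremity perfusion is therefore
obstructed while upper-extremity perfusion is not, and the obstruction
leaves a measurable imprint on the optical pulse waveform (PPG) a pulse
oximeter already records: diastolic run-off distal to the narrowing is
prolonged, flattening the falling limb of lower-extremity beats. The
package quantifies this with four slope features per beat, compares
upper and lower extremities within each newborn, and screens for COA
with a linear discriminant on the two fall-slope summaries.

The processing chain is:

1. **Session assembly.** Only continuous single-site recordings of at
   least 1 h are analysed; after each documented probe-site change a
   30-min grace period is discarded, because charting of the change
   time is imprecise. Both durations are configurable.
2. **Resampling and filtering.** 250 Hz recordings are decimated to the
   125 Hz analysis rate (polyphase, anti-aliased). A zero-phase
   4th-order Butterworth band-pass at 0.5–8 Hz removes baseline wander
   and broadband noise. Zero-phase (forward–backward) application
   matters here: a causal filter would delay rising and falling limbs
   differently and bias the rise/fall slope features asymmetrically.
3. **Segment selection.** A 60-s window slides along each session in
   10-s steps. Within a window, beats are delineated as
   trough–peak–trough triplets (local minima with prominence ≥ 0.2 ×
   the window's interquartile amplitude; beat periods restricted to
   0.25–1.0 s, the plausible neonatal band). A signal quality index
   (SQI) gates admission: every beat is linearly time-warped to the
   median beat length and Pearson-correlated with the mean-beat
   template (computed twice, excluding beats below the 0.8 correlation
   threshold from the second template so artifacts cannot contaminate
   it); the SQI is the fraction of beats with correlation ≥ 0.8.
   Windows with SQI ≥ 0.90 are accepted greedily and non-overlapping,
   so no beat enters the medians twice.
4. **Features.** Each beat is rescaled to trough 0, peak 1, making all
   features independent of device gain and offset. ARR/ARF are the
   chord slopes between the 20% and 80% amplitude crossings of the
   upslope/downslope (crossing times linearly interpolated between
   samples). MRR/MRF are the extreme endpoint slopes over all 40-ms
   windows slid one sample at a time (5 samples at 125 Hz). Raw slopes
   (normalised amplitude/s) are divided by the beat's instantaneous
   heart rate (beats/s), giving normalised amplitude per cardiac
   cycle; division removes the near-linear heart-rate dependence of the
   raw slopes exactly for self-similar beats. Beats whose falling limb
   never reaches the 20% level (high dicrotic plateau) are excluded,
   not imputed.
5. **Aggregation.** Median of per-beat values within each segment, then
   median of segment medians per site (midpoint convention at both
   levels), so a single noisy segment cannot dominate a site summary.
   Per patient and phase the table carries the eight site medians and
   the four upper-minus-lower deltas; a patient missing one site keeps
   the present site's values with missing deltas and is excluded only
   from analyses that need the absent site.
6. **Inference.** All twelve features are compared with the two-sided
   Wilcoxon rank-sum test (exact null distribution when the combined
   n ≤ 20 without ties, otherwise normal approximation with tie and
   continuity corrections) for pre-operative COA vs control and
   post-operative COA vs control; the four deltas are compared pre- vs
   post-operatively within COA patients. Significance is flagged at
   0.01 for the pre-operative contrast and 0.05 for the others, with no
   multiplicity correction by default (a Benjamini–Hochberg flag
   exists). Screening fits a two-class LDA (pooled covariance, equal
   priors) on (MRF_upper, MRF_lower), evaluated by leave-one-out
   cross-validation with one fold per patient; pooled fold scores give
   the ROC, whose trapezoidal area equals the normalised Mann–Whitney
   U. The suggested operating point maximises sensitivity subject to
   specificity ≥ 0.90 — in newborn screening a false positive triggers
   an echocardiogram, so a low false-positive rate is preferred even at
   some cost in sensitivity.

## Synthetic cohorts

Clinical neonatal waveforms for this problem are restricted, so the
package ships a generator that every stage is tested against.

**Beat model.** A raised-cosine upstroke over a fixed fraction of the
beat period (default 0.30), then an exponential decay with time
constant τ (default 0.15 s), baseline-anchored so the beat lands at
exactly 0 at the next trough — the anchor is an affine image of the
exponential, and per-beat normalisation makes slope features affine
invariant, but without it the truncated exponential leaves a step at
each beat boundary whose height grows with τ and corrupts the
maximum-fall features. A Gaussian dicrotic bump (default 12% of
systolic amplitude, width 10% of diastole) rides on the decay, centred
mid-diastole *relative to end-of-systole*; anchoring it to the beat
start instead would let a lengthened upstroke slide the bump's falling
side onto the steep post-peak decay and reverse the severity effect.

**Severity.** One knob `s ≥ 0` acts on lower-extremity beats only:
τ → τ(1+s) (slowed diastolic run-off, the "diastolic tailing"
physiology) and upstroke slope → slope/(1+0.1s). The systolic leak is
kept an order weaker than the diastolic effect deliberately: obstruction
chiefly limits run-off, and a stronger systolic coupling would make the
rise-slope deltas separate the groups as strongly as the fall-slope
deltas, which is not the clinical pattern this generator exists to
emulate. |MRF| of lower-extremity beats is monotonically decreasing in
`s`; upper-extremity beats are unaffected, and `s = 0` makes the two
sites statistically exchangeable.

**Records and cohorts.** Beats are concatenated with per-beat heart
rate drawn from N(140, 15) bpm (clipped to 90–220); sinusoidal baseline
wander at 0.2 Hz (30% of pulse amplitude, below the filter's high-pass
edge), white noise (2% of amplitude) and Poisson-placed clipped-noise
artifacts of 0.5–2 s (default 1/min) are added. Morphology varies
log-normally between patients (CV 0.10 on both τ and upstroke rate,
shared by a patient's two sites) and between sites (CV 0.025 on τ,
0.10 on upstroke rate): run-off is a property of the central
circulation and is tightly shared within a patient, while upstroke
steepness depends on local probe coupling and vasomotor tone and varies
more site to site. This variance structure is what makes the
upper-minus-lower MRF delta a low-variance screening signal, mirroring
the within-patient referencing idea of the screen itself. A cohort
consists of `n_coa` patients with pre-operative (severity s) and
post-operative (severity 0) sessions at both sites, plus `n_control`
patients with one session at both sites.

**Severity calibration.** The clinical effect size is not identifiable
from published summary statistics, so the default severity was
calibrated once against the generator's default variability: sweeping
s ∈ {0.15, 0.20, 0.25} over 30 replicate 18+18 cohorts, s* = 0.20 is
the smallest value at which the pre-operative ∆MRF contrast is
significant at α = 0.01 in every replicate while the ∆MRR contrast
stays non-significant in ~97% of them. The value is frozen as
`SEVERITY_STAR` and used as the `CohortConfig` default.

**What the generator does not emulate.** Real neonatal PPG has
respiration-locked amplitude modulation, slow vasomotor oscillations,
probe-repositioning transients, arrhythmic beats, and device-specific
transfer functions; motion artifacts are bursty and autocorrelated
rather than Poisson. Passing tests therefore demonstrate that the
pipeline recovers a known lower-extremity fall-slope deficit under
plausible noise — not that the screen reaches any particular
sensitivity on clinical data.

## Replicate study conditions

Replicate studies (null calibration, signature recovery, the acceptance
script) use 18+18 cohorts with 60-s artifact-free records per site —
exactly one clean segment per session, the unit on which all features
are defined — with the session-duration gate set to the record length.
Hundreds of such cohorts run on one CPU in minutes; the 1-h duration
gate, grace-period trimming and artifact/SQI rejection paths are
exercised by dedicated tests on long and corrupted records instead.

## Numerical choices and edge cases

- Records shorter than ten periods of the high-pass corner
  (10/(2π·0.5) ≈ 3.2 s) are refused rather than filtered.
- Crossing times are interpolated linearly between samples; at 125 Hz
  this bounds the crossing-time error by one sample interval (8 ms)
  and far less on steep limbs.
- The 40-ms window uses the endpoint difference, not an in-window
  regression: "slope over a window" is read literally, and the endpoint
  form makes piecewise-linear test cases exact.
- Because the MRR/MRF window is fixed in absolute time, these features
  are exactly heart-rate invariant only for piecewise-linear beats; for
  curved beats the window-curvature interaction drifts MRF by up to
  ~10% across 100–180 bpm at the neonatal decay constant. ARR/ARF are
  invariant to ≪1% regardless.
- A second pass of the band-pass filter shifts the slope features by
  ~3% (they read pulse harmonics near the 8 Hz edge), so preprocessing
  is feature-stable but not sample-idempotent.
- Two consecutive beats share one boundary sample; in the normalised
  segment it is written on the later beat's scale. Feature extraction
  re-normalises each beat slice exactly, so the overlap never reaches
  the features.
- Ties in the rank-sum test fall back to the tie-corrected normal
  approximation; two samples with all values identical give p = 1.
- A singular pooled covariance in the LDA is ridge-regularised with
  10⁻⁶ on the diagonal, with a warning.
- Under the null, pooled LOOCV decision scores are slightly
  *anticorrelated* with the labels — holding out a patient shifts the
  training class means away from that patient — so the null AUROC
  distribution centres a little below 0.5 (≈ 0.45 at 18+18). This is
  the well-known pessimistic bias of leave-one-out pooling, not a
  defect of the ROC construction; the calibration test bounds the
  deviation at 0.05.
- Quantiles use linear interpolation; medians use the midpoint
  convention.

## Known limitations

- The SQI is a template-correlation stand-in for the published lineage
  of PPG quality indices; the 0.8 correlation threshold and the 90%
  gate are configurable.
- The severity knob is phenomenological; it is not a hemodynamic model
  of the aorta, and the severity scale has no units of pressure
  gradient or lumen diameter.
- The pre- vs post-operative contrast uses the rank-sum test on the
  deltas (matching the study design it mirrors), not the signed-rank
  test a paired design would ordinarily suggest.
- Whether the clinical pipeline searched the 40-ms window over the
  whole beat or per limb is ambiguous; whole-beat search is used, which
  coincides with limb-restricted search for physiological beats.
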