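# Methods

`capcri` detects the cyclic alternating pattern (CAP) of NREM sleep and
screens for insomnia and narcolepsy using only cardiorespiratory signals:
ECG-derived RR intervals, respiration, and chest acceleration.  This note
documents the model, the numerical choices, the synthetic-data generator,
and what the shipped tests do and do not establish.

## Signal model and preprocessing

Respiratory sinus arrhythmia (RSA) — the modulation of heart rate by
breathing — is treated as a directed interaction from respiration to the
RR-interval series.  Preprocessing:

* **Respiration quality.** A segment is usable when the fraction of its
  Welch power-spectral-density mass inside the respiratory band
  (0.03–0.5 Hz) exceeds `Q > 0.85`.  Q is amplitude-invariant and is the
  gate applied to every 120-s analysis window.  The Welch estimate uses
  Hann tapers, segments of min(60 s, signal length), 50 % overlap.
* **RR artifact gate.** An interval is flagged when
  `|RRI_i − mean| ≥ 1.5·Std(RRI)` on the current analysis segment, or when
  it lies outside `(0.7, 1.3)` times the last *accepted* interval (so a
  single ectopic beat does not condemn its normal successor).  `Std` is
  estimated robustly as `1.4826·MAD`: a scale estimate dragged by the very
  artifacts the gate is meant to catch would either miss them (inflated by
  a large ectopic) or, when re-applied after repair, flag progressively
  more of the clean signal (each pass shrinks a non-robust Std, which
  cascades on flat-topped physiological oscillations).  With the robust
  scale, repair-and-re-check converges immediately and `clean_rr` is
  idempotent.  Flagged intervals are replaced by monotone piecewise-cubic
  interpolation from their valid neighbours.
* **Denoising.** Baseline drift is removed by zeroing the approximation
  band of a db4 discrete wavelet decomposition (level chosen so the
  approximation lies below the low cut), followed by a zero-phase
  4th-order Butterworth band-pass — (0.03, 0.5) Hz for respiration,
  (0.5, 40) Hz for ECG.
* **Beat detection.** Derivative–square–moving-window-integration with an
  adaptive threshold and local refinement on the band-passed ECG; rates
  outside 30–200 bpm raise a warning.

## Cardiopulmonary resonance indices

Within each 120-s window (10-s steps) the cleaned tachogram is resampled
to an evenly sampled instantaneous-RR series at 4 Hz (cubic spline through
interval midpoints; T = 480 samples), and respiration — band-passed to
0.03–0.5 Hz first, since out-of-band measurement noise otherwise caps the
causality of strongly coupled windows — is interpolated onto the same
grid.  A bivariate AR model

    RRI(t) = Σ_j A11_j·RRI(t−j) + Σ_j A12_j·RSP(t−j) + ε1(t)
    RSP(t) = Σ_j A21_j·RRI(t−j) + Σ_j A22_j·RSP(t−j) + ε2(t)

is fitted by least squares; the order is selected by BIC over 1…12 on a
common sample (a fixed order can be configured).  Time-domain Granger
causality is `ln(var(ε1 restricted)/var(ε1 full))`, both residuals taken
from the same regression sample so the ratio is non-negative by
construction.  The frequency-domain curve G(f) is Geweke's spectral
decomposition computed from the fitted transfer function
`H(f) = (I − Σ_j A_j e^{−2πi f j/fs})⁻¹` and the residual covariance,
with the respiration innovation orthogonalised against ε1; averaged over
the band it integrates back to the time-domain measure (verified to 5 %
in the tests).  G(f) is evaluated on 512 points over (0, 2] Hz.

The resonance indices summarise G(f) inside the respiratory band:

| index | definition | unit | meaning |
|-------|------------|------|---------|
| F_A   | argmax of G(f) in (0.03, 0.5) Hz | Hz | resonance frequency |
| CRA   | G(F_A) | – | coupling depth |
| CRB   | full width of G at half maximum (linear interpolation; flagged if truncated at the band edge) | Hz | coupling bandwidth |
| CRQ   | F_A / CRB | – | quality factor |
| CRR   | CRB / (2π·F_A²) | s/rad | damping analogue |

The series-RLC analogy is taken with unit capacitance, so
`CRQ·CRR·2π·F_A = 1` holds for every record.  G(f) is not normalised
before peak extraction.  Windows failing the quality gate or producing a
degenerate (flat) spectrum are kept in the track but marked missing, so
the 10-s grid stays regular.

## Epoch features (21 + 2)

Per 30-s epoch: 3 body-movement features (variance, approximate entropy,
sample entropy of the acceleration vector magnitude — rotation-invariant,
and exactly three numbers), 12 HRV features (SDNN, RMSSD, pNN50; VLF
0.003–0.04, LF 0.04–0.15, HF 0.15–0.4 Hz band powers and LF/HF from the
Welch PSD of the 4-Hz resampled tachogram; Poincaré SD1, SD2, SD1/SD2,
sample entropy, approximate entropy with m = 2, r = 0.2·SD), and 6 CRI
features (CRR, CRB, CRQ, CRA averaged over windows whose centres fall in
the epoch — nearest valid window if none — plus variance and 10-bin
Shannon entropy of CRA over the 5-min context centred on the epoch, bin
edges fixed per subject between the 1st and 99th CRA percentiles).
Frequency-domain HRV is unreliable on 30 s, so HRV uses the 120-s window
centred on the epoch, stamped to the epoch.  Missing values are explicit
NaN; the classifier imputes with per-class training medians at fit time
and overall training medians at predict time.

Two stability features are appended (23 characteristics total): an
18-state supervised HMM is trained on (CRA, expert label) pairs — the
transition matrix is the bigram estimate, emissions are per-state
Gaussians over CRA — and at inference the state sequence is
Viterbi-decoded from CRA alone (missing CRA epochs are treated as
uninformative observations).  Epoch t with decoded state s contributes
`a_ss` (persistence) and `Σ_i a_is` (column sum).  Rows of states never
visited in training are uniform and flagged.

## Staging and diagnosis

Layer 1 of the stager is a random forest (500 trees, √d features per
split, balanced subsample class weights, fixed seed) over the 6 macro
stages; epochs predicted S1–S4 go to that stage's layer-2 forest over
{A1, A2, A3, NA}.  Wake and REM epochs carry no CAP phase, so the
composition covers the full 18-class label set.  Layer-1 training epochs
are restricted to runs of ≥ 20 identical WAKE/LIGHT/DEEP macro-labels
(10 min of stable stage); REM epochs are all kept (the selection rule
does not mention REM, and dropping them would leave layer 1 without REM
examples); layer 2 uses every labelled epoch.  Feature outliers beyond
median ± 5·MAD of the training set can be compensated: an optional
re-preprocessing hook is invoked once, after which remaining outliers are
winsorised to the fence (two passes at most; idempotent).

A subject summary aggregates a staged recording: per macro stage the mean
and variance of the 23 characteristics; the deep-sleep (S3+S4) CRI
profile (median per index — epochs bordering CAP activations dilute a
mean); and the per-stage A-vs-NA CRA contrast (difference of medians).
Diagnosis is per subject, not per epoch (a chronic condition has no
epoch-level truth value): median imputation → standardisation → RBF SVM
with an inner stratified 3-fold grid over C and γ, seeded.  The training
library is versioned; appending a confirmed subject never retrains
implicitly.

## Evaluation

The 18×18 confusion matrix has rows = actual, columns = predicted.
Per-class F1 is the harmonic mean of precision and recall; classes with
zero support are excluded from the unweighted macro mean and flagged; a
support-weighted mean is always reported alongside, because the two
conventions genuinely differ on imbalanced data.  Collapsed views
(sleep–wake, 6-stage, per-stage A/NA) are computed by summing matrix
blocks, which equals collapsing the label sequences first.  The per-stage
"A-phase recognition rate" is reported both as the recall of the merged
A class and as binary A/NA accuracy within the stage, since either
reading is defensible.  Group statistics use one-way ANOVA plus Dunnett's
post hoc test against the control group; a pair is significant when its
mean difference exceeds the least significant range (the half-width of
the Dunnett simultaneous confidence interval at α = 0.05).
Cross-validation splits at the subject level (7 folds by default), and
the pooled confusion matrix is the sum of the fold matrices.

## The synthetic-data generator

Every stage of the pipeline is testable without data downloads because
the simulator generates overnight recordings with the statistical
structure the method assumes.  Design highlights, and the reasoning where
the design was genuinely open:

* **Sleep architecture.** An 18-state Markov chain on the 30-s grid:
  long stage runs (so 10-min stable stretches exist for training
  selection), CAP phases mostly one epoch long inside NREM, deep-sleep
  CAP sequences alternating with several-minute non-CAP stretches.
* **Respiration.** A flat-topped (tanh-squashed) narrow-band oscillation
  around a subject-specific rate (~0.25 Hz) with slow drift and
  breath-to-breath frequency jitter.  Breathing is erratic in wake/REM
  and very regular in slow-wave sleep; its rate also slows with depth.
  Both facts feed the resonance bandwidth/quality and CRR features their
  stage dependence.
* **Coupling as phase fidelity.** The heart-rate oscillation in the
  respiratory band runs at near-constant depth, but its phase tracks the
  delayed respiratory phase through a noisy pathway whose phase-noise SD
  is `0.30/gain^1.7` rad (clipped to [0.05, 2.5]).  The causality
  measure then sees a coherent fraction of the respiratory line that
  grades smoothly and monotonically over the whole gain range.  A purely
  additive amplitude coupling was rejected: under 4-Hz spline resampling
  of a ~1.1-Hz beat series, both the restricted and unrestricted
  innovations scale with the modulation amplitude squared, so the
  causality ratio — hence CRA — becomes amplitude-independent.
* **Waveform shapes and the artifact gate.** The displayed respiration
  uses a moderate squash (spectral concentration stays well above the
  Q gate); the RSA waveform the heart follows is squashed harder
  (vagal gating saturates), because per-beat integral averaging of the
  tachogram erodes the peak-to-RMS margin of softer shapes.  A
  flat-topped oscillation peaks near 1.3·Std, leaving real margin under
  the 1.5·Std gate; Gaussian-dominated compositions would be flagged at
  the ~13 % any 1.5σ rule implies and were therefore avoided throughout.
* **Other state cues**, each physiological and each feeding named
  features: Mayer-band (0.04–0.18 Hz) activity prominent in wake/REM and
  suppressed in deep sleep (LF, LF/HF); mild bradycardia with depth
  (smoothly interpolated across stage boundaries); movement bursts whose
  probability and amplitude grade with the somatomotor impact of the
  state (wake and A3 heavy, A1 subtle and infrequent); a transient
  heart-rate acceleration during A phases (6/10/14 ms for A1/A2/A3); an
  R-peak timing jitter of 0.8 ms (realistic detector error, and the one
  noise that survives resampling as an amplitude-independent innovation
  floor).
* **Groups.** Insomnia couples strongly in non-A deep sleep and weakly
  in A phases (large swing); narcolepsy couples weakly everywhere; the
  non-pathological profile sits between, deepening with sleep depth.
  CAP activations disrupt the coupling coherence in every group; the
  synchronized A1 subtype carries almost no somatomotor or heart-rate
  signature, so its cardiorespiratory expression is purely the
  coherence drop — which is exactly what makes the CRI features
  non-redundant for CAP recognition.  Per-subject random effects:
  lognormal gain scale (σ = 0.08), baseline RR offset (σ = 20 ms),
  respiratory rate (σ = 0.015 Hz).
* **Beats** are placed by an integrate-and-fire (IPFM) rule on the
  instantaneous rate, so the intervals genuinely carry the modulating
  signal; intervals stay within (300, 2000) ms under defaults.

What passing tests on this generator do **not** show: performance on real
polysomnography.  The generator's state contrasts are well separated by
construction (the sanity bars assume exactly that); real recordings have
apnoea, arrhythmia, electrode artifacts, inter-scorer disagreement and
far weaker, subject-specific stage signatures.  The end-to-end scores are
sanity bars for the pipeline's plumbing and learnability, not estimates
of clinical accuracy.

## Problem sizes used by the shipped tests

Unit tests run on seconds-to-minutes of synthetic signal.  The end-to-end
sanity experiment uses 13 non-pathological subjects of 6 h (10 training,
3 held out) for staging, and a 15-subject cohort (5 per group, 3 h each)
with leave-one-subject-out evaluation for diagnosis; the stager for the
diagnosis arm is trained on two labelled subjects per group.  These sizes
were chosen as the smallest that keep the training data per class healthy
for the two-layer forest; all seeds are fixed, so every reported number
is reproducible bit-for-bit.  The within-stage A/NA score is the balanced
recall of the binary decision (the evaluator additionally prints the raw
merged-A recall and the binary accuracy for both conventions).

## Known limitations

* The 120-s analysis window smears single-epoch CAP phases: an A-phase
  epoch's windows contain ≥ 75 % surrounding signal, and the causality of
  a mixed window is dominated by its least coherent segment.  A-phase
  detection therefore leans on the epoch-sharp movement features plus the
  diluted coupling drop; S1 and A1 remain the hardest classes, as they
  are on real data.
* Eq-level constants (0.7/1.3 continuity bounds, the 1.5 normality
  multiplier, the Q threshold 0.85, the 20-epoch training-run rule) are
  taken as given; only the scale estimator behind the normality rule is a
  documented robustness choice.
* The diagnosis SVM operates on ~290 summary dimensions from few
  subjects; with real cohort sizes a sparser summary or regularised
  model may be preferable.
* EDF reading requires the optional `mne` dependency; the CAP Sleep
  Database's native annotation dialect is out of scope (a documented
  converter stub raises with instructions).

One further generator caveat: the built-in group profiles are calibrated
to the coupling-depth (CRA) contrasts the sanity checks require —
insomnia > healthy > narcolepsy in non-A deep sleep, a large insomnia
A/NA swing, globally low narcolepsy coupling.  The group patterns of the
derived quality factor and resistance (CRQ, CRR) are emergent rather
than calibrated and should not be read as reproductions of clinical
group contrasts.
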