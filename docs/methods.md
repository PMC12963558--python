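# Methods

This note documents the models, numerical choices and known limitations of
the package in one place.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Design and measures

The analysed design is fixed: one two-level within-subject factor
(Explainability: black-box "BB" vs heat-map "HM" advisory) and one
two-level between-subject factor (Expertise: expert vs student), with
possibly unequal group sizes (the modelled study has 11 experts and 10
students).  Four dependent measures are analysed identically: two
questionnaire composites (willingness to use, perceived impact on work
performance) and two EEG neurometrics (WL, AW).

## EEG preprocessing

* **Band-pass.** 5th-order Butterworth, 2–30 Hz, applied forward-backward
  (zero phase).  The bidirectional pass doubles the effective order; only
  band power is consumed downstream, so the steeper roll-off is harmless,
  and zero phase keeps epochs aligned with events.
* **Blink handling.** The published recordings were corrected with a
  proprietary ocular-artifact algorithm whose internals are not available;
  this package substitutes a documented template-regression corrector with
  the same contract (blink suppression without spectral distortion
  elsewhere).  Blinks are detected on AFz by amplitude (default 40 µV on
  the filtered signal — the synthetic 120 µV transient retains a 50–60 µV
  peak after the 2 Hz high-pass edge, while background stays below
  ~35 µV), with a 400 ms minimum separation.  Around each detection the
  mean-removed AFz segment (±300 ms) is the regressor: every channel is
  reduced by its least-squares projection onto it.  Samples outside blink
  windows are untouched.  A `reject` mode marks blink epochs as artifacts
  instead.  Equivalence to the original algorithm cannot be asserted, only
  the contract, which the tests check against the generator's injected
  blink log.
* **Epoching.** Consecutive non-overlapping 1-s epochs; a trailing partial
  epoch is dropped; the first and last second are trimmed after filtering
  to remove edge transients.
* **Artifact rejection.** An epoch is rejected when any channel exceeds
  ±80 µV at any sample (any-channel violation rejects the whole epoch; the
  mask is monotone in the threshold).

## IAF and band power

The Individual Alpha Frequency is the largest sufficiently prominent local
maximum (≥1.5× the median in-range density, which rejects the spurious
local maxima of flat spectra) of the parietal Welch spectrum (2-s Hann
windows, 50% overlap → 0.5 Hz resolution) of an eyes-closed rest segment,
searched in 7–13 Hz; if no peak qualifies, a 10 Hz fallback is used and
flagged.  Bands are Θ = [IAF−6, IAF−2], α = [IAF−2, IAF+2]; they partition
[IAF−6, IAF+2] without gap, and band integrals use half-open intervals
[low, high) so the shared edge is counted once.

**GFP operationalization.** "Global field power of a band over a subset" is
not uniquely defined for 2–3 channel subsets; the default here is the mean
across the subset of each channel's band-integrated Hann periodogram (one
periodogram per 1-s epoch, 1 Hz resolution).  The classical
spatial-variance GFP (per-sample across-channel variance of the
band-limited signal, epoch-averaged) is available via
`gfp_mode="spatial-variance"` for sensitivity analysis; it is degenerate
(zero) for spatially uniform signals, which is why it is not the default.

**Channel subsets.** WL frontal = {AFz, AF3, AF4, AF7, AF8}, WL parietal =
{Pz, P3, P4}; AW right = {AF4, AF8}, AW left = {AF3, AF7} with midline AFz
excluded.  All configurable.

**Aggregation.** WL is the ratio of epoch-mean powers (not the mean of
per-epoch ratios), which is stable for 1-s epochs; the per-epoch-ratio mode
exists behind a flag.  AW is the raw power difference in µV²; a log-power
variant (common in the asymmetry literature) is available but not the
default.  No per-subject normalization is applied before the ANOVA.

## Mixed ANOVA

Sums of squares use the unweighted-cell-means formulation, which coincides
with Type III for this design and matters because the groups are unequal:
the condition main effect tests the unweighted mean of the two groups'
difference means.  The decomposition is computed in closed form (between
stratum on subject means, within stratum on condition differences); the
test suite checks it against an independent general-linear-model projection
oracle to 1e-10 relative on hundreds of random unbalanced datasets, and
against `pingouin` on balanced ones (pingouin's weighted-means condition
term differs under imbalance, by design).  With two within levels no
sphericity correction applies.  Degenerate inputs: all-equal data report
F = 0, p = 1; a zero residual stratum with nonzero effect reports an
infinite F with a warning.

Two η² conventions are always computed: classical (SS over the total of
all five SS rows) and partial (SS over SS plus the residual SS of the
source's stratum); classical ≤ partial always.  The packaged printed tables
are verified against the convention each one is arithmetically consistent
with: three of the four published tables match the classical convention and
one matches partial, despite uniform footnotes — the verification report
carries both columns so the discrepancy is visible rather than resolved.
Because the printed SS are themselves rounded to three decimals,
reconstructed F and η² can differ from the printed values by up to one unit
in the last printed digit; the verification tolerance is set accordingly
(1e-3 on η², stricter 5e-4 on the two F values whose inputs allow it).

Type III sums of squares are not additive under group imbalance, so the
five-row additivity diagnostic (SS summing to the total SS about the grand
mean) is asserted only on balanced designs, where it is exact.

**Duncan's multiple range test** runs on the four cell means when any ANOVA
source is significant at α = .05.  A comparison spanning p ordered means
uses the critical range q(p, df, α)·√(MS_err/n_h), with q the
studentized-range quantile at protection level 1 − (1 − α)^(p−1)
(numerically exact via `scipy.stats.studentized_range`, matching published
Duncan tables to ~0.01), n_h the harmonic mean of the two compared cell
sizes, and the standard non-crossing rule.  The error term is the
within-cell MS pooled across both residual strata with its pooled df — the
original analysis does not state its error-term choice, so this one is
documented and configurable at the call site.

## Questionnaire

Items are 5-point Likert.  Correlations are Pearson over observations
pooled across conditions, p from the t transform of r with n − 2 df.  A
composite merge is approved iff every pairwise r among its items is
positive with p < .001 (the threshold the modelled study reports);
composites are unweighted item means (sum and z-mean variants behind a
flag).  Cronbach's α is emitted as an informational diagnostic only.  The
exact published item battery is not reproduced; item ids and wording ship
as editable metadata using the published result-section phrasings.  The
per-scenario 3-question agreement/comprehensibility survey is ingested but
not analysed, mirroring the modelled study.

## Synthetic-study generator

The generator is first-class, tested code; its defaults are the study
conditions the rest of the package is validated under.

* **Background**: band-limited pink noise (white noise shaped to a 1/√f
  amplitude profile, i.e. 1/f power, over 1–45 Hz), per-channel RMS drawn
  per subject from 5–8 µV.
* **Rhythms**: amplitude-modulated sinusoid bursts (sequential 1–2 s Hann
  windows with independent phases, so spectra are peaks, not lines):
  frontal theta at IAF − 4 Hz (5–7 µV base amplitude, multiplied by the
  condition theta gain), parietal alpha at the IAF (6–9 µV base, condition
  alpha gain; doubled in eyes-closed rest), and frontal alpha at 0.6× the
  parietal base amplitude whose right-hemisphere amplitude exceeds the left
  by a per-subject offset (sd 0.2 µV) plus the programmed shift.
* **IAF**: truncated normal, mean 10 Hz, sd 1, bounds [8, 12].
* **Artifacts**: biphasic 400 ms blinks, 120 µV at AFz scaled 0.8 at
  AF3/AF4 and 0.6 at AF7/AF8 and absent parietally, Poisson arrivals at
  8–20/min; rare rectangular >100 µV spikes on random single channels.
* **Default effects** (the programmed "truth"): theta gain 1.3 and alpha
  gain 0.8 under BB (workload higher without explanation), right-frontal
  alpha shift +0.5 µV for students under HM, and questionnaire latent
  shifts that raise willingness under HM in both groups and raise perceived
  work-performance impact for students.  Amplitude scales were chosen once
  so the in-band signal-to-background ratio is near 1 and the paired
  effect is detectable at n = 21.
* **Questionnaire**: one latent per construct per subject × condition
  (base 3.0 + programmed shift + subject intercept, sd 0.6 — sized so
  items of one construct correlate near r ≈ 0.7 on the discretized scale);
  item response = loading (default 0.9) × latent + noise (sd 0.35), rounded
  and clipped to 1–5.
* **Determinism**: everything derives from one top-level seed through
  spawned child seeds; identical config + seed reproduces the study
  bit-identically, and the two conditions become exchangeable when all
  gains are 1 and shifts 0 (the basis of the type-I calibration runs).

What the generator does **not** emulate: volume conduction / realistic
head-model topographies, EOG channels, non-stationary drift, line noise,
muscle artifacts, or correlated across-channel background noise.  Passing
tests therefore demonstrate that the pipeline recovers effects with the
programmed structure at realistic amplitudes and artifact rates — not that
it is robust to every failure mode of real scalp EEG.

## Problem sizes

The defaults are 256 Hz, 300 s task recordings and 60 s rest.  Monte-Carlo
runs in the tests and the acceptance script use scaled recordings (128 Hz,
16–24 s tasks, 30 s rest): direction-recovery and rejection-rate statistics
do not depend on recording length, and the per-subject precision at ~20
clean epochs is already sufficient for the programmed effect sizes.  The
subject-level approach-withdrawal check uses 120 s recordings because the
power *difference* of two noisy band estimates needs more epochs to beat
the background fluctuation.

## Known limitations

* The blink corrector shares a contract, not an implementation, with the
  algorithm used on the original recordings.
* The Duncan error term for the published student/HM trend is not
  recoverable without the raw data; that trend is not a target of the
  verification suite.
* The correlation screen pools conditions, treating the two observations
  per subject as independent; a per-condition diagnostic mode exists but
  the pooled r is what the composites are validated on.
* EDF output is classic EDF (16-bit, 1-s records, integer sampling rates
  only); reading goes through mne and accepts anything mne's EDF reader
  does.
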