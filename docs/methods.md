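# Methods

This note documents the models, parameter choices, and numerical decisions
behind `vigikit`, and what the synthetic-data verification does and does not
establish about real recordings.

## Vigilance staging model

Every artifact-free 1-s segment is classified by a deterministic rule
cascade over regional spectral power:

1. **A-stages (alpha-dominant).** If occipital relative alpha ≥ 0.40, the
   segment is an A-stage. The alpha band is adaptive:
   `[iAPF − 2, iAPF + 2]` Hz. The substage follows the frontal/occipital
   alpha amplitude ratio ρ = √(P_front/P_occ): A1 if ρ < 0.5, A2 if
   ρ < 1.0, else A3 — anteriorization of alpha marks the descent within A.
2. **B2/3 (drowsiness).** Otherwise, if relative theta (4–7.5 Hz) ≥ 0.50.
3. **B1 vs 0.** Otherwise, B1 when a slow eye movement (SEM) overlaps the
   segment, else 0.

Relative powers are normalized by the 4–30 Hz total band. The delta range
is excluded from every denominator so that low-frequency content — often
non-neuronal in children, or movement-related — cannot change a label; a
property test adds pure 2 Hz content to staged segments and asserts label
invariance.

Regional power is channel-space: occipital = {O1, O2, P3, Pz, P4, T5, T6},
frontal = {Fp1, Fp2, F3, Fz, F4, F7, F8}, averaged Hann periodograms per
region, band powers by rectangle integration of the 1-Hz-resolution PSD.
Source localization (as used by LORETA-based tools) is deliberately not
attempted: a plain 10–20 montage recording carries the occipital-vs-anterior
gradient that defines the A-substages, and channel space keeps the method
desk-scale and auditable.

The dominance thresholds (0.40 alpha, 0.50 theta) and substage ratio bounds
(0.5, 1.0 on the amplitude scale) are package defaults chosen for
separability of the stage signatures and exposed in `StagingConfig`; they
are conventions, not measured constants, and studies with different
montages or populations may need to retune them.

**Low-voltage guard.** Relative band fractions of a near-zero segment are
numerically meaningless (they amplify filter leakage), so segments with
occipital total power < 1 µV² bypass the band rules and are classified 0/B1
by the SEM flag alone.

### iAPF estimation

Welch spectrum (4-s windows) of the occipital average over artifact-free
segments; the maximum in 7–13 Hz is refined by parabolic interpolation.
Near-ties (within 5% relative power) resolve to the **lower** frequency,
making the estimate deterministic for symmetric two-peak spectra. Alpha
counts as undetected when the candidate peak does not exceed 2× the 1/f
trend fitted log-log over 4–30 Hz excluding the search band; at least 30
artifact-free segments are required.

### Surrogate EOG and SEM detection

Horizontal ocular drifts project with opposite polarity onto the lateral
frontal electrodes, so the band-passed (0.1–1 Hz, Butterworth order 2,
forward–backward) difference F7 − F8 serves as a surrogate EOG. It is
derived from the *unfiltered* recording: the 0.5 Hz analysis high-pass
would remove the 0.25–0.5 Hz drifts themselves. A SEM is a run of
|surrogate| > 15 µV lasting ≥ 0.3 s; a segment is flagged when ≥ 0.1 s of a
qualifying run falls inside it. In clinical practice this component is
obtained from an ICA decomposition; the bipolar surrogate is the
deterministic, rater-free equivalent for the lateral-drift topography.

### Preprocessing

Butterworth band-pass 0.5–70 Hz, order 4, applied forward–backward
(zero phase), plus a 50 Hz notch (Q = 30). The analysis window is the first
8 min of non-hyperventilation data, counted from recording start; shorter
recordings are analyzed in full and flagged. Artifact rules: a segment is
rejected when any channel exceeds 150 µV absolute, or when all channels'
peak-to-peak stays under 1 µV (dropout). These thresholds are conventional
automated stand-ins for visual screening, configurable and logged in every
run manifest.

### Recording validation

A recording enters analysis only if all of: iAPF within 8.5–12.5 Hz;
artifact fraction < 15%; alpha plausibly detected — peak above the 1/f
trend, aggregate occipital alpha power above a threshold (default 25,000;
this quantity is amplifier-dependent and the unit is deliberately opaque,
computed here as alpha-band power summed over occipital channels and
artifact-free segments in µV²), and at least one A-stage segment within the
first 120 s (the operationalization of "alpha detected early"); and < 95%
of segments in {0, B1}, excluding low-voltage EEG.

## Arousal outcomes

**Occurrence percentages** use the artifact-free denominator. **Mean
vigilance** is the artifact-free mean of stage codes {0→6, A1→5, A2→4,
A3→3, B1→2, B2/3→1}. This coding is a verified reconstruction: applied to
published group occurrence rows it reproduces the printed group mean
vigilance in all six independent subsample rows (the acceptance suite
recomputes this identity), which pins the map uniquely.

**Stability index** (1–8) follows the scoring table literally: 8 when
> 2/3 of all artifact-free segments are {0, A1}; 7 when ≥ 2/3 are
{0, A1, A2, A3}; 6/5/4 when ≥ 1/3 of the last/second/first 160-s third is
B1; 3/2/1 the same for B2/3. Three points are underdetermined by the table
and fixed here as package decisions:

- *Precedence*: when several of 1–6 hold, the minimum wins (the earliest,
  deepest drowsiness event is the most unstable pattern); 8 is checked
  before 7 (its strict ">" vs "≥" implies it is the narrower criterion).
- *Thirds*: wall-clock 160-s thirds with per-third artifact-free
  denominators; an all-artifact third satisfies nothing.
- *Fallback*: diffuse B1 patterns can satisfy no criterion; the score is
  then 7 with an explicit `fallback_flag` rather than an invented value.

A brute-force evaluator (literal transcription of all eight criteria)
agrees with the implementation on 10,000 random sequences, and randomized
"stabilizing edits" (replacing B-segments with A1) never lower the score.

The sliding one-minute mean-vigilance series (60-segment windows, step 1)
is provided as a descriptive timecourse; it is not an input to the
stability score, whose criteria are defined on the fixed thirds.

## Statistics

- Mann–Whitney U: mid-rank ties, tie-corrected variance, no continuity
  correction; exact p for tie-free samples with n ≤ 20, else the normal
  approximation. Effect size r = |Z|/√n — note the magnitude convention
  and the square root; this is the form that reproduces all twelve
  checkable published effect-size cells, and the package treats the
  occasionally printed "r = Z/n" as a typographical variant.
- Kruskal–Wallis: tie-corrected H, χ²(k−1) p, η² = (H − k + 1)/(n − k)
  reported **unclamped** (H < k−1 yields small negative values which round
  to the near-zero magnitudes seen in published tables). The all-values-tied
  degenerate case returns H = 0, p = 1.
- Stability χ²: default bins {1–3, 4–5, 6–7, 8} (df = 3); empty bins are
  merged with a warning.
- Age matching: cases visited in seeded-random order, each paired with a
  random unused control within 2 months; deterministic under the seed;
  unmatched cases are dropped and countable.
- No multiple-testing correction anywhere, by design: the battery mirrors
  an explicitly explorative analysis protocol.

## Synthetic cohorts

The generator exists so that every claim the pipeline makes can be checked
against known latent truth.

**Trajectories** are a dwell-time Markov chain on the ordered stages with
per-minute hazards `decline_rate` (one stage toward B2/3) and
`recovery_rate` (one stage toward 0), converted to per-second probabilities
1 − exp(−rate/60), with a minimum dwell of 5 s per visited stage. Two
presets encode the clinical constructs: `adhd_like` (decline 0.9/min,
recovery 0.12/min — fast decline into drowsiness, median stability 3) and
`dep_like` (decline 0.05/min, recovery 0.15/min — hyperstable, A1-dominant,
median stability 8). They are calibrated so the preset stability medians
differ by ≥ 1 point in samples of 19 per group, the construct the matched
comparison rests on. Under identical presets in both arms, the stability
comparison rejects at 4–6% at nominal α = 0.05 (200-replicate check in the
acceptance suite).

**EEG synthesis** renders each second's stage signature at 512 Hz on the
19-electrode montage: occipital 10 Hz alpha at 20 µV with
frontal:occipital amplitude gradients 0.3/0.85/1.3 for A1/A2/A3; 5.5 Hz
theta at 20 µV for B2/3; 4 µV broadband desynchronized activity for 0 and
B1; SEM as back-to-back 1.5-s half-sine deflections of alternating
polarity, mirrored across F7/F8, 40 µV, during B1 runs; 1/f background
noise (4 µV RMS), optional 50 Hz line noise (2 µV) and frontal blinks.
Oscillators keep continuous phase and envelopes ramp over 0.1 s so segment
boundaries do not leak broadband power.

**Cohort tables** draw ages per group (ADHD-like 118 ± 33 months,
depression-like 184 ± 23, truncated to the 6–18-year study range),
medication categories with the published frequencies, and CBCL-like
clinical T-scores (Gaussian, truncated to [20, 100]) per subscale with the
published group means/SDs. A Gaussian copula links scores to each subject's
realized stability with a configurable Spearman ρ (default 0, matching the
null association the analysis design anticipates).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: developmental iAPF changes within a recording or
across age (iAPF is a per-subject scalar), posterior slow waves of youth
and other pediatric delta/theta variants, sleep graphoelements, cardiac and
sweat artifacts, electrode drift, reference asymmetries, and genuinely
ambiguous transitional segments. Stage signatures are spectrally clean, so
round-trip recovery (≥ 99% noise-free, ≥ 80% at default SNR — in practice
near 100%) is an upper bound on real-data performance, not an estimate of
it. The staging thresholds' adequacy for clinical EEG must be established
against expert-labeled recordings.

## Problem sizes and runtimes

The test suite runs single-subject pipelines at 60–480 s of synthetic EEG,
the construct-recovery check at 19 + 19 subjects (240-s recordings through
the full EEG path; 480-s trajectories through the table path), the type-I
calibration at 200 replicates of 19 + 19 trajectory simulations, and the
stability oracle comparison at 10,000 random sequences — sizes chosen so
the whole suite completes in about a minute on one CPU while keeping every
Monte Carlo bound comfortably away from its threshold.

## Known limitations

- EDF export is a minimal 16-bit writer (EDF+C for annotations): one data
  record per second, integer sampling rates only, all event annotations
  stored in the first record. Round trips through the mne reader are exact
  to one quantization step.
- The stability index's "1-min intervals" descriptive series and the
  160-s-third criteria coexist without a stated relation in the source
  literature; this package implements the scoring table literally and
  exposes the sliding series separately.
- The pooled-t power computations occasionally reported alongside such
  analyses are not reproduced here; `two_sample_t` returns the standard
  pooled Cohen's d only.
- Validation's absolute-alpha-power criterion is amplifier-relative; when
  analyzing data from a different acquisition chain, recalibrate
  `alpha_power_threshold` rather than trusting the default.
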