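# Methods

## Problem and pipeline

`eegaffect` implements a binary EEG emotion classifier (happy vs unhappy,
i.e. high vs low valence at low arousal) with the processing chain used by
consumer-headset affective BCI studies, plus the experiment harness needed to
characterize it:

1. **Acquisition model.** 14 channels (AF3, AF4, F3, F4, F7, F8, FC5, FC6,
   P7, P8, T7, T8, O1, O2; 10–20 system) at 128 Hz. A session has 5 trials
   per subject; each trial is a 60 s happy stimulus, 12 s rest, 60 s unhappy
   stimulus (132 s, happy first by convention).
2. **Preprocessing.** Zero-phase IIR notch at 50 and 60 Hz (quality factor
   30; ≥ 20 dB attenuation at the mains tone, < 1 dB at ±5 Hz), then
   per-channel subtraction of the whole-recording mean.
3. **Features.** Non-overlapping 1 s windows of the labelled segments
   (rest discarded) are decomposed by a 4-level dyadic DWT (db4). At 128 Hz
   the subbands coincide with the classical bands: A4 = delta 0–4 Hz,
   D4 = theta 4–8, D3 = alpha 8–16, D2 = beta 16–32, D1 = gamma 32–64.
   The per-band feature is the mean squared subband coefficient ("wavelet
   band power"); a Welch periodogram variant is available for comparison.
   14 channels × 5 bands = 70 features per window; a homologous pair gives
   10. Features are min–max scaled to [0, 1] per participant.
4. **Classification.** RBF-kernel SVM. Subject-dependent accuracy =
   leave-one-trial-out CV (LOTO, 5 folds); subject-independent =
   leave-one-subject-out CV (LOSO, one fold per subject). (C, γ) chosen by
   exhaustive grid search maximizing the unweighted mean of fold accuracies.
5. **Experiments.** LOTO vs LOSO comparison (with configurable subject
   exclusion), 7 homologous channel-pair ablation, 5-band ablation, and
   first-30 s / last-30 s / full-60 s stimulus-duration ablation, with
   two-sided paired t-tests across subjects (α = 0.05; Holm correction
   available, off by default — single pairwise claims are the design).
6. **Streaming detector.** Each incoming 1 s window is classified with a
   stored subject-dependent model; every 5 windows a majority vote emits a
   discrete level: 5/4/3 happy votes → Happy 3/2/1, 2/1/0 → Unhappy 1/2/3.
   The vote window is odd, so ties cannot occur; vote blocks do not overlap.

## Synthetic cohort generator

No public recordings exist for this protocol, so cohorts are synthesized.
Band power is the only signal property the pipeline consumes, which licenses
a minimal generative model: each channel is a sum over the five bands of
zero-phase band-pass-filtered white Gaussian noise (4th-order Butterworth at
the band edges, forward–backward), rescaled to unit RMS and multiplied by a
piecewise-constant envelope

    amplitude(channel, band, t) = noise_floor[band] × effect(label(t))
    effect = 1 + attenuation_subject × (gain(class, channel, band) − 1)

with all gains 1 during rest. Per-trial noise is seeded by
`(seed, seed_offset, subject, trial)`, so cohorts are bit-reproducible and
trial generation is order-independent.

Defaults (chosen once as the study conditions):

| parameter | default | rationale |
|---|---|---|
| subjects × trials | 10 × 5 | protocol size |
| sampling rate | 128 Hz | headset rate |
| stimulus / rest | 60 s / 12 s | protocol timing |
| noise floor (δ,θ,α,β,γ) | 20, 10, 8, 5, 3 µV RMS | 1/f-like scalp spectrum |
| happy gains | γ 1.10 / β 1.08 at T7, T8; γ 1.04 at P7, P8; β 1.03 at FC5, FC6 | contrast concentrated in high bands at temporal sites, weak secondary effects |
| subject jitter | U(0.5, 1.5) multiplier on excess gain, drawn once per (subject, channel, band) | individually different response topographies → LOSO < LOTO |
| attenuation | 0.3 for subjects 1, 3, 9 (else 1.0) | reduced response magnitude of the three oldest participants |

A 10 % amplitude gain is a ~21 % band-power shift against the ~18 % relative
sampling error of a 1 s band-power estimate (64 gamma coefficients), which
puts single-window discriminability in the modest, non-saturated regime such
studies report. `null_spec` (all gains 1) and `strong_effect_spec` (gain 3.0
at chosen channels/bands) provide the calibration endpoints used by the
tests: chance-level and ≥ 90 % LOTO accuracy respectively.

**What the generator does not emulate:** ocular/EMG artifacts, volume
conduction, non-stationarity within segments, evoked transients, and real
inter-feature correlation structure. Passing tests therefore demonstrate
correctness of the pipeline's bookkeeping, leakage discipline and
sensitivity — not field performance on real EEG.

## Numerical choices

- **DWT boundary handling** is `periodization`, making db4 exactly
  orthogonal on a 128-sample window: subband energies sum to the
  time-domain energy (Parseval) and coefficient counts are exactly dyadic
  (8/8/16/32/64). Symmetric extension is available via `mode=` but inflates
  white-noise subband energy by ~16 % through boundary duplication.
- **Band leakage.** Dyadic filters are imperfect: a pure 40 Hz tone puts
  most of its energy in gamma but leaks noticeably into beta (gamma ≈ 3×
  beta per-coefficient power); at the band centre (48 Hz) gamma dominates
  every other band by > 10×. Tests assert accordingly.
- **Normalization.** Per column, x → (x − x_min)/(x_max − x_min), clipped
  to [0, 1] when applied outside the fit rows. Constant columns map to 0
  with a warning. LOTO fits min/max on training trials only (leakage-free
  default; a pooled per-subject mode exists for comparison). LOSO scales
  each subject — held-out included — on its own rows only.
- **Grid search** is exhaustive; ties on mean fold accuracy break toward
  the smallest C, then the smallest γ (simpler model, deterministic).
  Default grid: C ∈ 2^{−5..15}, γ ∈ 2^{−15..3}, exponent step 2.
- **Paired t-test conventions.** Identical vectors → p = 1 (no difference
  anywhere); constant nonzero difference → p = 0 (the zero-variance limit
  of the t statistic).
- **Streaming baseline.** The offline whole-recording mean is unavailable
  online; the default subtracts a causal exponential running mean with a
  10 s half-life. `baseline="window"` (per-window demeaning) makes a file
  replay bit-identical to the batch pipeline and is what the equivalence
  tests use. Streaming input is assumed mains-notched upstream (as headset
  hardware does); replay drivers apply the software notch before streaming
  so training and replay features share one preprocessing.

## Problem sizes in the scripted runs

The analysis drivers and `scripts/acceptance.py` run the full 10 × 5 cohort
(6 000 windows). Subject-dependent runs there use a 5 × 5 power-of-two grid
(C ∈ 2^{−1,1,3,5,7}, γ ∈ 2^{−9..−1}) and the LOSO run a 3 × 2 grid — the
package's choice of search resolution for cohort-scale experiments; the
full default grid remains in place for single-subject calls. Null-effect
chance checks deliberately use a single (C, γ) point: selecting the best of
many grid cells on label-free data inflates the selected CV mean (winner's
curse) without indicating any pipeline leakage, and the check is about
leakage. SVM-heavy unit tests use reduced cohorts (3–4 subjects, 20 s
stimuli, 3 trials) with strong injected effects, where the expected ordering
is unambiguous.

## Known limitations

- Reported accuracies quantify the synthetic cohort only; they are not
  estimates of performance on real recordings.
- The first-30 s condition scores slightly below the full-60 s condition on
  synthetic data purely because halving the windows halves the training
  set; the generator is stationary within segments, so this is a sample-size
  effect, not an elicitation-dynamics effect.
- The EDF writer covers the subset of EDF this package produces (integer
  sampling rate, 1 s records, whole-second recordings, µV units); segment
  labels travel in a sidecar CSV rather than EDF+ annotations.
- LOSO grid search at cohort scale refits an SVM on ~5 400 rows per fold
  and cell; the kernel is the cost driver, hence the coarser LOSO grid.
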