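# Methods

## The problem and the model

A spatially-coded SSVEP brain-computer interface presents a single flicker
(here 60 Hz) and encodes the user's command in *where* the flicker falls in
the extrafoveal visual field: gazing at different targets around the flicker
produces steady-state visually evoked responses with different scalp
topographies, while the driving frequency is common to all classes.
Classification therefore has to separate spatial patterns of a narrow-band
oscillation rather than frequencies.

The pipeline is:

1. **Band-pass filtering.** Each trial is filtered with a zero-phase FIR
   band-pass (default 55–65 Hz, order 66, windowed-sinc with a Hamming
   window). "Zero-phase" is realized as forward–backward application of the
   linear-phase filter, implemented as a single convolution with
   `conv(b, reversed(b))` after reflection padding of one filter length at
   both ends. Note that a 67-tap FIR at 2048 Hz spans only 33 ms, so the
   transition bands are necessarily wide (≈200 Hz): the filter is a gentle
   spectral shaping around 60 Hz, not a brick wall. That is enough, because
   the CCA stage itself is frequency-selective.

2. **CCA spatial filter bank.** For each class c, the training trials of
   that class are trimmed to the analysis window, concatenated along time,
   and canonically correlated with the two-row sinusoidal reference
   Y = [sin 2πft; cos 2πft]: r = max_{A,B} corr(AX, BY). The solver
   orthogonalizes both (centered) sides and takes the SVD of the
   cross-product (equivalently, a whitened scatter-matrix eigenproblem —
   both solvers are implemented and agree to numerical precision; the
   scatter form allows cheap retraining, see below). The per-class filters
   A_c, B_c are then *fixed*; a new window is projected through all C of
   them, and the absolute first canonical correlation per class forms the
   feature vector f ∈ [0,1]^C. (A `feature_mode="both"` option uses both
   canonical pairs, d = 2C.)

3. **Gaussian LDA with posteriors.** Class-conditional densities are
   multivariate Gaussians with class centroids μ_c and one pooled covariance
   Σ (unbiased within-class pooling, scatter/(n−C)); priors are uniform by
   default (the protocol visits every target equally often). Posteriors
   follow from Bayes' rule, computed in log-space with log-sum-exp;
   ĉ(f) = argmax_c P(c|f). Σ is shrunk toward its diagonal with the
   smallest γ ∈ {0, 1e-4, 1e-2, 1e-1} that brings the condition number
   below 1e8; with d = C = 5 features this rarely triggers except in
   degenerate (noise-free) fixtures.

4. **Dynamic stopping.** Online, EEG arrives in amplifier chunks of 131
   samples (≈64 ms at 2048 Hz, a ~15.6 Hz decision rate). After each chunk
   the growing window is filtered, featurized and classified; the decision
   is final when N consecutive evaluations yield the same label, each with
   winning posterior ≥ P. Defaults N = 2, P = 0.95. A sub-threshold
   evaluation resets the agreement counter to zero (a "hold" variant that
   merely pauses the run when the label at least repeats is available
   behind `hold_on_low_posterior`). Because short windows compared against
   full-length training statistics lose accuracy, a separate filter bank
   and LDA are trained for every reachable window length with the training
   trials trimmed to that length — the *model cache*.

## Decisions where the design was open

* **Reference phase across concatenated trials.** The reference restarts at
  t = 0 for every concatenated trial rather than running continuously
  through the concatenation. Each trial's SSVEP phase is locked to its own
  stimulus onset, not to its position in the concatenation (131-sample
  chunks are not an integer number of 60 Hz cycles), and the restart makes
  the trained bank exactly invariant to trial order.

* **Timeout.** The stopping rule alone need not terminate; a `max_window`
  (default the 4 s training-trial length) forces a decision carrying the
  last label, flagged `forced`. Forced decisions count toward accuracy by
  default (an always-responding interface); a switch excludes them.

* **First classifiable window** is the first chunk multiple that exceeds
  the filter length (order+2 samples); with the defaults that is the very
  first 131-sample chunk.

* **Inter-trial gaze-shift time** (0.5 s in the online protocol) is *not*
  counted in classification time or ITR by default; `count_gap=True` adds
  it for throughput-style accounting.

* **ITR below chance.** The ITR formula's minimum is exactly 0 at G = 1/C
  and it is positive on both sides; below-chance accuracies are evaluated
  faithfully but warned about, since there the formula credits information
  to systematically wrong answers.

* **Degenerate projections.** A projection whose variance is below 1e-18 of
  the window's total power (times the squared filter norm) is treated as
  numerically nulled and its feature set to 0; otherwise pure roundoff —
  which after projection of rank-deficient data still looks sinusoidal —
  correlates spuriously with the reference.

## Fast retraining via scatter statistics

Training a bank and an LDA at every one of the ~62 cached window lengths,
and leave-one-trial-out loops that retrain filters per held-out trial,
would be prohibitively slow done naively. All training-side quantities are
functions of per-trial second moments (X Xᵀ, X Yᵀ, row sums) at each window
length, which accumulate incrementally over chunks in one pass over the
data. Class-level CCA then reduces to a small whitened eigenproblem and a
leave-one-out downdate to a subtraction. These fast paths are exactly
equivalent to the naive compositions (asserted in the test suite, including
a brute-force direction-search CCA oracle and a rebuild-everything LOO
oracle). The streaming path likewise caches filtered samples that can no
longer change (zero-phase FIR output more than one kernel half-width from
the window end is final) and refilters only the tail — bit-identical to
one-shot filtering.

## Synthetic data: what it emulates, and what it does not

No recordings were published with the original study, so a generator
provides the study conditions: 32 channels at 2048 Hz, 5 classes, a 60 Hz
sinusoidal component projected through class-specific unit-norm scalp
patterns, 1/f background noise mixed across channels, 4 s trials, sessions
organized in randomized sequences visiting every target once, and online
delivery in 131-sample chunks.

* **Topographies** mix a shared spatial direction with per-class orthogonal
  directions so that all pairs have correlation exactly 1 − min_separation
  (default 0.5 — the study gives no quantitative inter-class similarity;
  the value is a configurable guess).
* **Per-trial variability**: lognormal amplitude jitter (σ = 0.3, mean 1)
  and Gaussian phase jitter (σ = 0.3 rad) — trial-to-trial response
  variability of this order is what makes adaptive stopping useful at all.
* **SNR calibration.** The response-strength estimator used throughout is
  the periodogram power at the stimulation bin over the mean power of the
  0.25 Hz bins in 58.75–61.25 Hz excluding that bin (channel-averaged
  spectra; recordings are zero-padded to the next 4 s multiple so the bins
  align exactly). The generator calibrates its tone amplitude *against this
  estimator*: the measured SNR of generated trials matches the configured
  value in expectation. Because the stimulation bin itself contains noise,
  the estimator has a floor of ~1, so configured values ≤ 1 produce no
  tone at all — the generator cannot realize sub-floor SNRs, only chance
  data.
* **Not modeled**: harmonics (the pipeline band-passes 55–65 Hz), blinks
  and eye movements, electrode drift, fatigue or any non-stationarity
  across a session. The last point matters for interpretation: in the
  original cohort the fixed-window estimate came from training data while
  both strategies were scored online, where signal quality differed; the
  synthetic sessions are statistically stationary, which removes one of
  the real-world advantages of adaptive stopping. Passing the synthetic
  comparison therefore demonstrates the machinery and the adaptivity gain
  from trial-to-trial variability, not the full effect size seen in vivo.

## The synthetic cohort study

`ssvepds.study.synthetic_cohort_study` evaluates 20 subjects with SNRs
evenly spaced over 0.5–8, each with a 30-sequence training session and a
25-sequence (125-trial) online session of 4 s trials. Per subject it
selects the optimal fixed window on the training data (argmax over all
chunk-aligned lengths of ITR(LOO accuracy)), then scores both the fixed
window and dynamic stopping (N=2, P=0.95) on the online trials, mirroring
the original evaluation protocol. These problem sizes (20 subjects, 125
online trials) keep the whole study around 7 minutes on one CPU while
holding the binomial error of per-subject accuracies near 3 %.

Robustness is summarized by the worst DS/fixed ITR ratio over *informative*
subjects — those whose fixed-window online accuracy is significantly above
chance (one-sided binomial test, α = 0.05). For a subject at the SNR floor
both ITRs are sampling noise around zero (the fixed window's, at a ~0.2 s
denominator, noisier than the DS one), and a ratio of two such numbers
carries no information about the method.

Typical behavior across the SNR range: near the floor both strategies are
at chance; for SNR ≈ 1.3–4 dynamic stopping wins clearly (higher accuracy
at moderately longer windows); at high SNR the optimal fixed window shrinks
to ~2 chunks and nearly ties with DS, which by construction needs at least
N agreeing evaluations.

## Numerical and procedural details

* Leave-one-trial-out excludes the held-out trial from *both* the CCA
  filters of its class and the LDA training features; a deliberate-leakage
  mode exists solely as a negative control in tests.
* Grid searches break ties toward the cheaper operating point: lowest
  filter order, shortest window; the (N, P) search prefers larger N then
  larger P (more conservative stopping). The (N, P) search cross-validates
  over stimulation sequences (5-fold) to keep class balance; a
  train-on-all mode is available.
* Classification ties (equal posteriors) go to the lowest class index.
* All randomness flows through explicit seeds; identical configuration and
  seed reproduce sessions bit-for-bit.

## Known limitations

* EDF/BDF files are read (via mne) but not written; the native interchange
  format is a columnar CSV plus JSON sidecar, which is lossless where
  EDF's 16-bit quantization is not.
* The feature composition of the original system (how many canonical
  correlations were "merged") is not fully specified in the source
  material; the default d = C (first correlation per class, absolute
  value) is the minimal standard choice and is configurable.
* Sub-floor SNRs (≤ 1 under the estimator above) cannot be synthesized,
  only chance data; see the calibration note.
* No self-paced / no-control-state detection, no per-target thresholds.
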