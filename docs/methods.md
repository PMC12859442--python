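# Methods

## Synthetic signal model

`emgadapt.synthgen` emulates a hand-force-exercise sEMG acquisition:
`n_subjects` participants each perform `n_classes` exercises
`n_trials_per_class` times, recorded on `n_channels` forearm channels
at `sampling_rate` Hz with `trial_length` samples per trial. Defaults
(14 subjects, 15 classes, 20 trials, 8 channels, 500 Hz, 2000 samples)
match a realistic desk-scale wearable-sensor protocol and yield 4200
trials.

Each trial is built as

    x_ch(t) = A[c,ch] * s_subj * g(t) * f(t) * r(t) * (n_bl(t) + a[c,ch])
              + sigma_0 * n_floor(t)

where

- `n_bl` is band-limited (10–245 Hz Butterworth, within the 10–500 Hz
  physiological sEMG band and below the 250 Hz Nyquist limit),
  unit-variance zero-mean noise — the interference-pattern carrier;
- `g(t)` is a burst gate with class-specific repetition rate
  (1.5–4 Hz) and class-and-channel-specific duty cycle (0.30–0.90),
  edge-smoothed with a 50 ms raised-cosine kernel — differential
  recruitment of the eight muscles across exercises;
- `A[c,ch]` in 0.5–1.6 is the class/channel amplitude pattern and
  `s_subj` a per-subject lognormal scale (SD 0.08) — between-subject
  variability;
- `a[c,ch]` in −0.45–0.45 is a waveform asymmetry: motor-unit action
  potentials are asymmetric biphasic waves, so the rectified positive
  and negative phases differ. This term gives sign-sensitive amplitude
  features (AVSER) a stable class-specific expectation instead of a
  zero-mean random walk;
- `f(t)` is a slow (~4 Hz support) multiplicative fluctuation of depth
  0.15; `r(t)` a linear fatigue drift; `sigma_0 = 0.02` the baseline
  noise floor. Units are arbitrary mV-like amplitudes — absolute
  calibration is irrelevant to classification.

All class/subject parameters and per-trial noise derive from
`SeedSequence` keys of the dataset seed, so identical (config, seed)
pairs are bit-identical, and the per-trial draws are independent of
cohort.

### The shifted cohort

`ShiftProfile` applies, multiplicatively and after all random draws:
amplitude gain 1.6, noise-floor gain 3.0, fluctuation gain 1.8, and a
fatigue drift starting at 40 % of the trial (slope 0.6 over the
remainder) — the qualitative signal differences reported for smoking
and alcohol-consuming participants: higher amplitude, elevated
baseline noise, pronounced fluctuation, earlier fatigue.

These purely multiplicative distortions rescale feature vectors but
largely preserve nearest-class structure, which cannot reproduce the
empirical phenomenon this package studies: a static classifier falling
*below chance* on the shifted population while the population remains
internally separable. That phenomenon requires the class-conditional
distributions to be coherently *remapped*, which is physiologically a
reorganization of motor-unit recruitment under impaired neuromuscular
coordination — a systematic cohort-level effect, not per-subject
noise. `recruitment_shift` (default 0.7) therefore blends the shifted
cohort's per-class duty/amplitude/asymmetry patterns toward an
alternative seed-deterministic pattern set. The identity profile (all
gains 1, onset 1, blend 0) reproduces the baseline cohort exactly.

The defaults were calibrated once so that (a) within-baseline
subject-wise CV accuracy of a plain kNN exceeds 0.90 (it reaches 1.0),
and (b) the baseline-trained static kNN collapses on the shifted
cohort while the adaptive model recovers. No parameter encodes any
particular target accuracy; the recovered accuracy is an emergent
result of the experiment.

### What the generator does not model

Motor-unit-level physiology, electrode placement and crosstalk,
inter-session electrode displacement, power-line interference, and the
idiosyncratic statistics of any real recording. Passing tests
demonstrate that the adaptation mechanism behaves as designed under a
controlled, internally consistent covariate shift — not that it will
achieve any particular accuracy on real populations.

## Features

The per-channel time-domain features use the standard sEMG-literature
definitions (see the `features` module docstring for formulas). Two
choices were genuinely open:

- **AVSER** is implemented as |Σ sgn(x_i)·|x_i|^p| with p = 0.75, the
  sign-preserving fractional-power form that stays real for negative
  samples; the exponent is configurable.
- **WAMP threshold**: signals are uncalibrated, so a fixed absolute
  threshold is meaningless. The default is data-driven: 5 % of the
  pooled per-channel standard deviation of the *training* trials,
  overridable with a fixed value. Thresholds and the per-dimension
  z-scaler are always fitted on the training fold only, never on test
  or buffered data.

Feature vectors are channel-major (all features of channel 0, then
channel 1, …); the minimal tier WAMP+AVSER gives 16 dimensions on 8
channels. The registry accepts additional user-registered features;
the larger historical feature sets are deliberately out of scope.
Features are computed on the full 2000-sample trial (one vector per
trial), not on sub-windows.

## Classifier

Design points where the procedure was underdetermined:

- **Candidate pool**: base set ∪ buffer by default. A buffer-only mode
  exists (falling back to the base set while the buffer holds fewer
  than k entries); the union is the default because it preserves
  near-perfect resubstitution accuracy on the training set while still
  adapting.
- **Label source**: oracle mode (true labels; default, the upper-bound
  protocol used in the reported experiments) and self-training mode
  (own predictions gated by confidence ≥ τ, default 0.8). Confidence
  is top vote mass divided by total mass.
- **Determinism**: ties in the k-th distance break toward the smaller
  base/arrival index; ties in vote mass toward the smallest class id.
- **eps = 1e-8**: far below the O(1) distances of z-scored features;
  predictions are empirically identical for eps in 1e-12…1e-6 (tested).
- **Search**: exact full scan per query; at desk scale (pools of a few
  thousand instances) approximate indexing is unnecessary.
- The **static baseline** is the conventional unweighted-majority kNN
  (k = 3, L1). The W = 0 limit of the adaptive model is the *weighted*
  static kNN; the window-sweep's W = 0 row is that limit by
  construction, and the equivalence is asserted in tests.

## Evaluation protocol

- Splits are strictly subject-wise; `SplitPlan` raises on any
  train/test subject overlap (hard assertion, not a warning).
- `subject_kfold` deals shuffled subjects round-robin, balancing
  cohort composition across folds where counts permit; 14 subjects in
  5 folds gives sizes {3,3,3,3,2}.
- The cohort-transfer experiment partitions the *baseline* subjects
  into 5 folds; each fold trains on its baseline training subjects and
  streams the complete shifted cohort in a seeded random order. Static
  and adaptive models are strictly paired: same feature tables, same
  scaler, same stream order.
- Macro averaging for precision/recall/F1 over classes present in the
  true labels (classes are balanced by design, so macro ≈ micro);
  per-class F1 is 0 where undefined. Metrics agree with independent
  reference implementations in tests.
- Train accuracy for the adaptive model is resubstitution on the base
  set with the buffer frozen empty, i.e. the static-kNN notion.
- A repeated 70/30 subject-level holdout (`repeated_holdout_plan`) is
  provided as a preset of the same split machinery.
- Wall-clock timings are recorded as informational fields and never
  asserted; CLI-written reports null them out so artifacts are
  bit-reproducible.

## Problem sizes

The default experiments stream 900 shifted trials per fold (3 subjects
× 300 trials) against training sets of ~2400 trials; the paired
transfer experiment uses 5 folds × 3 stream seeds and the window sweep
5 folds × 5 seeds × W ∈ {0, 50, 100, 200, 400}. These sizes make the
full protocol reproducible on a single CPU in a few minutes while
keeping per-fold statistics stable (stream-order SD of accuracy is
well under one point).

## Known limitations

- Oracle-mode adaptation assumes true labels become available during
  deployment; self-training mode is implemented but its error dynamics
  (label pollution under low-confidence regimes) are not studied here.
- The shifted cohort is stationary within itself; gradual drift within
  a deployment session is only partially captured by the fatigue term.
- The long-format CSV dataset writer is intended for small datasets
  (it materializes one row per sample); the default 4200-trial dataset
  is better regenerated from its seed than stored.
- Predictions depend on stream order by design (the buffer is FIFO);
  all experiments therefore fix orders with recorded seeds.
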