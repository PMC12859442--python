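# emgadapt

Adaptive incremental k-nearest-neighbor classification of surface-EMG
(sEMG) hand-force exercises under population shift.

## The problem

sEMG gesture-recognition systems are usually trained on one population
and deployed on another. Lifestyle-related physiological differences —
for example the neuromuscular effects of chronic smoking or alcohol use
— introduce *systematic* covariate shift: elevated signal amplitude,
higher baseline noise, stronger envelope fluctuation, earlier fatigue
onset, and reorganized motor-unit recruitment. A static classifier
whose decision boundaries were learned on the source population can
collapse to near-zero accuracy on the shifted one, even when both
populations are internally easy to classify.

`emgadapt` implements, and evaluates under controlled synthetic
conditions, a lightweight remedy: an **adaptive incremental kNN**. The
model keeps the original training data as an immutable reference set
and maintains a bounded FIFO buffer of the W most recently acquired
labeled instances from the deployment stream. A query x is classified
by distance-weighted voting over its k nearest candidates, each
neighbor x_i contributing weight

    w_i = 1 / (d(x, x_i) + eps),

with d either the L1 or the Euclidean distance (defaults: k = 3, L1,
eps = 1e-8, W = 200). After every prediction the buffer is updated —
with the true label (*oracle* mode) or the model's own
confidence-gated prediction (*self-training* mode) — and pruned FIFO
back to capacity. With W = 0 the model reduces to a static kNN.

The package contains, as tested first-class components:

- `emgadapt.synthgen` — a deterministic multi-subject sEMG trial
  generator with a baseline cohort and a physiologically shifted cohort
  (14 subjects × 15 classes × 20 trials × 8 channels × 2000 samples at
  500 Hz by default);
- `emgadapt.features` — time-domain per-channel features (WAMP, AVSER,
  SSI, RMS, MAV, MMAV1, RSSQ, PKF) behind an extensible registry, with
  the minimal WAMP+AVSER tier as default;
- `emgadapt.adinc` — the classifier (static baseline + adaptive
  incremental variant);
- `emgadapt.evaluation` — strictly subject-wise splits (leakage is a
  hard assertion), cohort-transfer experiments, macro metrics with
  confusion matrices, window-size sweep, feature-tier comparison;
- `emgadapt.cli` — `emgadapt simulate | extract | evaluate | transfer |
  sweep | tiers`.

## Worked example

```python
from emgadapt import (GeneratorConfig, generate_dataset, run_cohort_experiment,
                      run_within_cohort_cv, TIER_2)
from emgadapt.adinc import ADINCConfig

cfg = GeneratorConfig(seed=1)          # 14 subjects, 15 classes, 20 trials
trials = generate_dataset(cfg)         # 11 baseline / 3 shifted subjects

baseline = run_within_cohort_cv(trials, TIER_2, seed=0)
print(f"within-baseline 5-fold CV accuracy: "
      f"{baseline['aggregate']['accuracy']['mean']:.3f}")

report = run_cohort_experiment(trials, TIER_2, ADINCConfig(window_size=200),
                               seeds=(1, 2, 3))
agg = report["aggregate"]
print(f"static kNN on shifted cohort:  {agg['static_accuracy']['mean']:.3f} "
      f"+/- {agg['static_accuracy']['sd']:.3f}")
print(f"adaptive kNN (W=200, oracle):  {agg['adinc_accuracy']['mean']:.3f} "
      f"+/- {agg['adinc_accuracy']['sd']:.3f}")
print(f"paired accuracy gap:           {agg['accuracy_gap']['mean']:.3f}")
```

prints

```
within-baseline 5-fold CV accuracy: 1.000
static kNN on shifted cohort:  0.012 +/- 0.001
adaptive kNN (W=200, oracle):  0.983 +/- 0.000
paired accuracy gap:           0.971
```

Reading: within the baseline cohort the task is easy (perfect
subject-wise CV accuracy). Transferred to the shifted cohort, the
static kNN collapses to 1.2 % — far below the 6.7 % chance level,
because the shift maps class signatures systematically onto *wrong*
baseline classes. The adaptive model, streaming the same trials in the
same order and updating its 200-instance buffer with true labels,
recovers to 98.3 %.

The same experiment from the shell:

```sh
emgadapt transfer --preset cohort_alcohol --seed 1 --out out/
```

## Documentation

`docs/methods.md` describes the signal model behind the synthetic
generator, the classifier and evaluation-protocol design choices, the
parameter defaults, and known limitations.
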