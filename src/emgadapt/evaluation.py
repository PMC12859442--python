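"""Subject-wise evaluation protocol.

Implements the experimental machinery around the classifier: strictly
subject-wise fold assignment (no individual contributes to both
training and testing — the leakage guard is a hard assertion), cohort
transfer from a baseline population to a shifted one, classification
metrics with macro averaging, the paired static-vs-adaptive cohort
experiment, the sliding-window-size sweep, and the feature-tier
comparison.

All experiments are paired: the static baseline and the adaptive model
see identical folds, identical feature tables (WAMP thresholds and the
z-scaler are fitted on the fold's training trials only) and identical
seeded stream orders.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .adinc import ADINCConfig, AdincKNN
from .features import (FeatureScaler, FeatureSpec, extract_table,
                       fit_wamp_thresholds, table_matrix)
from .synthgen import BASELINE, SHIFTED, SignalTrial

__all__ = [
    "SplitPlan", "Metrics", "SweepResult", "subject_kfold",
    "repeated_holdout_plan", "cohort_transfer_split", "compute_metrics",
    "run_within_cohort_cv", "run_cohort_experiment", "window_size_sweep",
    "compare_feature_sets", "save_report", "load_report",
]


# ---------------------------------------------------------------------------
# splits

@dataclass
class SplitPlan:
    """Train/test subject assignment for one evaluation fold."""

    train_subjects: frozenset[str]
    test_subjects: frozenset[str]
    fold_index: int = 0
    role: str = "within_population_cv"  # or "cohort_transfer"

    def __post_init__(self) -> None:
        self.train_subjects = frozenset(self.train_subjects)
        self.test_subjects = frozenset(self.test_subjects)
        overlap = self.train_subjects & self.test_subjects
        # hard leakage guard: a subject must never appear on both sides
        assert not overlap, f"subject leakage between train and test: {sorted(overlap)}"
        if not self.train_subjects or not self.test_subjects:
            raise ValueError("train and test subject sets must be non-empty")


def subject_kfold(subjects: Sequence[str], n_folds: int = 5,
                  cohort_labels: Mapping[str, str] | None = None,
                  seed: int = 0) -> list[SplitPlan]:
    """Distribute subjects across folds, balanced by cohort where possible.

    Subjects are shuffled within each cohort group and dealt round-robin
    to folds, so fold sizes differ by at most one and cohort composition
    stays as even as the counts permit.  Deterministic under ``seed``.
    """
    subjects = list(dict.fromkeys(subjects))
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > len(subjects):
        raise ValueError(f"n_folds={n_folds} exceeds number of subjects ({len(subjects)})")
    rng = np.random.default_rng(seed)
    if cohort_labels is None:
        groups = [subjects]
    else:
        by_cohort: dict[str, list[str]] = {}
        for s in subjects:
            by_cohort.setdefault(cohort_labels[s], []).append(s)
        groups = [by_cohort[c] for c in sorted(by_cohort)]
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    pos = 0
    for grp in groups:
        order = rng.permutation(len(grp))
        for j in order:
            folds[pos % n_folds].append(grp[j])
            pos += 1
    all_subjects = set(subjects)
    return [SplitPlan(frozenset(all_subjects - set(f)), frozenset(f), i,
                      "within_population_cv")
            for i, f in enumerate(folds)]


def repeated_holdout_plan(subjects: Sequence[str], test_fraction: float = 0.3,
                          n_repeats: int = 10, seed: int = 0) -> list[SplitPlan]:
    """Repeated subject-level random holdout (70/30 by default)."""
    subjects = list(dict.fromkeys(subjects))
    n_test = max(1, int(round(test_fraction * len(subjects))))
    if n_test >= len(subjects):
        raise ValueError("test_fraction leaves no training subjects")
    rng = np.random.default_rng(seed)
    plans = []
    for r in range(n_repeats):
        perm = rng.permutation(len(subjects))
        test = frozenset(subjects[i] for i in perm[:n_test])
        train = frozenset(subjects[i] for i in perm[n_test:])
        plans.append(SplitPlan(train, test, r, "within_population_cv"))
    return plans


def cohort_transfer_split(trials: Sequence[SignalTrial],
                          train_cohort: str = BASELINE,
                          test_cohort: str = SHIFTED) -> SplitPlan:
    """All subjects of one cohort train, all of the other test."""
    train = {t.subject_id for t in trials if t.cohort == train_cohort}
    test = {t.subject_id for t in trials if t.cohort == test_cohort}
    if not train or not test:
        raise ValueError(f"empty cohort: train={train_cohort!r} has {len(train)} "
                         f"subjects, test={test_cohort!r} has {len(test)}")
    return SplitPlan(frozenset(train), frozenset(test), 0, "cohort_transfer")


# ---------------------------------------------------------------------------
# metrics

@dataclass
class Metrics:
    """Classification metrics bundle for one evaluation.

    The confusion matrix has rows = true class, columns = predicted
    class; macro averages run over the classes present in the true
    labels, with per-class F1 set to 0 where undefined.
    """

    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion_matrix: np.ndarray
    train_accuracy: float | None = None
    prediction_time_s: float | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "confusion_matrix": np.asarray(self.confusion_matrix).tolist(),
            "train_accuracy": self.train_accuracy,
            "prediction_time_s": self.prediction_time_s,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Metrics":
        return cls(d["accuracy"], d["macro_precision"], d["macro_recall"],
                   d["macro_f1"], np.asarray(d["confusion_matrix"], dtype=int),
                   d.get("train_accuracy"), d.get("prediction_time_s"))


def compute_metrics(y_true, y_pred, n_classes: int) -> Metrics:
    """Accuracy, macro precision/recall/F1 and the confusion matrix."""
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_pred = np.asarray(y_pred, dtype=int).ravel()
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred length mismatch")
    if len(y_true) == 0:
        raise ValueError("cannot compute metrics on empty label vectors")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    accuracy = float(np.trace(cm)) / len(y_true)
    present = np.unique(y_true)
    diag = np.diag(cm).astype(float)
    col = cm.sum(axis=0).astype(float)
    row = cm.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(col > 0, diag / np.maximum(col, 1), 0.0)
        rec = np.where(row > 0, diag / np.maximum(row, 1), 0.0)
        denom = prec + rec
        f1 = np.where(denom > 0, 2 * prec * rec / np.maximum(denom, 1e-300), 0.0)
    return Metrics(accuracy=accuracy,
                   macro_precision=float(prec[present].mean()),
                   macro_recall=float(rec[present].mean()),
                   macro_f1=float(f1[present].mean()),
                   confusion_matrix=cm)


def _aggregate(values: Sequence[float]) -> dict:
    arr = np.asarray(values, dtype=float)
    return {"mean": float(arr.mean()), "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0}


# ---------------------------------------------------------------------------
# fold preparation

def _trials_for(trials: Sequence[SignalTrial], subjects: frozenset[str]) -> list[SignalTrial]:
    return [t for t in trials if t.subject_id in subjects]


def _prepare_fold(train_trials: Sequence[SignalTrial],
                  test_trials: Sequence[SignalTrial],
                  spec: FeatureSpec, sampling_rate: float):
    """Fit thresholds + scaler on training trials, featurize both sides."""
    thr = (fit_wamp_thresholds(train_trials)
           if "WAMP" in spec.feature_list and spec.wamp_threshold is None else None)
    ftr = extract_table(train_trials, spec, thr, sampling_rate)
    fte = extract_table(test_trials, spec, thr, sampling_rate)
    Xtr, mtr = table_matrix(ftr)
    Xte, mte = table_matrix(fte)
    scaler = FeatureScaler().fit(Xtr)
    return (scaler.transform(Xtr), mtr["class_label"].to_numpy(int), mtr,
            scaler.transform(Xte), mte["class_label"].to_numpy(int), mte)


def _static_batch(model: AdincKNN, X: np.ndarray, weighted: bool = False) -> np.ndarray:
    return np.array([model.static_predict(x, weighted=weighted).label for x in X], dtype=int)


def _resubstitution_accuracy(model: AdincKNN, X: np.ndarray, y: np.ndarray) -> float:
    """Train accuracy with the buffer frozen empty (base-set resubstitution)."""
    pred = _static_batch(model, X, weighted=False)
    return float(np.mean(pred == y))


# ---------------------------------------------------------------------------
# experiments

def run_within_cohort_cv(trials: Sequence[SignalTrial], spec: FeatureSpec,
                         knn_config: ADINCConfig | None = None,
                         cohort: str = BASELINE, n_folds: int = 5,
                         seed: int = 0, sampling_rate: float = 500.0) -> dict:
    """Subject-wise k-fold CV of the static kNN within one cohort."""
    knn_config = knn_config or ADINCConfig(window_size=0)
    pool = [t for t in trials if t.cohort == cohort]
    subjects = sorted({t.subject_id for t in pool})
    n_classes = max(t.class_label for t in pool) + 1
    plans = subject_kfold(subjects, n_folds, seed=seed)
    folds = []
    for plan in plans:
        Xtr, ytr, _, Xte, yte, _ = _prepare_fold(
            _trials_for(pool, plan.train_subjects),
            _trials_for(pool, plan.test_subjects), spec, sampling_rate)
        model = AdincKNN(knn_config).fit(Xtr, ytr)
        t0 = time.perf_counter()
        pred = _static_batch(model, Xte)
        m = compute_metrics(yte, pred, n_classes)
        m.prediction_time_s = time.perf_counter() - t0
        m.train_accuracy = _resubstitution_accuracy(model, Xtr, ytr)
        folds.append({"fold": plan.fold_index,
                      "test_subjects": sorted(plan.test_subjects),
                      "metrics": m.to_dict()})
    return {
        "experiment": "within_cohort_cv", "cohort": cohort, "seed": seed,
        "spec": spec.name, "n_folds": n_folds,
        "folds": folds,
        "aggregate": {"accuracy": _aggregate([f["metrics"]["accuracy"] for f in folds]),
                      "macro_f1": _aggregate([f["metrics"]["macro_f1"] for f in folds])},
    }


def run_cohort_experiment(trials: Sequence[SignalTrial], spec: FeatureSpec,
                          adinc_config: ADINCConfig | None = None,
                          seeds: Sequence[int] = (1, 2, 3), n_folds: int = 5,
                          split_seed: int = 0, sampling_rate: float = 500.0,
                          with_train_accuracy: bool = True) -> dict:
    """Paired static-kNN vs adaptive-kNN cohort-transfer experiment.

    Folds partition the *baseline* subjects; each fold trains on its
    baseline training subjects and streams the full shifted cohort in a
    seeded random order.  The static baseline and the adaptive model
    consume identical feature tables and stream orders.
    """
    adinc_config = adinc_config or ADINCConfig()
    transfer = cohort_transfer_split(trials)  # validates both cohorts non-empty
    base_pool = _trials_for(trials, transfer.train_subjects)
    test_pool = _trials_for(trials, transfer.test_subjects)
    n_classes = max(t.class_label for t in trials) + 1
    plans = subject_kfold(sorted(transfer.train_subjects), n_folds, seed=split_seed)

    records = []
    for plan in plans:
        train_trials = _trials_for(base_pool, plan.train_subjects)
        Xtr, ytr, _, Xte, yte, mte = _prepare_fold(train_trials, test_pool,
                                                   spec, sampling_rate)
        # leakage guard across the transfer boundary
        eval_plan = SplitPlan(plan.train_subjects,
                              transfer.test_subjects, plan.fold_index, "cohort_transfer")
        test_subject_ids = mte["subject_id"].to_numpy()
        train_acc = None
        if with_train_accuracy:
            probe = AdincKNN(adinc_config).fit(Xtr, ytr)
            train_acc = _resubstitution_accuracy(probe, Xtr, ytr)
        for stream_seed in seeds:
            order = np.random.default_rng((stream_seed, plan.fold_index)).permutation(len(yte))
            Xs, ys, sids = Xte[order], yte[order], test_subject_ids[order]

            static_model = AdincKNN(adinc_config).fit(Xtr, ytr)
            t0 = time.perf_counter()
            static_pred = _static_batch(static_model, Xs)
            static_m = compute_metrics(ys, static_pred, n_classes)
            static_m.prediction_time_s = time.perf_counter() - t0
            static_m.train_accuracy = train_acc

            adinc_model = AdincKNN(adinc_config).fit(Xtr, ytr)
            t0 = time.perf_counter()
            preds = adinc_model.predict_stream(Xs, labels=ys, subject_ids=sids)
            adinc_m = compute_metrics(ys, [p.label for p in preds], n_classes)
            adinc_m.prediction_time_s = time.perf_counter() - t0
            adinc_m.train_accuracy = train_acc

            records.append({"fold": plan.fold_index, "stream_seed": stream_seed,
                            "train_subjects": sorted(eval_plan.train_subjects),
                            "test_subjects": sorted(eval_plan.test_subjects),
                            "static": static_m.to_dict(), "adinc": adinc_m.to_dict()})

    static_acc = [r["static"]["accuracy"] for r in records]
    adinc_acc = [r["adinc"]["accuracy"] for r in records]
    gaps = [a - s for a, s in zip(adinc_acc, static_acc)]
    return {
        "experiment": "cohort_transfer",
        "config": {"adinc": _cfg_dict(adinc_config), "spec": spec.name,
                   "n_folds": n_folds, "split_seed": split_seed,
                   "stream_seeds": list(seeds)},
        "records": records,
        "aggregate": {
            "static_accuracy": _aggregate(static_acc),
            "adinc_accuracy": _aggregate(adinc_acc),
            "accuracy_gap": _aggregate(gaps),
            "static_macro_f1": _aggregate([r["static"]["macro_f1"] for r in records]),
            "adinc_macro_f1": _aggregate([r["adinc"]["macro_f1"] for r in records]),
        },
    }


@dataclass
class SweepResult:
    """Per-window-size paired train/test metrics."""

    window_sizes: list[int]
    rows: list[dict]

    def to_dict(self) -> dict:
        return {"window_sizes": self.window_sizes, "rows": self.rows}


def window_size_sweep(trials: Sequence[SignalTrial], spec: FeatureSpec,
                      sizes: Sequence[int] = (0, 50, 100, 200, 400),
                      adinc_config: ADINCConfig | None = None,
                      seeds: Sequence[int] = (1,), n_folds: int = 5,
                      split_seed: int = 0, sampling_rate: float = 500.0) -> SweepResult:
    """Cohort-transfer accuracy as a function of buffer capacity W.

    The W=0 row is the static (weighted-vote) limit by construction;
    all sizes share feature tables and stream orders within a fold.
    """
    if not sizes:
        raise ValueError("sizes must be non-empty")
    adinc_config = adinc_config or ADINCConfig()
    import dataclasses as _dc
    transfer = cohort_transfer_split(trials)
    base_pool = _trials_for(trials, transfer.train_subjects)
    test_pool = _trials_for(trials, transfer.test_subjects)
    n_classes = max(t.class_label for t in trials) + 1
    plans = subject_kfold(sorted(transfer.train_subjects), n_folds, seed=split_seed)

    per_size: dict[int, list[dict]] = {int(w): [] for w in sizes}
    for plan in plans:
        Xtr, ytr, _, Xte, yte, mte = _prepare_fold(
            _trials_for(base_pool, plan.train_subjects), test_pool, spec, sampling_rate)
        # resubstitution train accuracy uses a frozen-empty buffer, so it
        # is independent of W: compute once per fold
        probe = AdincKNN(adinc_config).fit(Xtr, ytr)
        train_acc = _resubstitution_accuracy(probe, Xtr, ytr)
        for stream_seed in seeds:
            order = np.random.default_rng((stream_seed, plan.fold_index)).permutation(len(yte))
            Xs, ys = Xte[order], yte[order]
            for w in sizes:
                cfg = _dc.replace(adinc_config, window_size=int(w))
                model = AdincKNN(cfg).fit(Xtr, ytr)
                preds = model.predict_stream(Xs, labels=ys)
                m = compute_metrics(ys, [p.label for p in preds], n_classes)
                m.train_accuracy = train_acc
                per_size[int(w)].append(m)
    rows = []
    for w in sizes:
        ms = per_size[int(w)]
        test_acc = _aggregate([m.accuracy for m in ms])
        train_acc = _aggregate([m.train_accuracy for m in ms])
        rows.append({"window_size": int(w),
                     "test_accuracy": test_acc, "train_accuracy": train_acc,
                     "macro_f1": _aggregate([m.macro_f1 for m in ms]),
                     "overfit_gap": train_acc["mean"] - test_acc["mean"]})
    return SweepResult([int(w) for w in sizes], rows)


def compare_feature_sets(trials: Sequence[SignalTrial], specs: Sequence[FeatureSpec],
                         knn_config: ADINCConfig | None = None, n_folds: int = 5,
                         seed: int = 0, cohort: str = BASELINE,
                         sampling_rate: float = 500.0) -> dict:
    """Within-cohort CV of the static kNN under each feature tier (paired folds)."""
    if len(specs) < 2:
        raise ValueError("need at least two feature specs to compare")
    rows = []
    for spec in specs:
        t0 = time.perf_counter()
        rep = run_within_cohort_cv(trials, spec, knn_config, cohort, n_folds,
                                   seed, sampling_rate)
        rows.append({"spec": spec.name, "n_dims": None,
                     "aggregate": rep["aggregate"],
                     "folds": rep["folds"],
                     "wall_time_s": time.perf_counter() - t0})
    return {"experiment": "feature_tiers", "seed": seed, "n_folds": n_folds,
            "rows": rows}


def _cfg_dict(cfg) -> dict:
    import dataclasses as _dc
    return _dc.asdict(cfg)


def strip_timing(obj):
    """Return a copy with wall-clock fields nulled.

    Timings are informational and hardware-dependent; stripping them
    makes report artifacts bit-reproducible across runs.
    """
    if isinstance(obj, dict):
        return {k: (None if k in ("prediction_time_s", "wall_time_s")
                    else strip_timing(v)) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [strip_timing(v) for v in obj]
    return obj


def save_report(path, report: Mapping, *, reproducible: bool = False) -> None:
    if reproducible:
        report = strip_timing(report)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def load_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
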