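"""Adaptive incremental k-nearest-neighbor classification.

The classifier keeps an immutable *base* reference set (the initial
training data) and a bounded FIFO *buffer* of recently acquired labeled
instances.  At query time the candidate pool is the union of base set
and buffer (configurable to buffer-only); the k nearest candidates vote
with weights

    w_i = 1 / (d(x, x_i) + eps)

so that nearer neighbors dominate.  After each streamed prediction the
buffer is updated — with the true label (*oracle* mode) or with the
model's own prediction gated by a confidence threshold
(*self_training* mode) — and pruned FIFO back to its capacity W.  With
W = 0 the model degenerates exactly to a static kNN with weighted
voting; a separate unweighted-majority static predictor is provided as
the conventional baseline.

Determinism: ties in the k-th distance are broken by smaller base /
arrival index, ties in vote mass by smallest class id.
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

METRICS = ("l1", "l2")
LABEL_MODES = ("oracle", "self_training")


def distance(a, b, metric: str = "l1") -> float:
    """Pointwise L1 (cityblock) or L2 (Euclidean) distance."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if metric == "l1":
        return float(np.abs(a - b).sum())
    if metric == "l2":
        return float(np.sqrt(((a - b) ** 2).sum()))
    raise ValueError(f"unknown metric {metric!r}")


def neighbor_weight(d: float, epsilon: float) -> float:
    """Inverse-distance vote weight 1 / (d + eps)."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    return 1.0 / (d + epsilon)


def _pool_distances(X: np.ndarray, x: np.ndarray, metric: str) -> np.ndarray:
    diff = X - x[None, :]
    if metric == "l1":
        return np.abs(diff).sum(axis=1)
    if metric == "l2":
        return np.sqrt((diff * diff).sum(axis=1))
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class LabeledInstance:
    """One stored training / buffered example."""

    values: np.ndarray
    label: int
    subject_id: str | None = None
    arrival_index: int = -1
    label_source: str = "ground_truth"  # or "predicted"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.isfinite(self.values).all():
            raise ValueError("instance values must be finite")


class AdaptiveBuffer:
    """Bounded FIFO store of labeled instances.

    Eviction always removes the entry with the smallest arrival index,
    so after any update the buffer holds the W most recent appends.
    """

    def __init__(self, capacity: int):
        if capacity < 0:
            raise ValueError("capacity must be >= 0")
        self.capacity = int(capacity)
        self._entries: deque[LabeledInstance] = deque()

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def entries(self) -> tuple[LabeledInstance, ...]:
        return tuple(self._entries)

    def append(self, instance: LabeledInstance) -> None:
        self._entries.append(instance)
        while len(self._entries) > self.capacity:
            self._entries.popleft()

    def clear(self) -> None:
        self._entries.clear()

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(values matrix, labels, arrival indices) in arrival order."""
        if not self._entries:
            return (np.empty((0, 0)), np.empty(0, dtype=int), np.empty(0, dtype=int))
        X = np.stack([e.values for e in self._entries])
        y = np.array([e.label for e in self._entries], dtype=int)
        idx = np.array([e.arrival_index for e in self._entries], dtype=int)
        return X, y, idx


@dataclass(frozen=True)
class ADINCConfig:
    """Hyper-parameters of the adaptive incremental kNN."""

    k: int = 3
    metric: str = "l1"
    epsilon: float = 1e-8
    window_size: int = 200
    label_mode: str = "oracle"
    confidence_gate: float = 0.8
    include_base_set: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.window_size < 0:
            raise ValueError("window_size must be >= 0")
        if self.label_mode not in LABEL_MODES:
            raise ValueError(f"label_mode must be one of {LABEL_MODES}")
        if not 0.0 <= self.confidence_gate <= 1.0:
            raise ValueError("confidence_gate must be in [0, 1]")


@dataclass
class Prediction:
    """Outcome of one query: label, per-class vote mass, confidence."""

    label: int
    class_weight_mass: dict[int, float]
    confidence: float
    neighbor_ids: list[tuple[str, int]]  # ("base"|"buffer", base row / arrival index)


class AdincKNN:
    """Adaptive incremental kNN with FIFO buffer and weighted voting."""

    def __init__(self, config: ADINCConfig | None = None):
        self.config = config or ADINCConfig()
        self._base_X: np.ndarray | None = None
        self._base_y: np.ndarray | None = None
        self.buffer = AdaptiveBuffer(self.config.window_size)
        self._arrival_counter = 0
        self.classes_: np.ndarray | None = None
        self._warned_small_pool = False

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y, subject_ids: Sequence[str] | None = None) -> "AdincKNN":
        """Store the immutable base reference set and reset the buffer."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int).ravel()
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("training set must be a non-empty 2-D matrix")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if X.shape[0] < self.config.k:
            raise ValueError(f"need at least k={self.config.k} training instances")
        if not np.isfinite(X).all():
            raise ValueError("training values must be finite")
        self._base_X = X.copy()
        self._base_y = y.copy()
        self.classes_ = np.unique(y)
        self.buffer = AdaptiveBuffer(self.config.window_size)
        self._arrival_counter = 0
        return self

    @property
    def is_fitted(self) -> bool:
        return self._base_X is not None

    def _require_fitted(self) -> None:
        if not self.is_fitted:
            raise ValueError("model is not fitted")

    # -- prediction -------------------------------------------------------

    def _candidate_pool(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[tuple[str, int]]]:
        """Pool matrix, labels, tie-break order and provenance ids.

        Base rows come first (order = row index); buffer entries follow
        in arrival order, so the tie-break prefers older references.
        """
        bX, by, bidx = self.buffer.arrays()
        use_buffer_only = (not self.config.include_base_set
                           and len(self.buffer) >= self.config.k)
        if use_buffer_only:
            ids = [("buffer", int(i)) for i in bidx]
            return bX, by, np.arange(len(by)), ids
        if len(self.buffer) == 0:
            ids = [("base", i) for i in range(len(self._base_y))]
            return self._base_X, self._base_y, np.arange(len(self._base_y)), ids
        X = np.vstack([self._base_X, bX])
        y = np.concatenate([self._base_y, by])
        ids = ([("base", i) for i in range(len(self._base_y))]
               + [("buffer", int(i)) for i in bidx])
        return X, y, np.arange(len(y)), ids

    def _vote(self, dists: np.ndarray, labels: np.ndarray, order: np.ndarray,
              ids: list[tuple[str, int]], weighted: bool) -> Prediction:
        k = self.config.k
        if len(labels) < k:
            if not self._warned_small_pool:
                logger.warning("candidate pool (%d) smaller than k=%d; using full pool",
                               len(labels), k)
                self._warned_small_pool = True
            k = len(labels)
        sel = np.lexsort((order, dists))[:k]
        mass: dict[int, float] = {}
        for i in sel:
            w = neighbor_weight(dists[i], self.config.epsilon) if weighted else 1.0
            mass[int(labels[i])] = mass.get(int(labels[i]), 0.0) + w
        total = sum(mass.values())
        # ties in vote mass break toward the smallest class id
        label = min(mass, key=lambda c: (-mass[c], c))
        return Prediction(label=label, class_weight_mass=mass,
                          confidence=mass[label] / total,
                          neighbor_ids=[ids[i] for i in sel])

    def predict_one(self, x) -> Prediction:
        """Distance-weighted vote over the k nearest pool candidates."""
        self._require_fitted()
        x = np.asarray(x, dtype=float).ravel()
        X, y, order, ids = self._candidate_pool()
        dists = _pool_distances(X, x, self.config.metric)
        return self._vote(dists, y, order, ids, weighted=True)

    def static_predict(self, x, weighted: bool = False) -> Prediction:
        """Static kNN over the base set only (buffer ignored).

        ``weighted=False`` (default) is the conventional unweighted
        majority-vote baseline; ``weighted=True`` is the static limit of
        the adaptive model, identical to :meth:`predict_one` with W=0.
        """
        self._require_fitted()
        x = np.asarray(x, dtype=float).ravel()
        dists = _pool_distances(self._base_X, x, self.config.metric)
        ids = [("base", i) for i in range(len(self._base_y))]
        return self._vote(dists, self._base_y, np.arange(len(self._base_y)),
                          ids, weighted=weighted)

    # -- adaptation -------------------------------------------------------

    def update(self, x, label: int | None = None,
               prediction: Prediction | None = None,
               subject_id: str | None = None) -> bool:
        """Append a newly acquired instance to the buffer (FIFO-pruned).

        Returns True if an append occurred.  In oracle mode ``label``
        (the true label) is required; in self_training mode the
        ``prediction`` is stored instead, gated by its confidence.
        """
        self._require_fitted()
        x = np.asarray(x, dtype=float).ravel()
        mode = self.config.label_mode
        if mode == "oracle":
            if label is None:
                raise ValueError("oracle mode requires the true label")
            stored, source = int(label), "ground_truth"
        else:
            if prediction is None:
                prediction = self.predict_one(x)
            if prediction.confidence < self.config.confidence_gate:
                return False
            stored, source = prediction.label, "predicted"
        if self.config.window_size == 0:
            return False
        inst = LabeledInstance(x, stored, subject_id,
                               arrival_index=self._arrival_counter, label_source=source)
        self._arrival_counter += 1
        self.buffer.append(inst)
        return True

    def predict_stream(self, X, labels: Sequence[int] | None = None,
                       subject_ids: Sequence[str] | None = None) -> list[Prediction]:
        """Predict-then-update over an ordered stream.

        Predictions depend on the stream order (deterministically so);
        the caller fixes the order, typically with a seeded shuffle.
        """
        self._require_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(0, 0) if X.size == 0 else X.reshape(1, -1)
        if self.config.label_mode == "oracle":
            if labels is None:
                raise ValueError("oracle mode requires stream labels")
            labels = np.asarray(labels, dtype=int).ravel()
            if len(labels) != len(X):
                raise ValueError("labels length mismatch")
        preds: list[Prediction] = []
        for i in range(len(X)):
            p = self.predict_one(X[i])
            preds.append(p)
            sid = subject_ids[i] if subject_ids is not None else None
            if self.config.label_mode == "oracle":
                self.update(X[i], label=int(labels[i]), subject_id=sid)
            else:
                self.update(X[i], prediction=p, subject_id=sid)
        return preds

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        self._require_fitted()
        return {
            "config": dataclasses_asdict(self.config),
            "base_X": self._base_X.tolist(),
            "base_y": self._base_y.tolist(),
            "arrival_counter": self._arrival_counter,
            "buffer": [{
                "values": e.values.tolist(), "label": e.label,
                "subject_id": e.subject_id, "arrival_index": e.arrival_index,
                "label_source": e.label_source,
            } for e in self.buffer.entries],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AdincKNN":
        model = cls(ADINCConfig(**d["config"]))
        model.fit(np.asarray(d["base_X"], dtype=float), np.asarray(d["base_y"], dtype=int))
        model._arrival_counter = int(d["arrival_counter"])
        for e in d["buffer"]:
            model.buffer.append(LabeledInstance(
                np.asarray(e["values"], dtype=float), int(e["label"]),
                e["subject_id"], int(e["arrival_index"]), e["label_source"]))
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "AdincKNN":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def dataclasses_asdict(cfg) -> dict:
    import dataclasses as _dc
    return _dc.asdict(cfg)
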