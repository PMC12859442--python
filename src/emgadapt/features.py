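"""Time-domain sEMG feature extraction.

Implements the named per-channel features used throughout the package
— WAMP, AVSER, SSI, RMS, MAV, MMAV1, RSSQ, PKF — behind an extensible
registry, plus per-trial feature-vector assembly under a selectable
:class:`FeatureSpec` tier and a train-set-fitted z-scaler.

Each single-feature operation takes one channel's samples (a real
vector of at least two points) and returns a scalar.  Definitions are
the standard ones from the sEMG feature-engineering literature:

WAMP(x; t)   = sum_i 1[|x_{i+1} - x_i| >= t]          (Wilson amplitude)
AVSER(x; p)  = | sum_i sgn(x_i) |x_i|^p |             (default p = 0.75)
SSI(x)       = sum_i x_i^2
RMS(x)       = sqrt(mean x_i^2)
MAV(x)       = mean |x_i|
MMAV1(x)     = (1/N) sum_i w_i |x_i|,  w_i = 1 for 0.25N <= i <= 0.75N
               (1-based i), else 0.5
RSSQ(x)      = sqrt(sum x_i^2)
PKF(x; fs)   = argmax-frequency of the periodogram, Hz
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .synthgen import SignalTrial

__all__ = [
    "wamp", "avser", "ssi", "rms", "mav", "mmav1", "rssq", "pkf",
    "FeatureSpec", "FeatureVector", "FeatureScaler", "TIER_2", "TIER_8",
    "register_feature", "available_features", "fit_wamp_thresholds",
    "extract_features", "extract_table", "table_matrix",
    "write_table", "read_table",
]


def _as_channel(x, min_len: int, op: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_len:
        raise ValueError(f"{op} requires at least {min_len} samples, got {x.size}")
    return x


def wamp(x, threshold: float) -> int:
    """Wilson amplitude: count of consecutive differences >= threshold."""
    x = _as_channel(x, 2, "wamp")
    if threshold < 0:
        raise ValueError("wamp threshold must be >= 0")
    return int(np.count_nonzero(np.abs(np.diff(x)) >= threshold))


def avser(x, exponent: float = 0.75) -> float:
    """Absolute value of the summation of the signed fractional-power root."""
    x = _as_channel(x, 1, "avser")
    if exponent <= 0:
        raise ValueError("avser exponent must be > 0")
    return float(abs(np.sum(np.sign(x) * np.abs(x) ** exponent)))


def ssi(x) -> float:
    """Simple square integral (signal energy)."""
    x = _as_channel(x, 1, "ssi")
    return float(np.sum(x * x))


def rms(x) -> float:
    """Root mean square."""
    x = _as_channel(x, 1, "rms")
    return float(np.sqrt(np.mean(x * x)))


def mav(x) -> float:
    """Mean absolute value."""
    x = _as_channel(x, 1, "mav")
    return float(np.mean(np.abs(x)))


def rssq(x) -> float:
    """Root sum of squares."""
    x = _as_channel(x, 1, "rssq")
    return float(np.sqrt(np.sum(x * x)))


def mmav1(x) -> float:
    """Modified MAV: full weight in the middle half, half weight at edges."""
    x = _as_channel(x, 4, "mmav1")
    n = x.size
    i = np.arange(1, n + 1)
    w = np.where((i >= 0.25 * n) & (i <= 0.75 * n), 1.0, 0.5)
    return float(np.sum(w * np.abs(x)) / n)


def pkf(x, sampling_rate: float) -> float:
    """Peak frequency: argmax of the full-length periodogram, in Hz."""
    x = _as_channel(x, 8, "pkf")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    freqs, pxx = periodogram(x, fs=sampling_rate, detrend=False)
    return float(freqs[int(np.argmax(pxx))])


# ---------------------------------------------------------------------------
# registry and spec

@dataclass(frozen=True)
class _FeatureContext:
    sampling_rate: float
    wamp_threshold: float
    avser_exponent: float


_REGISTRY: dict[str, Callable[[np.ndarray, _FeatureContext], float]] = {
    "WAMP": lambda x, ctx: wamp(x, ctx.wamp_threshold),
    "AVSER": lambda x, ctx: avser(x, ctx.avser_exponent),
    "SSI": lambda x, ctx: ssi(x),
    "RMS": lambda x, ctx: rms(x),
    "MAV": lambda x, ctx: mav(x),
    "MMAV1": lambda x, ctx: mmav1(x),
    "RSSQ": lambda x, ctx: rssq(x),
    "PKF": lambda x, ctx: pkf(x, ctx.sampling_rate),
}


def register_feature(name: str,
                     fn: Callable[[np.ndarray, _FeatureContext], float]) -> None:
    """Register an additional per-channel feature (extensibility hook
    toward the larger feature sets of the wider sEMG literature)."""
    if name in _REGISTRY:
        raise ValueError(f"feature {name!r} already registered")
    _REGISTRY[name] = fn


def available_features() -> tuple[str, ...]:
    return tuple(_REGISTRY)


@dataclass(frozen=True)
class FeatureSpec:
    """Named, ordered selection of per-channel features.

    ``wamp_threshold=None`` means the threshold is data-driven and must
    be supplied at extraction time (see :func:`fit_wamp_thresholds`).
    """

    name: str
    feature_list: tuple[str, ...]
    wamp_threshold: float | None = None
    avser_exponent: float = 0.75

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_list", tuple(self.feature_list))
        if not self.feature_list:
            raise ValueError("feature_list must be non-empty")
        if len(set(self.feature_list)) != len(self.feature_list):
            raise ValueError("feature_list contains duplicates")
        unknown = [f for f in self.feature_list if f not in _REGISTRY]
        if unknown:
            raise ValueError(f"unknown feature identifiers {unknown}; "
                             f"known: {sorted(_REGISTRY)}")
        if self.wamp_threshold is not None and self.wamp_threshold < 0:
            raise ValueError("wamp_threshold must be >= 0")
        if self.avser_exponent <= 0:
            raise ValueError("avser_exponent must be > 0")


#: the two top-ranked features — the minimal tier
TIER_2 = FeatureSpec("tier2", ("WAMP", "AVSER"))
#: the intermediate eight-feature tier
TIER_8 = FeatureSpec("tier8", ("SSI", "RMS", "MAV", "MMAV1", "WAMP", "AVSER", "RSSQ", "PKF"))

TIERS: dict[str, FeatureSpec] = {"tier2": TIER_2, "tier8": TIER_8}


@dataclass
class FeatureVector:
    """Per-trial feature values, channel-major (ch0·f0, ch0·f1, …, ch1·f0, …)."""

    subject_id: str
    cohort: str
    class_label: int
    trial_index: int
    values: np.ndarray
    spec_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("feature vector contains non-finite values")


def fit_wamp_thresholds(trials: Sequence[SignalTrial], fraction: float = 0.05) -> np.ndarray:
    """Data-driven WAMP thresholds: ``fraction`` x the pooled per-channel SD.

    Fit on *training* trials only, never on test or buffered data, so
    the thresholds carry no information about the deployment stream.
    """
    if not trials:
        raise ValueError("cannot fit thresholds on an empty trial collection")
    n_channels = trials[0].samples.shape[0]
    total = np.zeros(n_channels)
    total_sq = np.zeros(n_channels)
    count = 0
    for tr in trials:
        if tr.samples.shape[0] != n_channels:
            raise ValueError("heterogeneous channel counts across trials")
        total += tr.samples.sum(axis=1)
        total_sq += (tr.samples ** 2).sum(axis=1)
        count += tr.samples.shape[1]
    var = total_sq / count - (total / count) ** 2
    return fraction * np.sqrt(np.clip(var, 0.0, None))


def _resolve_thresholds(spec: FeatureSpec, n_channels: int,
                        wamp_thresholds) -> np.ndarray:
    if wamp_thresholds is not None:
        thr = np.broadcast_to(np.asarray(wamp_thresholds, dtype=float), (n_channels,))
        return thr.copy()
    if spec.wamp_threshold is not None:
        return np.full(n_channels, float(spec.wamp_threshold))
    if "WAMP" in spec.feature_list:
        raise ValueError("WAMP requested but no threshold available: pass "
                         "wamp_thresholds= (see fit_wamp_thresholds) or set "
                         "spec.wamp_threshold")
    return np.zeros(n_channels)


def extract_features(trial: SignalTrial, spec: FeatureSpec,
                     wamp_thresholds=None,
                     sampling_rate: float = 500.0) -> FeatureVector:
    """Compute the per-trial feature vector in channel-major order."""
    C = trial.samples.shape[0]
    thr = _resolve_thresholds(spec, C, wamp_thresholds)
    values = np.empty(C * len(spec.feature_list))
    pos = 0
    for ch in range(C):
        ctx = _FeatureContext(sampling_rate, thr[ch], spec.avser_exponent)
        x = trial.samples[ch]
        for feat in spec.feature_list:
            values[pos] = _REGISTRY[feat](x, ctx)
            pos += 1
    return FeatureVector(trial.subject_id, trial.cohort, trial.class_label,
                         trial.trial_index, values, spec.name)


_META_COLUMNS = ["subject_id", "cohort", "class_label", "trial_index"]


def feature_columns(n_channels: int, spec: FeatureSpec) -> list[str]:
    return [f"ch{ch}_{feat}" for ch in range(n_channels) for feat in spec.feature_list]


def extract_table(trials: Sequence[SignalTrial], spec: FeatureSpec,
                  wamp_thresholds=None, sampling_rate: float = 500.0) -> pd.DataFrame:
    """One feature row per trial, order-preserving.

    Columns: subject_id, cohort, class_label, trial_index, then one
    column per feature dimension named ``ch<i>_<FEATURE>``.
    """
    if len(trials) == 0:
        return pd.DataFrame(columns=_META_COLUMNS)
    C = trials[0].samples.shape[0]
    if any(tr.samples.shape[0] != C for tr in trials):
        raise ValueError("heterogeneous channel counts across trials")
    rows = np.empty((len(trials), C * len(spec.feature_list)))
    meta = []
    for i, tr in enumerate(trials):
        fv = extract_features(tr, spec, wamp_thresholds, sampling_rate)
        rows[i] = fv.values
        meta.append((tr.subject_id, tr.cohort, tr.class_label, tr.trial_index))
    df = pd.DataFrame(meta, columns=_META_COLUMNS)
    return pd.concat([df, pd.DataFrame(rows, columns=feature_columns(C, spec))], axis=1)


def table_matrix(table: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Split a feature table into (values matrix, metadata frame)."""
    feat_cols = [c for c in table.columns if c not in _META_COLUMNS]
    return table[feat_cols].to_numpy(dtype=float), table[_META_COLUMNS].copy()


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format="%.12g")


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed feature table {path}: missing columns {missing}")
    return df


@dataclass
class FeatureScaler:
    """Per-dimension z-scoring fitted on the initial training set only.

    kNN distances are scale-sensitive; fitting the scaler on training
    data alone prevents leakage from the deployment stream.
    """

    mean_: np.ndarray | None = None
    sd_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("scaler requires a non-empty 2-D matrix")
        self.mean_ = X.mean(axis=0)
        self.sd_ = np.maximum(X.std(axis=0), 1e-12)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValueError("scaler is not fitted")
        return (np.asarray(X, dtype=float) - self.mean_) / self.sd_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def to_dict(self) -> dict:
        return {"mean": self.mean_.tolist(), "sd": self.sd_.tolist()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureScaler":
        sc = cls()
        sc.mean_ = np.asarray(d["mean"], dtype=float)
        sc.sd_ = np.asarray(d["sd"], dtype=float)
        return sc
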