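"""Synthetic surface-EMG trial generator.

Emulates a hand-force-exercise acquisition: multiple subjects, each
performing a set of exercise classes many times, recorded on several
forearm channels at a fixed sampling rate.  A trial is band-limited
zero-mean noise (the interference-pattern carrier) multiplied by a
class- and channel-specific burst envelope, plus additive baseline
noise.  Class identity is encoded in the per-channel burst duty cycle
and amplitude, mimicking differential recruitment of forearm muscles
across exercises.

Two cohorts are supported.  The *baseline* cohort is generated as-is;
the *shifted* cohort applies a :class:`ShiftProfile` — elevated signal
amplitude, a higher baseline-noise floor, deeper envelope fluctuation,
and a linear amplitude drift from an earlier fatigue onset — the
hallmarks of lifestyle-related neuromuscular change (e.g. smoking or
alcohol use) in deployed myoelectric systems.

Generation is fully deterministic: identical (config, seed) pairs give
bit-identical datasets, and the random draws are independent of cohort
so an identity ShiftProfile reproduces the baseline cohort exactly.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

logger = logging.getLogger(__name__)

BASELINE = "baseline"
SHIFTED = "shifted"
COHORTS = (BASELINE, SHIFTED)

# sub-seed keys, fixed forever so datasets are reproducible across versions
_CLASS_KEY = 101
_SUBJECT_KEY = 202
_TRIAL_KEY = 303


@dataclass(frozen=True)
class ShiftProfile:
    """Multiplicative distortions applied to the shifted cohort.

    amplitude_gain
        Gain (>= 1) on the activation envelope.
    noise_floor_gain
        Gain (>= 1) on the baseline-noise standard deviation.
    fluctuation_gain
        Gain (>= 1) on the slow envelope-modulation depth.
    fatigue_onset_fraction
        Fraction of the trial (0, 1] at which a linear amplitude drift
        begins; smaller means earlier fatigue.  1.0 disables the drift.
    subject_scale_sd
        Log-scale SD of the per-subject multiplicative amplitude factor
        (applied to *all* subjects, both cohorts).
    recruitment_shift
        Fraction in [0, 1] by which the shifted cohort's per-class
        recruitment parameters (duty cycle, amplitude pattern, waveform
        asymmetry) are blended toward an alternative, seed-deterministic
        pattern set.  Models the systematic reorganization of motor-unit
        recruitment under impaired neuromuscular coordination: the
        effect is consistent across the shifted cohort (so an adaptive
        classifier can track it) yet remaps class signatures away from
        their baseline locations (so a static classifier collapses).
        0 disables the remapping.
    """

    amplitude_gain: float = 1.6
    noise_floor_gain: float = 3.0
    fluctuation_gain: float = 1.8
    fatigue_onset_fraction: float = 0.4
    subject_scale_sd: float = 0.08
    recruitment_shift: float = 0.7

    def __post_init__(self) -> None:
        if self.amplitude_gain < 1 or self.noise_floor_gain < 1 or self.fluctuation_gain < 1:
            raise ValueError("shift gains must be >= 1")
        if not 0 < self.fatigue_onset_fraction <= 1:
            raise ValueError("fatigue_onset_fraction must be in (0, 1]")
        if self.subject_scale_sd < 0:
            raise ValueError("subject_scale_sd must be >= 0")
        if not 0.0 <= self.recruitment_shift <= 1.0:
            raise ValueError("recruitment_shift must be in [0, 1]")

    @classmethod
    def identity(cls, subject_scale_sd: float = 0.08) -> "ShiftProfile":
        """Profile under which the shifted cohort equals the baseline one."""
        return cls(1.0, 1.0, 1.0, 1.0, subject_scale_sd, 0.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Acquisition-protocol parameters for one synthetic dataset."""

    n_subjects: int = 14
    n_classes: int = 15
    n_trials_per_class: int = 20
    n_channels: int = 8
    sampling_rate: float = 500.0  # Hz
    trial_length: int = 2000      # samples
    shift: ShiftProfile = field(default_factory=ShiftProfile)
    seed: int = 0
    # signal-model constants (mV-like arbitrary units)
    baseline_noise_sd: float = 0.02
    fluctuation_depth: float = 0.15
    fatigue_slope: float = 0.6
    band: tuple[float, float] = (10.0, 245.0)  # Hz, carrier pass-band

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_classes", "n_trials_per_class", "n_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.trial_length < 2:
            raise ValueError("trial_length must be >= 2")
        if not 0 < self.band[0] < self.band[1] < self.sampling_rate / 2:
            raise ValueError("band must satisfy 0 < low < high < Nyquist")

    def subject_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]


@dataclass
class SignalTrial:
    """One trial: raw multi-channel waveform plus annotations."""

    subject_id: str
    cohort: str
    class_label: int
    trial_index: int
    samples: np.ndarray  # (n_channels, trial_length), mV-like units

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples contain non-finite values")
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")


def _class_params(cfg: GeneratorConfig) -> dict[str, np.ndarray]:
    """Deterministic per-class signal parameters drawn from the seed.

    duty[c, ch]  — burst duty cycle in [0.30, 0.90]
    amp[c, ch]   — envelope amplitude in [0.5, 1.6]
    rate[c]      — burst repetition rate in [1.5, 4.0] Hz
    asym[c, ch]  — waveform asymmetry in [-0.45, 0.45] (motor-unit action
                   potentials are asymmetric biphasic waves, so the
                   rectified positive and negative phases differ; this
                   gives sign-sensitive amplitude features a stable,
                   class-specific expectation)

    The shifted cohort's effective parameters blend ``duty``, ``amp``
    and ``asym`` toward an alternative pattern set (same distributions,
    fresh seed-deterministic draws) with weight ``recruitment_shift``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, _CLASS_KEY)))
    params = {
        "duty": rng.uniform(0.30, 0.90, size=(cfg.n_classes, cfg.n_channels)),
        "amp": rng.uniform(0.5, 1.6, size=(cfg.n_classes, cfg.n_channels)),
        "rate": rng.uniform(1.5, 4.0, size=cfg.n_classes),
        "asym": rng.uniform(-0.45, 0.45, size=(cfg.n_classes, cfg.n_channels)),
    }
    alt = np.random.default_rng(np.random.SeedSequence((cfg.seed, _CLASS_KEY, 1)))
    params["duty_alt"] = alt.uniform(0.30, 0.90, size=(cfg.n_classes, cfg.n_channels))
    params["amp_alt"] = alt.uniform(0.5, 1.6, size=(cfg.n_classes, cfg.n_channels))
    params["asym_alt"] = alt.uniform(-0.45, 0.45, size=(cfg.n_classes, cfg.n_channels))
    return params


def _subject_scales(cfg: GeneratorConfig) -> np.ndarray:
    """Per-subject multiplicative amplitude factors (lognormal)."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, _SUBJECT_KEY)))
    return np.exp(rng.normal(0.0, cfg.shift.subject_scale_sd, size=cfg.n_subjects))


def trial_rng(cfg: GeneratorConfig, subject_index: int, class_label: int,
              trial_index: int) -> np.random.Generator:
    """The canonical per-trial RNG; independent of cohort by construction."""
    ss = np.random.SeedSequence((cfg.seed, _TRIAL_KEY, subject_index, class_label, trial_index))
    return np.random.default_rng(ss)


def _smooth_kernel(cfg: GeneratorConfig) -> np.ndarray:
    # ~50 ms raised-cosine edge smoothing on the burst gate
    n = max(3, int(round(0.05 * cfg.sampling_rate)) | 1)
    k = np.hanning(n + 2)[1:-1]
    return k / k.sum()


def generate_trial(cfg: GeneratorConfig, subject_id: str, class_label: int,
                   cohort: str, rng: np.random.Generator, *,
                   noise_floor: bool = True) -> SignalTrial:
    """Generate a single trial.

    The random draws (carrier, burst phase, slow modulation, baseline
    noise) are made unconditionally and in a fixed order; cohort gains
    are applied multiplicatively afterwards, so an identity
    :class:`ShiftProfile` yields samples identical to the baseline
    cohort under the same ``rng`` state.

    ``noise_floor=False`` suppresses the additive baseline-noise term
    (useful for inspecting the envelope component in isolation).
    """
    if not 0 <= class_label < cfg.n_classes:
        raise ValueError(f"class_label {class_label} outside [0, {cfg.n_classes})")
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}")

    C, T, fs = cfg.n_channels, cfg.trial_length, cfg.sampling_rate
    params = _class_params(cfg)
    ids = cfg.subject_ids()
    scale = _subject_scales(cfg)[ids.index(subject_id)] if subject_id in ids else 1.0

    # --- random draws (fixed count and order; cohort-independent) ---
    white = rng.standard_normal((C, T))
    phase = rng.uniform(0.0, 1.0, size=C)
    n_slow = int(4.0 * T / fs) + 2  # ~4 Hz support for slow modulation
    slow = rng.standard_normal(n_slow)
    floor = rng.standard_normal((C, T))

    # band-limited unit-variance carrier (interference pattern)
    sos = _sig.butter(4, cfg.band, btype="bandpass", fs=fs, output="sos")
    carrier = _sig.sosfilt(sos, white, axis=1)
    carrier /= np.maximum(carrier.std(axis=1, keepdims=True), 1e-12)

    shifted = cohort == SHIFTED
    prof = cfg.shift
    amp_gain = prof.amplitude_gain if shifted else 1.0
    noise_gain = prof.noise_floor_gain if shifted else 1.0
    fluct_gain = prof.fluctuation_gain if shifted else 1.0
    onset = prof.fatigue_onset_fraction if shifted else 1.0
    blend = prof.recruitment_shift if shifted else 0.0

    # cohort-level recruitment remapping (systematic, not per-subject)
    duty = ((1 - blend) * params["duty"][class_label]
            + blend * params["duty_alt"][class_label])
    amp = ((1 - blend) * params["amp"][class_label]
           + blend * params["amp_alt"][class_label])
    asym = ((1 - blend) * params["asym"][class_label]
            + blend * params["asym_alt"][class_label])

    t = np.arange(T) / fs
    # burst gate: class-specific repetition rate and per-channel duty cycle
    ph = (params["rate"][class_label] * t[None, :] + phase[:, None]) % 1.0
    gate = (ph < duty[:, None]).astype(float)
    gate = _sig.fftconvolve(gate, _smooth_kernel(cfg)[None, :], mode="same", axes=1)
    gate = np.clip(gate, 0.0, 1.0)

    # slow multiplicative fluctuation, ~unit-sd, interpolated to T samples
    slow_t = np.interp(np.linspace(0.0, n_slow - 1.0, T), np.arange(n_slow), slow)
    fluct = np.clip(1.0 + cfg.fluctuation_depth * fluct_gain * slow_t, 0.05, None)

    # linear fatigue drift after onset (shifted cohort only; onset=1 disables)
    frac = t / (T / fs)
    drift = 1.0 + cfg.fatigue_slope * np.clip(frac - onset, 0.0, None) / max(1.0 - onset, 1e-9)

    envelope = amp[:, None] * scale * amp_gain * gate * (fluct * drift)[None, :]
    # asymmetric biphasic waveform: the activity-scaled offset shifts the
    # rectified positive/negative balance without altering burst timing
    samples = envelope * (carrier + asym[:, None])
    if noise_floor:
        samples = samples + cfg.baseline_noise_sd * noise_gain * floor

    return SignalTrial(subject_id=subject_id, cohort=cohort,
                       class_label=class_label, trial_index=-1, samples=samples)


def default_cohort_assignment(cfg: GeneratorConfig, n_shifted: int = 3) -> dict[str, str]:
    """Assign the last ``n_shifted`` subjects to the shifted cohort.

    The 14-subject default with ``n_shifted=3`` mirrors an 11/3
    baseline/shifted composition; ``n_shifted=5`` gives the 9/5 variant.
    """
    if not 0 <= n_shifted <= cfg.n_subjects:
        raise ValueError("n_shifted outside [0, n_subjects]")
    ids = cfg.subject_ids()
    cut = cfg.n_subjects - n_shifted
    return {s: (BASELINE if i < cut else SHIFTED) for i, s in enumerate(ids)}


def generate_dataset(cfg: GeneratorConfig,
                     cohort_assignment: Mapping[str, str] | None = None) -> list[SignalTrial]:
    """Generate the full dataset: subjects x classes x trials.

    ``cohort_assignment`` maps every subject id to a cohort; by default
    the last 3 subjects form the shifted cohort (or 1 for very small
    configs).
    """
    if cohort_assignment is None:
        cohort_assignment = default_cohort_assignment(cfg, 3 if cfg.n_subjects >= 4 else 1)
    ids = cfg.subject_ids()
    missing = set(ids) - set(cohort_assignment)
    if missing:
        raise ValueError(f"cohort_assignment missing subjects: {sorted(missing)}")
    for s, c in cohort_assignment.items():
        if c not in COHORTS:
            raise ValueError(f"unknown cohort {c!r} for subject {s}")

    trials: list[SignalTrial] = []
    for s_idx, sid in enumerate(ids):
        cohort = cohort_assignment[sid]
        for c in range(cfg.n_classes):
            for t_idx in range(cfg.n_trials_per_class):
                trial = generate_trial(cfg, sid, c, cohort, trial_rng(cfg, s_idx, c, t_idx))
                trial.trial_index = t_idx
                trials.append(trial)
    return trials


# ---------------------------------------------------------------------------
# long-format CSV round-trip

_COLUMNS = ["subject_id", "cohort", "class_label", "trial_index",
            "channel", "sample_index", "value"]


def write_dataset(path, trials: Sequence[SignalTrial],
                  cfg: GeneratorConfig | None = None) -> None:
    """Write trials as long-format CSV with a ``#`` metadata header line."""
    meta = ""
    if cfg is not None:
        meta = (f"# seed={cfg.seed} n_subjects={cfg.n_subjects} n_classes={cfg.n_classes} "
                f"n_trials_per_class={cfg.n_trials_per_class} n_channels={cfg.n_channels} "
                f"sampling_rate={cfg.sampling_rate} trial_length={cfg.trial_length}\n")
    frames = []
    for tr in trials:
        C, T = tr.samples.shape
        frames.append(pd.DataFrame({
            "subject_id": np.repeat(tr.subject_id, C * T),
            "cohort": tr.cohort,
            "class_label": tr.class_label,
            "trial_index": tr.trial_index,
            "channel": np.repeat(np.arange(C), T),
            "sample_index": np.tile(np.arange(T), C),
            "value": tr.samples.ravel(),
        }))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=_COLUMNS)
    with open(path, "w") as fh:
        fh.write(meta)
        df.to_csv(fh, index=False, float_format="%.10g")


def read_dataset(path) -> list[SignalTrial]:
    """Read a long-format CSV written by :func:`write_dataset`."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed dataset CSV {path}: missing columns {missing}")
    bad = df["value"].isna()
    if bad.any():
        raise ValueError(f"malformed dataset CSV {path}: missing value at row {int(bad.idxmax())}")
    trials = []
    keys = ["subject_id", "cohort", "class_label", "trial_index"]
    for (sid, cohort, label, t_idx), grp in df.groupby(keys, sort=False):
        C = int(grp["channel"].max()) + 1
        T = int(grp["sample_index"].max()) + 1
        if len(grp) != C * T:
            raise ValueError(f"malformed dataset CSV {path}: trial {(sid, label, t_idx)} "
                             f"has {len(grp)} rows, expected {C * T}")
        samples = np.empty((C, T))
        samples[grp["channel"].to_numpy(), grp["sample_index"].to_numpy()] = grp["value"].to_numpy()
        trials.append(SignalTrial(str(sid), str(cohort), int(label), int(t_idx), samples))
    return trials
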