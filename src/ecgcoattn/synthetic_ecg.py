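"""Seeded synthetic 12-lead ECG datasets with known ground truth.

The generator builds each record as a train of template beats.  A beat is a
sum of five Gaussian bumps (P, Q, R, S, T) on a single reference waveform,
projected to the 12 leads by a fixed weight vector with small per-record
jitter, so the leads carry the correlated structure a lead-attention model
can exploit.  Class identity enters through template edits:

* ``MI``   - ST-segment depression and deepened Q on the inferior leads
             (II, III, aVF);
* ``STTC`` - ST elevation and T-wave inversion on the precordial leads
             V3-V6;
* ``CD``   - QRS widened by a factor 1.8 (conduction slowing);
* ``HYP``  - enlarged R (and deepened S) amplitudes;
* rhythm classes - mean RR interval and RR jitter (bradycardia >= 1.0 s,
  tachycardia <= 0.6 s, irregular rhythms with RR jitter >= 0.15 s), plus a
  widened-QRS "abnormal rhythm" category.

Two regimes mirror the public benchmarks the pipeline is aimed at: a
record-level multi-label 5-superclass scheme at 100 Hz and a mutually
exclusive rhythm scheme at 500 Hz with known R-peak positions.  Everything
is a pure function of the configuration, including its seed.

Ground-truth R-peak indices and the injected-anomaly region (leads and time
windows) are stored on each record so detector recall and class-activation
localization can be scored exactly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BeatTemplate", "SynthConfig", "ECGRecord",
    "SUPERCLASS_NAMES", "RHYTHM_NAMES", "LEAD_NAMES",
    "make_beat", "project_to_leads", "synth_record", "synth_dataset",
    "class_names",
]

LEAD_NAMES = ["I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6"]

SUPERCLASS_NAMES = ["NORM", "MI", "STTC", "CD", "HYP"]
RHYTHM_NAMES = ["sinus_rhythm", "sinus_tachycardia", "sinus_bradycardia",
                "sinus_arrhythmia", "irregular_sinus_rhythm", "abnormal_rhythm"]

# R-wave projection weights for the standard 12 leads (dimensionless);
# lead II carries the strongest positive R, aVR is inverted, V1 biphasic.
BASE_LEAD_WEIGHTS = np.array(
    [0.55, 1.00, 0.45, -0.75, 0.25, 0.65, -0.30, 0.35, 0.60, 0.85, 1.00, 0.80])

INFERIOR_LEADS = [1, 2, 5]          # II, III, aVF
PRECORDIAL_LEADS = [8, 9, 10, 11]   # V3-V6


class ConfigurationError(ValueError):
    """Raised for invalid generator/template settings."""


@dataclass
class BeatTemplate:
    """One cardiac cycle as Gaussian bumps relative to the R peak.

    ``waves`` maps wave name -> (center offset s, width s, amplitude mV).
    """

    waves: dict[str, tuple[float, float, float]]
    rr_mean: float = 0.85
    rr_jitter_sd: float = 0.03

    def __post_init__(self):
        for name, (_, width, _) in self.waves.items():
            if width <= 0:
                raise ConfigurationError(f"wave {name!r} has non-positive width")
        if self.rr_mean <= 0:
            raise ConfigurationError("rr_mean must be positive")
        if self.rr_jitter_sd < 0:
            raise ConfigurationError("rr_jitter_sd must be non-negative")


def norm_template() -> BeatTemplate:
    """Baseline sinus beat: P-QRS-T with a dominant R."""
    return BeatTemplate(waves={
        "P": (-0.20, 0.025, 0.15),
        "Q": (-0.040, 0.010, -0.10),
        "R": (0.0, 0.016, 1.00),
        "S": (0.040, 0.012, -0.25),
        "T": (0.30, 0.055, 0.35),
    })


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset."""

    n_records: int = 500
    fs: int = 100
    duration: float = 10.0
    n_leads: int = 12
    class_scheme: str = "superclass5"      # or "rhythm"
    label_mode: str = "multilabel"         # or "exclusive"
    noise_sd: float = 0.05                 # mV
    co_label_prob: float = 0.15            # multilabel: chance of a 2nd label
    seed: int = 0

    def __post_init__(self):
        if self.fs not in (100, 500):
            raise ConfigurationError(f"fs must be 100 or 500 Hz, got {self.fs}")
        t = self.duration * self.fs
        if abs(t - round(t)) > 1e-9:
            raise ConfigurationError("duration*fs must be an integer")
        if self.n_records <= 0:
            raise ConfigurationError("n_records must be positive")
        if self.class_scheme not in ("superclass5", "rhythm"):
            raise ConfigurationError(f"unknown class_scheme {self.class_scheme!r}")
        if self.label_mode not in ("multilabel", "exclusive"):
            raise ConfigurationError(f"unknown label_mode {self.label_mode!r}")
        if self.class_scheme == "rhythm" and self.label_mode != "exclusive":
            raise ConfigurationError("rhythm scheme uses exclusive labels")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    @property
    def class_names(self) -> list[str]:
        return class_names(self.class_scheme)

    @property
    def n_folds(self) -> int:
        # record-level scheme follows a 10-fold train/val/test protocol,
        # rhythm scheme a five-fold cross-validation protocol
        return 10 if self.class_scheme == "superclass5" else 5


def class_names(scheme: str) -> list[str]:
    return list(SUPERCLASS_NAMES if scheme == "superclass5" else RHYTHM_NAMES)


@dataclass
class ECGRecord:
    """One multi-lead recording plus ground truth."""

    signal: np.ndarray                       # (n_leads, T) millivolts
    fs: int
    labels: np.ndarray                       # multi-hot over K classes
    record_id: str
    true_r_peaks: np.ndarray | None = None   # sample indices
    fold: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if not np.isfinite(self.signal).all():
            raise ValueError("signal contains NaN/Inf")

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


# --------------------------------------------------------------------------
# beat construction
# --------------------------------------------------------------------------

def make_beat(template: BeatTemplate, fs: float, length: int,
              r_index: int) -> np.ndarray:
    """Evaluate the template's Gaussian bumps on a sample grid.

    The R bump sits at ``r_index``; other bumps are placed at their offsets
    in seconds relative to it.  Deterministic given its inputs.
    """
    if fs <= 0:
        raise ConfigurationError("fs must be positive")
    if not 0 <= r_index < length:
        raise ValueError(f"r_index {r_index} outside [0, {length})")
    t = (np.arange(length) - r_index) / float(fs)
    out = np.zeros(length)
    for name, (center, width, amp) in template.waves.items():
        if width <= 0:
            raise ConfigurationError(f"wave {name!r} has non-positive width")
        if amp != 0.0:
            out += amp * np.exp(-((t - center) ** 2) / (2.0 * width ** 2))
    return out


def project_to_leads(beat: np.ndarray, lead_weights: np.ndarray) -> np.ndarray:
    """Project a single waveform onto leads: row i = lead_weights[i] * beat."""
    lead_weights = np.asarray(lead_weights, dtype=float)
    if not np.isfinite(lead_weights).all():
        raise ValueError("lead weights must be finite")
    return np.outer(lead_weights, np.asarray(beat, dtype=float))


# --------------------------------------------------------------------------
# class-conditional morphology
# --------------------------------------------------------------------------

def _apply_superclass_edits(template: BeatTemplate, labels: Sequence[int]):
    """Return (template, per-lead anomaly waves, anomaly lead set)."""
    tpl = copy.deepcopy(template)
    anomaly_waves: dict[int, list[tuple[float, float, float]]] = {}
    anomaly_leads: set[int] = set()
    names = SUPERCLASS_NAMES

    def widen_qrs(factor: float):
        for w in ("Q", "R", "S"):
            c, width, a = tpl.waves[w]
            tpl.waves[w] = (c, width * factor, a)

    active = {names[i] for i, bit in enumerate(labels) if bit}
    if "CD" in active:
        widen_qrs(1.8)
    if "HYP" in active:
        c, w, a = tpl.waves["R"]
        tpl.waves["R"] = (c, w, a * 1.8)
        c, w, a = tpl.waves["S"]
        tpl.waves["S"] = (c, w, a * 1.5)
    if "MI" in active:
        for lead in INFERIOR_LEADS:
            anomaly_waves.setdefault(lead, []).extend([
                (0.16, 0.06, -0.20),   # ST depression
                (-0.040, 0.012, -0.15),  # pathological Q
            ])
        anomaly_leads.update(INFERIOR_LEADS)
    if "STTC" in active:
        for lead in PRECORDIAL_LEADS:
            anomaly_waves.setdefault(lead, []).extend([
                (0.16, 0.06, 0.20),    # ST elevation
                (0.30, 0.055, -0.60),  # T inversion (net negative T)
            ])
        anomaly_leads.update(PRECORDIAL_LEADS)
    return tpl, anomaly_waves, anomaly_leads


def _apply_rhythm_edits(template: BeatTemplate, labels: Sequence[int]):
    tpl = copy.deepcopy(template)
    anomaly_waves: dict[int, list[tuple[float, float, float]]] = {}
    anomaly_leads: set[int] = set()
    idx = int(np.argmax(labels))
    name = RHYTHM_NAMES[idx]
    if name == "sinus_rhythm":
        tpl.rr_mean, tpl.rr_jitter_sd = 0.85, 0.03
    elif name == "sinus_tachycardia":
        tpl.rr_mean, tpl.rr_jitter_sd = 0.50, 0.02
    elif name == "sinus_bradycardia":
        tpl.rr_mean, tpl.rr_jitter_sd = 1.20, 0.04
    elif name == "sinus_arrhythmia":
        tpl.rr_mean, tpl.rr_jitter_sd = 0.85, 0.18
    elif name == "irregular_sinus_rhythm":
        tpl.rr_mean, tpl.rr_jitter_sd = 0.90, 0.25
    elif name == "abnormal_rhythm":
        tpl.rr_mean, tpl.rr_jitter_sd = 0.80, 0.06
        for w in ("Q", "R", "S"):
            c, width, a = tpl.waves[w]
            tpl.waves[w] = (c, width * 1.8, a * (0.8 if w == "R" else 1.0))
        # abnormal morphology concentrates on the precordial leads
        for lead in PRECORDIAL_LEADS:
            anomaly_waves.setdefault(lead, []).append((0.30, 0.055, -0.45))
        anomaly_leads.update(PRECORDIAL_LEADS)
    return tpl, anomaly_waves, anomaly_leads


# --------------------------------------------------------------------------
# record and dataset synthesis
# --------------------------------------------------------------------------

def synth_record(class_labels: Sequence[int], config: SynthConfig,
                 rng: np.random.Generator,
                 template: BeatTemplate | None = None,
                 record_id: str = "rec") -> ECGRecord:
    """Synthesize one labeled record.

    The beat train tiles :func:`make_beat` at RR intervals drawn from the
    class-dependent rhythm; morphology edits and lead-subset anomalies are
    applied per label, followed by additive Gaussian noise of
    ``config.noise_sd`` millivolts.
    """
    labels = np.asarray(class_labels, dtype=np.int8)
    names = config.class_names
    if labels.shape != (len(names),):
        raise ConfigurationError(
            f"labels must have length {len(names)} for scheme "
            f"{config.class_scheme!r}")
    if config.label_mode == "exclusive" and labels.sum() != 1:
        raise ConfigurationError("exclusive mode requires exactly one label")

    base = template if template is not None else norm_template()
    if config.class_scheme == "superclass5":
        tpl, anomaly_waves, anomaly_leads = _apply_superclass_edits(base, labels)
    else:
        tpl, anomaly_waves, anomaly_leads = _apply_rhythm_edits(base, labels)

    fs, n = config.fs, config.n_samples
    rr_mean = tpl.rr_mean * float(rng.uniform(0.95, 1.05))
    if config.duration < rr_mean:
        raise ConfigurationError(
            f"duration {config.duration}s too short for one beat "
            f"(rr_mean {rr_mean:.2f}s)")

    # R-peak times: first beat centered half an interval into the record
    r_times = []
    t = 0.5 * rr_mean
    while t < config.duration:
        r_times.append(t)
        rr = rr_mean + float(rng.normal(0.0, tpl.rr_jitter_sd))
        t += max(rr, 0.25)          # physiologic floor on RR
    r_peaks = np.array([int(round(rt * fs)) for rt in r_times])
    r_peaks = r_peaks[(r_peaks >= 0) & (r_peaks < n)]
    if len(r_peaks) == 0:
        raise ConfigurationError("record too short to place a beat")

    amp_scale = float(rng.uniform(0.9, 1.1))
    beat_train = np.zeros(n)
    anomaly_trains = {lead: np.zeros(n) for lead in anomaly_waves}
    grid = np.arange(n, dtype=float)
    for p in r_peaks:
        rel = (grid - p) / fs
        for _, (center, width, amp) in tpl.waves.items():
            beat_train += (amp * amp_scale) * np.exp(
                -((rel - center) ** 2) / (2.0 * width ** 2))
        for lead, waves in anomaly_waves.items():
            tr = anomaly_trains[lead]
            for center, width, amp in waves:
                tr += amp * np.exp(-((rel - center) ** 2) / (2.0 * width ** 2))

    lead_weights = BASE_LEAD_WEIGHTS[:config.n_leads] * rng.uniform(
        0.92, 1.08, size=config.n_leads)
    signal = project_to_leads(beat_train, lead_weights)
    for lead, tr in anomaly_trains.items():
        if lead < config.n_leads:
            signal[lead] += tr
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=signal.shape)

    # ST/T region of each beat, where ischemia-type anomalies are injected
    anomaly_windows = [
        (int(p + round(0.05 * fs)), int(min(p + round(0.45 * fs), n)))
        for p in r_peaks
    ] if anomaly_leads else []

    return ECGRecord(
        signal=signal.astype(np.float32), fs=fs, labels=labels,
        record_id=record_id, true_r_peaks=r_peaks,
        meta={
            "anomaly_leads": sorted(int(v) for v in anomaly_leads),
            "anomaly_windows": anomaly_windows,
            "rr_mean": rr_mean,
        })


def _label_matrix(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-record multi-hot labels honoring the scheme and proportions."""
    k = len(config.class_names)
    n = config.n_records
    if n < k:
        raise ConfigurationError(
            f"n_records={n} smaller than the {k} classes")
    # uniform primary-class allocation, exact up to rounding
    counts = np.full(k, n // k, dtype=int)
    counts[: n % k] += 1
    primary = np.repeat(np.arange(k), counts)
    rng.shuffle(primary)
    labels = np.zeros((n, k), dtype=np.int8)
    labels[np.arange(n), primary] = 1
    if config.label_mode == "multilabel" and config.co_label_prob > 0:
        norm_idx = config.class_names.index("NORM") \
            if "NORM" in config.class_names else None
        for i in range(n):
            if primary[i] == norm_idx:
                continue                     # normals carry no co-label
            if rng.random() < config.co_label_prob:
                choices = [c for c in range(k)
                           if c != primary[i] and c != norm_idx]
                labels[i, rng.choice(choices)] = 1
    return labels


def _stratified_folds(labels: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Round-robin fold assignment within each label signature."""
    folds = np.zeros(len(labels), dtype=int)
    signatures = [tuple(row) for row in labels]
    for sig in sorted(set(signatures)):
        idx = np.array([i for i, s in enumerate(signatures) if s == sig])
        rng.shuffle(idx)
        offset = int(rng.integers(n_folds))
        folds[idx] = (np.arange(len(idx)) + offset) % n_folds + 1
    return folds


def synth_dataset(config: SynthConfig) -> list[ECGRecord]:
    """Generate the full dataset with label-stratified fold assignment.

    Folds are numbered 1..n_folds.  The whole dataset is a pure function of
    the configuration, including the seed.
    """
    ss = np.random.SeedSequence(config.seed)
    label_rng, fold_rng, *rec_seeds = [
        np.random.default_rng(s) for s in ss.spawn(config.n_records + 2)]
    labels = _label_matrix(config, label_rng)
    folds = _stratified_folds(labels, config.n_folds, fold_rng)
    records = []
    for i in range(config.n_records):
        rec = synth_record(labels[i], config, rec_seeds[i],
                           record_id=f"syn{i:05d}")
        rec.fold = int(folds[i])
        records.append(rec)
    return records
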