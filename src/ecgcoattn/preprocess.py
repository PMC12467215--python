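"""Record loading, normalization, QRS detection, and beat segmentation.

Normalization is per-record, per-lead robust scaling ``(x - median) / IQR``,
resistant to transient artifacts on individual leads.  Records are unified
to a fixed length (truncate / zero-pad).  QRS complexes are found with the
classic Pan-Tompkins cascade (band-pass, 5-point derivative, squaring,
moving-window integration, adaptive dual thresholds with refractory period
and RR-based search-back), each detection refined to the nearby signal
maximum.  Beats are cut as a fixed window of 0.4 s before to 0.6 s after
the R peak.

WFDB (.hea/.dat) support is a self-contained reader/writer for format-16
records (16-bit little-endian samples with gain/baseline scaling), enough
to round-trip the standard 10 s resting ECG exports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .synthetic_ecg import LEAD_NAMES, ECGRecord

__all__ = [
    "BeatSegment", "PanTompkinsParams",
    "read_wfdb_record", "write_wfdb_record",
    "robust_scale", "fix_length", "pan_tompkins_qrs", "segment_beats",
]


@dataclass
class BeatSegment:
    """One cardiac cycle: 0.4 s before to 0.6 s after the R peak."""

    signal: np.ndarray          # (n_leads, W)
    fs: int
    r_peak_index: int           # within the segment: round(0.4 * fs)
    parent_record_id: str
    labels: np.ndarray


@dataclass
class PanTompkinsParams:
    """Detector constants (classical published values)."""

    bandpass_low: float = 5.0       # Hz
    bandpass_high: float = 15.0     # Hz
    integration_window: float = 0.150   # s
    refractory: float = 0.200       # s
    threshold_decay: float = 0.125  # running-estimate blending fraction
    searchback_factor: float = 1.66  # missed-beat search-back, x mean RR

    def __post_init__(self):
        if not 0 < self.bandpass_low < self.bandpass_high:
            raise ValueError("need 0 < bandpass_low < bandpass_high")
        if self.refractory <= 0:
            raise ValueError("refractory must be positive")


# --------------------------------------------------------------------------
# WFDB format-16 I/O
# --------------------------------------------------------------------------

def write_wfdb_record(path: str | Path, signal: np.ndarray, fs: int,
                      lead_names: Sequence[str], gain: float = 1000.0) -> Path:
    """Write a (n_leads, T) millivolt array as a WFDB header/data pair.

    ``path`` is the record path without extension.  Samples are stored as
    interleaved little-endian int16 at the given ADC gain (units per mV).
    """
    path = Path(path)
    signal = np.asarray(signal, dtype=float)
    n_sig, n_samp = signal.shape
    digital = np.rint(signal * gain).astype(np.int64)
    if np.abs(digital).max(initial=0) > 32767:
        raise ValueError("signal exceeds int16 range at this gain")
    digital = digital.astype("<i2")
    lines = [f"{path.name} {n_sig} {fs:g} {n_samp}"]
    for i, name in enumerate(lead_names):
        checksum = int(np.sum(digital[i], dtype=np.int16))
        lines.append(
            f"{path.name}.dat 16 {gain:g}(0)/mV 16 0 "
            f"{int(digital[i, 0])} {checksum} 0 {name}")
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    path.with_suffix(".dat").write_bytes(digital.T.tobytes())
    return path


def _parse_gain(token: str) -> tuple[float, float]:
    """Parse WFDB gain spec 'gain(baseline)/units' -> (gain, baseline)."""
    spec = token.split("/")[0]
    baseline = 0.0
    if "(" in spec:
        spec, rest = spec.split("(")
        baseline = float(rest.rstrip(")"))
    gain = float(spec) if spec else 200.0
    if gain == 0:
        gain = 200.0    # WFDB convention: 0 means the default gain
    return gain, baseline


def read_wfdb_record(path: str | Path,
                     require_leads: Sequence[str] | None = None) -> ECGRecord:
    """Read a format-16 WFDB record into millivolts.

    Leads found among the standard 12 (I, II, III, aVR, aVL, aVF, V1-V6)
    are reordered into that canonical sequence; other leads follow in file
    order.  ``require_leads`` asserts presence of the named leads and
    raises a ``ValueError`` listing any that are absent.
    """
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"no WFDB header at {hea}")
    lines = [ln.strip() for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samp = int(head[3]) if len(head) > 3 else None
    gains, baselines, names, dat_files = [], [], [], []
    for ln in lines[1:1 + n_sig]:
        tok = ln.split()
        dat_files.append(tok[0])
        fmt = tok[1].split("x")[0].split(":")[0]
        if fmt != "16":
            raise ValueError(f"unsupported WFDB format {tok[1]!r} (only 16)")
        gain, baseline = _parse_gain(tok[2]) if len(tok) > 2 else (200.0, 0.0)
        gains.append(gain)
        baselines.append(baseline)
        names.append(tok[8] if len(tok) > 8 else f"sig{len(names)}")
    if len(set(dat_files)) != 1:
        raise ValueError("multi-file WFDB records are not supported")
    raw = np.frombuffer((path.parent / dat_files[0]).read_bytes(), dtype="<i2")
    if n_samp is None:
        n_samp = len(raw) // n_sig
    digital = raw[: n_samp * n_sig].reshape(n_samp, n_sig).T.astype(float)
    physical = (digital - np.asarray(baselines)[:, None]) \
        / np.asarray(gains)[:, None]

    if require_leads is not None:
        missing = [l for l in require_leads if l not in names]
        if missing:
            raise ValueError(f"record is missing leads: {', '.join(missing)}")
    order = [names.index(l) for l in LEAD_NAMES if l in names]
    order += [i for i in range(n_sig) if i not in order]
    physical = physical[order]
    names = [names[i] for i in order]
    return ECGRecord(signal=physical.astype(np.float32), fs=int(round(fs)),
                     labels=np.zeros(0, dtype=np.int8), record_id=path.name,
                     meta={"lead_names": names})


# --------------------------------------------------------------------------
# normalization and length fixing
# --------------------------------------------------------------------------

def robust_scale(signal: np.ndarray) -> np.ndarray:
    """Per-lead (x - median) / IQR with a zero-IQR guard.

    Quantiles use linear interpolation between order statistics.  Leads
    with IQR = 0 (constant leads) are centered only.
    """
    signal = np.asarray(signal, dtype=float)
    if np.isnan(signal).any():
        raise ValueError("signal contains NaN")
    if signal.ndim != 2 or signal.shape[1] < 4:
        raise ValueError("expected (n_leads, T) with T >= 4")
    med = np.median(signal, axis=1, keepdims=True)
    q75, q25 = np.percentile(signal, [75, 25], axis=1, keepdims=True)
    iqr = q75 - q25
    iqr_safe = np.where(iqr == 0, 1.0, iqr)
    return (signal - med) / iqr_safe


def fix_length(signal: np.ndarray, target_t: int) -> np.ndarray:
    """Truncate to, or zero-pad up to, ``target_t`` samples."""
    if target_t <= 0:
        raise ValueError("target length must be positive")
    signal = np.asarray(signal)
    n_leads, t = signal.shape
    if t == target_t:
        return signal
    if t > target_t:
        return signal[:, :target_t]
    out = np.zeros((n_leads, target_t), dtype=signal.dtype)
    out[:, :t] = signal
    return out


# --------------------------------------------------------------------------
# QRS detection
# --------------------------------------------------------------------------

def pan_tompkins_qrs(lead_signal: np.ndarray, fs: float,
                     params: PanTompkinsParams | None = None) -> np.ndarray:
    """Pan-Tompkins R-peak detection on a single lead.

    Returns strictly increasing sample indices, each refined to the local
    signal maximum within +/- 0.05 s of the integrated-energy peak.
    """
    params = params or PanTompkinsParams()
    x = np.asarray(lead_signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single lead (1-D array)")
    if len(x) < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    if fs < 2 * params.bandpass_high:
        raise ValueError(
            f"fs={fs} too low for band-pass upper edge {params.bandpass_high}")
    if np.ptp(x) == 0:
        return np.array([], dtype=int)

    # 1) band-pass  2) derivative  3) squaring  4) moving-window integration
    b, a = butter(2, [params.bandpass_low, params.bandpass_high],
                  btype="bandpass", fs=fs)
    bp = filtfilt(b, a, x)
    deriv = np.convolve(bp, np.array([2, 1, 0, -1, -2]) * (fs / 8.0),
                        mode="same")
    sq = deriv ** 2
    win = max(int(round(params.integration_window * fs)), 1)
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(params.refractory * fs))
    cand, _ = find_peaks(mwi, distance=max(refractory, 1))
    if len(cand) == 0:
        return np.array([], dtype=int)

    # adaptive dual thresholds with running signal/noise peak estimates
    lead_in = mwi[: int(2 * fs)]
    spk = float(lead_in.max()) / 3.0
    npk = float(np.mean(lead_in)) / 2.0
    decay = params.threshold_decay
    accepted: list[int] = []
    rr_hist: list[int] = []

    def threshold1():
        return npk + 0.25 * (spk - npk)

    for p in cand:
        peak = mwi[p]
        is_qrs = False
        if peak > threshold1() and (not accepted or p - accepted[-1] > refractory):
            is_qrs = True
        elif accepted and rr_hist:
            # search-back: gap longer than 1.66x the running mean RR
            rr_mean = float(np.mean(rr_hist[-8:]))
            if (p - accepted[-1]) > params.searchback_factor * rr_mean \
                    and peak > 0.5 * threshold1():
                is_qrs = True
        if is_qrs:
            if accepted:
                rr_hist.append(p - accepted[-1])
            accepted.append(int(p))
            spk = decay * peak + (1 - decay) * spk
        else:
            npk = decay * peak + (1 - decay) * npk

    # refine to the local signal maximum within +/- 0.05 s
    w = int(round(0.05 * fs))
    refined = []
    for p in accepted:
        lo, hi = max(p - w, 0), min(p + w + 1, len(x))
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = sorted(set(refined))
    # enforce strict increase and the refractory spacing after refinement
    out: list[int] = []
    for p in refined:
        if out and p - out[-1] <= refractory // 2:
            if x[p] > x[out[-1]]:
                out[-1] = p
            continue
        out.append(p)
    return np.array(out, dtype=int)


def segment_beats(record: ECGRecord,
                  peaks: Sequence[int]) -> list[BeatSegment]:
    """Cut the fixed [R - 0.4 s, R + 0.6 s) window around each peak.

    Peaks whose window would leave the record are dropped.  Segments
    inherit the record's labels.
    """
    fs = record.fs
    pre = int(round(0.4 * fs))
    post = int(round(0.6 * fs))
    t = record.n_samples
    segments = []
    for p in peaks:
        start, end = p - pre, p + post
        if start < 0 or end > t:
            continue
        segments.append(BeatSegment(
            signal=record.signal[:, start:end].copy(), fs=fs,
            r_peak_index=pre, parent_record_id=record.record_id,
            labels=record.labels.copy()))
    return segments
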