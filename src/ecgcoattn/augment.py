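"""Label-preserving, seeded data augmentations.

Two schemes are covered: record-level transforms (circular time shift,
amplitude scaling, additive noise) and QRS-aware transforms for
beat-segmented data (noise confined to the QRS region, lead-specific gain,
smooth monotone time warping).  Every transform preserves array shape and
labels; an :class:`Augmenter` composes them with a per-transform
application probability and a dedicated random stream so augmented batches
are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AugmentConfig", "Augmenter",
    "time_shift", "amplitude_scale", "add_noise", "qrs_region_noise",
    "lead_gain", "time_warp",
]


@dataclass
class AugmentConfig:
    """Magnitudes for each transform (defaults are deliberately slight)."""

    shift_max: float = 0.5              # s
    scale_range: tuple[float, float] = (0.9, 1.1)
    noise_sd: float = 0.02              # scaled units
    qrs_noise_sd: float = 0.02
    qrs_halfwidth: float = 0.05         # s
    lead_gain_range: tuple[float, float] = (0.9, 1.1)
    warp_max: float = 0.1               # fraction of the time axis
    apply_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.apply_prob <= 1.0:
            raise ValueError("apply_prob must be in [0, 1]")
        if min(self.scale_range) <= 0 or min(self.lead_gain_range) <= 0:
            raise ValueError("scale/gain ranges must be positive")
        if not 0.0 <= self.warp_max < 0.5:
            raise ValueError("warp_max must be in [0, 0.5)")


def time_shift(x: np.ndarray, shift: int) -> np.ndarray:
    """Circular shift along the time axis (beat count preserved)."""
    if abs(shift) >= x.shape[-1]:
        raise ValueError("|shift| must be smaller than the record length")
    return np.roll(x, shift, axis=-1)


def amplitude_scale(x: np.ndarray, factor: float) -> np.ndarray:
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return x * factor


def add_noise(x: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd < 0:
        raise ValueError("noise sd must be non-negative")
    if sd == 0:
        return x.copy()
    return x + rng.normal(0.0, sd, size=x.shape)


def qrs_region_noise(x: np.ndarray, peaks, sd: float, halfwidth: float,
                     fs: float, rng: np.random.Generator) -> np.ndarray:
    """Add noise only inside [p - hw, p + hw) windows around each R peak."""
    out = x.copy()
    if sd == 0 or len(peaks) == 0:
        return out
    hw = int(round(halfwidth * fs))
    t = x.shape[-1]
    mask = np.zeros(t, dtype=bool)
    for p in peaks:
        mask[max(int(p) - hw, 0):min(int(p) + hw, t)] = True
    noise = rng.normal(0.0, sd, size=x.shape)
    out[..., mask] += noise[..., mask]
    return out


def lead_gain(x: np.ndarray, gains: np.ndarray) -> np.ndarray:
    gains = np.asarray(gains, dtype=float)
    if gains.shape != (x.shape[0],):
        raise ValueError(
            f"need one gain per lead: got {gains.shape} for {x.shape[0]} leads")
    if (gains <= 0).any():
        raise ValueError("gains must be positive")
    return x * gains[:, None]


def _warp_function(t: int, warp_max: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Piecewise-linear monotone warp with 4 interior knots.

    Knot displacements are bounded so the slope stays within
    [1 - warp_max, 1 + warp_max]; endpoints are fixed.
    """
    n_seg = 5
    knots_t = np.linspace(0, t - 1, n_seg + 1)
    max_d = warp_max * (t - 1) / (2 * n_seg)
    disp = np.zeros(n_seg + 1)
    disp[1:-1] = rng.uniform(-max_d, max_d, size=n_seg - 1)
    return np.interp(np.arange(t), knots_t, knots_t + disp)


def time_warp(x: np.ndarray, warp_max: float,
              rng: np.random.Generator) -> np.ndarray:
    """Resample through a smooth monotone warp, back to the same length."""
    if not 0.0 <= warp_max < 0.5:
        raise ValueError("warp_max must be in [0, 0.5)")
    t = x.shape[-1]
    if warp_max == 0:
        return x.copy()
    phi = _warp_function(t, warp_max, rng)
    grid = np.arange(t)
    return np.stack([np.interp(phi, grid, row) for row in np.atleast_2d(x)]) \
        .reshape(x.shape)


class Augmenter:
    """Composite on-the-fly pipeline over (n_leads, T) arrays.

    ``mode='record'`` applies shift/scale/noise; ``mode='qrs'`` additionally
    applies QRS-region noise, lead gain, and time warping (given peaks).
    With ``apply_prob = 0`` the pipeline is the identity.
    """

    def __init__(self, config: AugmentConfig, fs: float,
                 mode: str = "record"):
        if mode not in ("record", "qrs"):
            raise ValueError(f"unknown mode {mode!r}")
        self.config = config
        self.fs = fs
        self.mode = mode
        self.rng = np.random.default_rng(config.seed)

    def reseed(self, seed: int):
        self.rng = np.random.default_rng(seed)

    def __call__(self, x: np.ndarray, peaks=None) -> np.ndarray:
        cfg = self.config
        rng = self.rng
        out = np.asarray(x, dtype=float)
        if cfg.apply_prob == 0:
            return out.copy()
        if rng.random() < cfg.apply_prob and cfg.shift_max > 0:
            max_shift = int(round(cfg.shift_max * self.fs))
            if max_shift > 0:
                out = time_shift(out, int(rng.integers(-max_shift,
                                                       max_shift + 1)))
        if rng.random() < cfg.apply_prob:
            out = amplitude_scale(out, float(rng.uniform(*cfg.scale_range)))
        if rng.random() < cfg.apply_prob and cfg.noise_sd > 0:
            out = add_noise(out, cfg.noise_sd, rng)
        if self.mode == "qrs":
            if peaks is not None and len(peaks) and \
                    rng.random() < cfg.apply_prob and cfg.qrs_noise_sd > 0:
                out = qrs_region_noise(out, peaks, cfg.qrs_noise_sd,
                                       cfg.qrs_halfwidth, self.fs, rng)
            if rng.random() < cfg.apply_prob:
                gains = rng.uniform(*cfg.lead_gain_range, size=out.shape[0])
                out = lead_gain(out, gains)
            if rng.random() < cfg.apply_prob and cfg.warp_max > 0:
                out = time_warp(out, cfg.warp_max, rng)
        return out
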