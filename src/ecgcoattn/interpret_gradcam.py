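"""Gradient-weighted class-activation maps over the lead x time plane.

For a chosen class logit and feature layer, the gradient of the logit with
respect to the layer's activation is pooled per channel to weights
``w_c``; the map ``ReLU(sum_c w_c A_c)`` is resampled bilinearly to the
input resolution and min-max normalized (an all-zero map stays zero).
Model weights are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import zoom

from .model_core import CoAttentionECGNet

__all__ = ["CamMap", "grad_cam", "render_cam"]


@dataclass
class CamMap:
    heat: np.ndarray            # (n_leads, input_len) in [0, 1]
    class_index: int
    layer_name: str
    record_id: str = ""

    def to_dict(self) -> dict:
        return {"class_index": self.class_index, "layer_name": self.layer_name,
                "record_id": self.record_id, "heat": self.heat.tolist()}


def grad_cam(model: CoAttentionECGNet, signal: np.ndarray, class_index: int,
             layer_name: str = "branch_concat",
             record_id: str = "") -> CamMap:
    """Compute the class-activation map for one record.

    ``signal`` is a (n_leads, T) array already preprocessed the way the
    model was trained (robust-scaled, length-fixed).
    """
    available = model.layer_names()
    if layer_name not in available:
        raise ValueError(
            f"unknown layer {layer_name!r}; available: {', '.join(available)}")
    cfg = model.cfg
    x = np.asarray(signal, dtype=np.float32)[None, None, :, :]
    model.eval()
    model.zero_grad()
    logits = model.forward(x, capture=True)
    if not 0 <= class_index < logits.shape[1]:
        raise ValueError(f"class_index {class_index} out of range")
    seed = np.zeros_like(logits.data)
    seed[0, class_index] = 1.0
    logits.backward(seed)
    act = model.activations[layer_name]
    grads = act.grad[0]                     # (C, l', T')
    amap = act.data[0]
    weights = grads.mean(axis=(1, 2))       # GAP of gradients per channel
    cam = np.maximum((weights[:, None, None] * amap).sum(axis=0), 0.0)
    # bilinear resample to the input lead x time resolution
    fy = cfg.n_leads / cam.shape[0]
    fx = cfg.input_len / cam.shape[1]
    if fy != 1.0 or fx != 1.0:
        cam = zoom(cam, (fy, fx), order=1)
        cam = cam[: cfg.n_leads, : cfg.input_len]
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = (cam - cam.min()) / (peak - cam.min())
    model.zero_grad()
    model.activations = {}
    return CamMap(heat=cam.astype(np.float32), class_index=class_index,
                  layer_name=layer_name, record_id=record_id)


def render_cam(cam: CamMap, signal: np.ndarray, path: str | Path,
               lead_names: list[str] | None = None) -> Path:
    """Per-lead waveform panel with the heat map as background shading."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    signal = np.asarray(signal)
    n_leads, t = signal.shape
    if cam.heat.shape != (n_leads, t):
        raise ValueError("heat map and signal dimensions disagree")
    names = lead_names or [f"lead{i}" for i in range(n_leads)]
    fig, axes = plt.subplots(n_leads, 1, figsize=(8, 1.0 * n_leads),
                             sharex=True)
    axes = np.atleast_1d(axes)
    for i, ax in enumerate(axes):
        ax.imshow(cam.heat[i][None, :], aspect="auto", cmap="inferno",
                  alpha=0.6, vmin=0.0, vmax=1.0,
                  extent=(0, t, float(signal[i].min()),
                          float(signal[i].max()) or 1.0))
        ax.plot(signal[i], color="k", lw=0.6)
        ax.set_ylabel(names[i], rotation=0, ha="right", fontsize=7)
        ax.set_yticks([])
    axes[-1].set_xlabel("sample")
    fig.suptitle(f"class {cam.class_index} @ {cam.layer_name}", fontsize=9)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
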