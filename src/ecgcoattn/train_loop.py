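"""Training protocol: He init, focal loss, AdamW, cosine annealing, clipping.

The loss is focal loss: cross-entropy modulated by ``(1 - p_t)**gamma`` so
easy examples are down-weighted, with an ``alpha`` class weight, in its
per-label binary form for multi-label tasks and its softmax form for
mutually exclusive tasks.  The learning rate follows a per-step cosine
annealing schedule; gradients are clipped by global L2 norm.  Training is
a pure function of (model weights, data, config seed): data order,
augmentation and dropout all draw from streams spawned off the one seed.

On-the-fly augmentation is applied to training folds only; validation
records pass through untouched.  The checkpoint returned is the epoch with
the best validation macro AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .layers import AdamW, BatchNorm1d, BatchNorm2d, Conv2d, Linear, Module
from .metrics_eval import macro_auc_score
from .model_core import ModelConfig, build_model
from .preprocess import fix_length, robust_scale
from .synthetic_ecg import ECGRecord

__all__ = [
    "TrainConfig", "focal_loss", "he_init", "cosine_lr", "clip_gradients",
    "prepare_arrays", "train", "predict_scores",
    "save_checkpoint", "load_checkpoint",
]


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 32
    lr0: float = 1e-3
    lr_min: float = 1e-6
    weight_decay: float = 1e-2
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    clip_norm: float = 10.0
    seed: int = 0
    task_mode: str = "multilabel"       # or "exclusive"
    early_stop_auc: float | None = None  # stop once validation AUC reaches this

    def __post_init__(self):
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be positive")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be non-negative")
        if self.lr_min > self.lr0:
            raise ValueError("lr_min must not exceed lr0")
        if self.task_mode not in ("multilabel", "exclusive"):
            raise ValueError(f"unknown task_mode {self.task_mode!r}")


# --------------------------------------------------------------------------
# loss / schedule / clipping primitives
# --------------------------------------------------------------------------

def focal_loss(logits: Tensor, targets: np.ndarray, gamma: float = 2.0,
               alpha=0.25, mode: str = "multilabel") -> Tensor:
    """Mean focal loss over a batch of logits.

    Multilabel: per-entry binary focal loss
    ``-alpha_t (1 - p_t)**gamma log(p_t)`` with ``p = sigmoid(logit)``.
    Exclusive: softmax focal loss on the true class, ``alpha`` scalar or a
    per-class weight vector.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    t = np.asarray(targets, dtype=np.float32)
    if not np.isin(t, (0.0, 1.0)).all():
        raise ValueError("targets must be 0/1")
    if mode == "multilabel":
        tt = Tensor(t)
        lp1 = logits.log_sigmoid()
        lp0 = (-logits).log_sigmoid()
        if gamma == 0:
            mod1 = mod0 = Tensor(np.ones_like(t))
        else:
            mod1 = (lp0 * gamma).exp()      # (1 - p)**gamma
            mod0 = (lp1 * gamma).exp()      # p**gamma
        a = float(alpha)
        elem = -(tt * mod1 * lp1 * a) - ((1.0 - tt) * mod0 * lp0 * (1.0 - a))
        return elem.mean()
    # exclusive / softmax form
    lsm = logits.log_softmax(axis=1)
    tt = Tensor(t)
    lpy = (lsm * tt).sum(axis=1)            # log p_y
    alpha_arr = np.asarray(alpha, dtype=np.float32)
    if alpha_arr.ndim == 0:
        a_t = Tensor(np.full(t.shape[0], float(alpha_arr), dtype=np.float32))
    else:
        a_t = Tensor((t * alpha_arr).sum(axis=1).astype(np.float32))
    if gamma == 0:
        return (-(a_t * lpy)).mean()
    p_y = lpy.exp()
    mod = (1.0 - p_y).pow_const(gamma)
    return (-(a_t * mod * lpy)).mean()


def he_init(model: Module, seed: int = 0) -> Module:
    """He-normal weights (var 2 / fan_in), zero biases, unit batch norms."""
    rng = np.random.default_rng(seed)
    for m in model.modules():
        if isinstance(m, Conv2d):
            fan_in = m.in_channels * m.kernel_size[0] * m.kernel_size[1]
            m.weight.data = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), m.weight.data.shape
            ).astype(np.float32)
            if m.bias is not None:
                m.bias.data[:] = 0.0
        elif isinstance(m, Linear):
            m.weight.data = rng.normal(
                0.0, np.sqrt(2.0 / m.in_features), m.weight.data.shape
            ).astype(np.float32)
            if m.bias is not None:
                m.bias.data[:] = 0.0
        elif isinstance(m, (BatchNorm2d, BatchNorm1d)):
            m.gamma.data[:] = 1.0
            m.beta.data[:] = 0.0
            m.running_mean[:] = 0.0
            m.running_var[:] = 1.0
    return model


def cosine_lr(step: int, total_steps: int, lr0: float, lr_min: float) -> float:
    """Cosine annealing from lr0 (step 0) to lr_min (final step)."""
    if total_steps <= 0:
        raise ValueError("total_steps must be positive")
    if not 0 <= step <= total_steps:
        raise ValueError("step outside [0, total_steps]")
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + np.cos(np.pi * step / total_steps))


def clip_gradients(grads, threshold: float):
    """Global-L2-norm gradient clipping; returns (grads, norm).

    ``grads`` is a list of arrays (or a single array); when the joint norm
    exceeds ``threshold`` every array is scaled by ``threshold / norm`` in
    place.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    single = isinstance(grads, np.ndarray)
    glist = [grads] if single else [g for g in grads if g is not None]
    norm = float(np.sqrt(sum(float((g.astype(np.float64) ** 2).sum())
                             for g in glist)))
    if norm > threshold:
        scale = threshold / norm
        for g in glist:
            g *= scale
    return (glist[0] if single else grads), norm


# --------------------------------------------------------------------------
# data plumbing
# --------------------------------------------------------------------------

def prepare_arrays(records: list[ECGRecord], target_len: int | None = None,
                   normalize: bool = True):
    """Records -> (X (N,1,l,T) float32, y (N,K), folds (N,)).

    Applies per-lead robust scaling and unifies lengths.
    """
    if not records:
        raise ValueError("no records")
    t = target_len or records[0].n_samples
    xs, ys, folds = [], [], []
    for rec in records:
        sig = rec.signal.astype(np.float64)
        if normalize:
            sig = robust_scale(sig)
        xs.append(fix_length(sig, t))
        ys.append(rec.labels)
        folds.append(rec.fold if rec.fold is not None else 0)
    x = np.stack(xs)[:, None, :, :].astype(np.float32)
    y = np.stack(ys).astype(np.float32)
    return x, y, np.asarray(folds)


def predict_scores(model: Module, x: np.ndarray, mode: str = "multilabel",
                   batch_size: int = 64) -> np.ndarray:
    """Eval-mode class scores: sigmoid (multilabel) or softmax (exclusive)."""
    model.eval()
    outs = []
    for i in range(0, len(x), batch_size):
        logits = model(x[i:i + batch_size]).data
        if mode == "multilabel":
            outs.append(1.0 / (1.0 + np.exp(-logits)))
        else:
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            outs.append(e / e.sum(axis=1, keepdims=True))
    return np.concatenate(outs, axis=0)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def train(model: Module, x: np.ndarray, y: np.ndarray, folds: np.ndarray,
          cfg: TrainConfig, train_folds, val_folds, augmenter=None,
          verbose: bool = False):
    """Run the full protocol; returns (model at best val AUC, history).

    ``augmenter`` is called per training record, never on validation data.
    """
    train_folds = set(train_folds)
    val_folds = set(val_folds)
    tr_idx = np.flatnonzero([f in train_folds for f in folds])
    va_idx = np.flatnonzero([f in val_folds for f in folds])
    if len(tr_idx) == 0:
        raise ValueError("training fold selection is empty")
    if len(va_idx) == 0:
        raise ValueError("validation fold selection is empty")
    x_tr, y_tr = x[tr_idx], y[tr_idx]
    x_va, y_va = x[va_idx], y[va_idx]

    ss = np.random.SeedSequence(cfg.seed)
    shuffle_rng, dropout_rng, aug_seed = ss.spawn(3)
    shuffle_rng = np.random.default_rng(shuffle_rng)
    model.set_dropout_rng(np.random.default_rng(dropout_rng))
    if augmenter is not None:
        augmenter.reseed(int(aug_seed.generate_state(1)[0] % (2 ** 31)))

    opt = AdamW(model.parameters(), lr=cfg.lr0,
                weight_decay=cfg.weight_decay)
    n_batches = int(np.ceil(len(x_tr) / cfg.batch_size))
    total_steps = cfg.epochs * n_batches
    history: list[dict] = []
    best_auc, best_state = -np.inf, model.state_dict()
    step = 0
    for epoch in range(cfg.epochs):
        model.train()
        order = shuffle_rng.permutation(len(x_tr))
        losses = []
        for b in range(n_batches):
            idx = order[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            xb = x_tr[idx]
            if augmenter is not None:
                xb = np.stack([augmenter(s[0])[None] for s in xb]) \
                    .astype(np.float32)
            loss = focal_loss(model(xb), y_tr[idx], cfg.focal_gamma,
                              cfg.focal_alpha, cfg.task_mode)
            model.zero_grad()
            loss.backward()
            clip_gradients([p.grad for p in opt.params], cfg.clip_norm)
            lr = cosine_lr(step, total_steps, cfg.lr0, cfg.lr_min)
            opt.step(lr=lr)
            step += 1
            losses.append(float(loss.data))
        model.eval()
        val_scores = predict_scores(model, x_va, cfg.task_mode,
                                    cfg.batch_size)
        vl, vn = 0.0, 0
        for b in range(0, len(x_va), cfg.batch_size):
            xb, yb = x_va[b:b + cfg.batch_size], y_va[b:b + cfg.batch_size]
            vl += float(focal_loss(model(xb), yb, cfg.focal_gamma,
                                   cfg.focal_alpha, cfg.task_mode).data) * len(xb)
            vn += len(xb)
        val_loss = vl / vn
        auc = macro_auc_score(val_scores, y_va)
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                 "val_loss": val_loss, "val_macro_auc": auc,
                 "lr": cosine_lr(step, total_steps, cfg.lr0, cfg.lr_min)}
        history.append(entry)
        if verbose:
            print(json.dumps(entry))
        if auc > best_auc:
            best_auc = auc
            best_state = model.state_dict()
        if cfg.early_stop_auc is not None and auc >= cfg.early_stop_auc:
            break
    model.load_state_dict(best_state)
    model.eval()
    return model, history


# --------------------------------------------------------------------------
# checkpointing
# --------------------------------------------------------------------------

def save_checkpoint(path: str | Path, model: Module, model_cfg: ModelConfig,
                    extra: dict | None = None) -> Path:
    path = Path(path)
    state = model.state_dict()
    meta = {"model_cfg": model_cfg.to_dict(), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8),
        **{f"param/{k}": v for k, v in state.items()})
    return path if path.suffix == ".npz" else path.with_suffix(".npz")


def load_checkpoint(path: str | Path):
    """Returns (model in eval mode, ModelConfig, extra dict)."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
    cfg = ModelConfig.from_dict(meta["model_cfg"])
    model = build_model(cfg)
    model.load_state_dict(state)
    model.eval()
    return model, cfg, meta["extra"]
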