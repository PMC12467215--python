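"""Desk-scale reference run: the study conditions used for validation.

The full-size configuration (``ModelConfig()`` defaults, ~25M parameters)
is impractical to train on one CPU, so system-level validation uses the
same architecture at reduced channel widths on a 500-record synthetic
5-superclass dataset (100 Hz, 10 s, 12 leads).  Training follows the full
protocol - He init, focal loss, AdamW, per-step cosine annealing, gradient
clipping, on-the-fly augmentation of training folds - and stops as soon as
the validation macro AUC reaches the 0.95 learnability bar (capped at 20
epochs).  One seed fans out to the generator, initialization and training
streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augment import AugmentConfig, Augmenter
from .model_core import ModelConfig, build_model
from .synthetic_ecg import ECGRecord, SynthConfig, synth_dataset
from .train_loop import TrainConfig, he_init, prepare_arrays, train

__all__ = ["ReferenceRun", "reduced_model_config", "run_reference_training"]

# architecture unchanged, channel plan shrunk for single-CPU training
REDUCED_WIDTHS = dict(stem_channels=4, ltcar1_channels=6, ltcar2_channels=8,
                      branch_channels=8, head_hidden=32, reduction_r=4,
                      dropout_p=0.2)


def reduced_model_config(n_leads: int = 12, input_len: int = 1000,
                         n_classes: int = 5, **overrides) -> ModelConfig:
    kwargs = dict(REDUCED_WIDTHS)
    kwargs.update(overrides)
    return ModelConfig(n_leads=n_leads, input_len=input_len,
                       n_classes=n_classes, **kwargs)


@dataclass
class ReferenceRun:
    model: object
    history: list
    x: np.ndarray
    y: np.ndarray
    folds: np.ndarray
    records: list[ECGRecord]
    synth_cfg: SynthConfig
    model_cfg: ModelConfig
    train_cfg: TrainConfig

    @property
    def best_val_auc(self) -> float:
        return max(h["val_macro_auc"] for h in self.history)

    def split(self, fold_set):
        mask = np.isin(self.folds, list(fold_set))
        return self.x[mask], self.y[mask]


def run_reference_training(seed: int = 0, n_records: int = 500,
                           epochs: int = 20,
                           early_stop_auc: float | None = 0.95,
                           verbose: bool = False) -> ReferenceRun:
    """Generate the dataset, train the reduced-width model, return both."""
    ss = np.random.SeedSequence(seed)
    synth_seed, init_seed, train_seed = [
        int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(3)]
    synth_cfg = SynthConfig(n_records=n_records, seed=synth_seed)
    records = synth_dataset(synth_cfg)
    x, y, folds = prepare_arrays(records)
    model_cfg = reduced_model_config(
        n_leads=synth_cfg.n_leads, input_len=x.shape[3],
        n_classes=len(synth_cfg.class_names))
    model = he_init(build_model(model_cfg), seed=init_seed)
    train_cfg = TrainConfig(epochs=epochs, batch_size=16, lr0=3e-3,
                            seed=train_seed, early_stop_auc=early_stop_auc)
    augmenter = Augmenter(AugmentConfig(), fs=synth_cfg.fs)
    model, history = train(model, x, y, folds, train_cfg,
                           train_folds=range(1, 9), val_folds=[9],
                           augmenter=augmenter, verbose=verbose)
    return ReferenceRun(model=model, history=history, x=x, y=y, folds=folds,
                        records=records, synth_cfg=synth_cfg,
                        model_cfg=model_cfg, train_cfg=train_cfg)
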