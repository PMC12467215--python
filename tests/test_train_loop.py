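"""Focal loss analytics, He init, schedule/clipping, training bookkeeping."""

import numpy as np
import pytest

from ecgcoattn.autodiff import Tensor
from ecgcoattn.layers import BatchNorm2d, Conv2d, Linear
from ecgcoattn.model_core import ModelConfig, build_model
from ecgcoattn.synthetic_ecg import SynthConfig, synth_dataset
from ecgcoattn.train_loop import (
    TrainConfig, clip_gradients, cosine_lr, focal_loss, he_init,
    load_checkpoint, predict_scores, prepare_arrays, save_checkpoint, train,
)


class TestFocalLoss:
    def test_gamma_zero_reduces_to_half_bce(self, rng):
        logits = rng.normal(size=(8, 5)).astype(np.float32)
        targets = (rng.random((8, 5)) < 0.4).astype(np.float32)
        got = float(focal_loss(Tensor(logits), targets, gamma=0.0,
                               alpha=0.5).data)
        p = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
        bce = -(targets * np.log(p) + (1 - targets) * np.log(1 - p)).mean()
        assert abs(got - 0.5 * bce) < 1e-6

    def test_closed_form_single_entry(self):
        logit = np.log(0.9 / 0.1)                 # p = 0.9
        got = float(focal_loss(Tensor([[logit]]), np.array([[1.0]]),
                               gamma=2.0, alpha=1.0).data)
        expect = 0.01 * (-np.log(0.9))            # ~1.0536e-3
        assert abs(got - expect) < 1e-7

    def test_loss_vanishes_for_confident_correct(self):
        losses = [float(focal_loss(Tensor([[z]]), np.array([[1.0]]),
                                   2.0, 0.25).data)
                  for z in (0.0, 2.0, 5.0, 10.0, 20.0)]
        assert all(a > b for a, b in zip(losses, losses[1:]))
        assert losses[-1] < 1e-8

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(Tensor([[0.0]]), np.array([[1.0]]), gamma=-1.0)

    def test_exclusive_mode_matches_softmax_arithmetic(self, rng):
        logits = rng.normal(size=(6, 4)).astype(np.float32)
        y = np.eye(4, dtype=np.float32)[rng.integers(0, 4, 6)]
        got = float(focal_loss(Tensor(logits), y, gamma=2.0, alpha=1.0,
                               mode="exclusive").data)
        z = logits.astype(np.float64)
        p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        py = (p * y).sum(axis=1)
        expect = (-(1 - py) ** 2 * np.log(py)).mean()
        assert abs(got - expect) < 1e-5

    def test_non_binary_targets_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(Tensor([[0.0]]), np.array([[0.5]]))


class TestHeInit:
    def test_conv_weight_variance(self):
        conv = Conv2d(64, 8, (3, 15))
        he_init(conv, seed=0)
        fan_in = 64 * 3 * 15
        var = conv.weight.data.var()
        assert abs(var - 2.0 / fan_in) < 0.2 * 2.0 / fan_in
        assert not conv.bias.data.any()

    def test_batchnorm_reset(self):
        bn = BatchNorm2d(4)
        bn.gamma.data[:] = 3.0
        bn.running_var[:] = 7.0
        he_init(bn, seed=0)
        np.testing.assert_array_equal(bn.gamma.data, np.ones(4))
        np.testing.assert_array_equal(bn.running_var, np.ones(4))

    def test_same_seed_identical_weights(self, tiny_model_cfg):
        a = he_init(build_model(tiny_model_cfg), seed=5)
        b = he_init(build_model(tiny_model_cfg), seed=5)
        for (na, pa), (nb, pb) in zip(a.named_parameters(),
                                      b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)


class TestSchedulesAndClipping:
    def test_cosine_endpoints_and_midpoint(self):
        assert cosine_lr(0, 100, 1e-3, 1e-6) == pytest.approx(1e-3)
        assert cosine_lr(100, 100, 1e-3, 1e-6) == pytest.approx(1e-6)
        assert cosine_lr(50, 100, 1e-3, 1e-6) == pytest.approx(
            (1e-3 + 1e-6) / 2)

    def test_cosine_zero_steps_rejected(self):
        with pytest.raises(ValueError):
            cosine_lr(0, 0, 1e-3, 1e-6)

    def test_clip_rescales_above_threshold(self):
        g = np.array([30.0, 40.0])
        clipped, norm = clip_gradients(g, 10.0)
        assert norm == pytest.approx(50.0)
        np.testing.assert_allclose(clipped, [6.0, 8.0])

    def test_clip_identity_below_threshold(self):
        g = np.array([3.0, 4.0])
        clipped, norm = clip_gradients(g.copy(), 10.0)
        np.testing.assert_array_equal(clipped, g)

    def test_clipped_norm_bounded(self, rng):
        grads = [rng.normal(size=(5, 5)) * 100 for _ in range(3)]
        _, _ = clip_gradients(grads, 10.0)
        total = np.sqrt(sum((g ** 2).sum() for g in grads))
        assert total <= 10.0 + 1e-6


@pytest.fixture(scope="module")
def tiny_training_setup():
    """A short-duration dataset and small model for protocol tests."""
    cfg = SynthConfig(n_records=50, fs=100, duration=2.0, noise_sd=0.02,
                      seed=31)
    records = synth_dataset(cfg)
    x, y, folds = prepare_arrays(records)
    mcfg = ModelConfig(n_leads=12, input_len=200, n_classes=5,
                       stem_channels=3, ltcar1_channels=4, ltcar2_channels=4,
                       branch_channels=4, head_hidden=8, reduction_r=2,
                       dropout_p=0.2)
    return x, y, folds, mcfg


class TestTrain:
    def test_history_bookkeeping(self, tiny_training_setup):
        x, y, folds, mcfg = tiny_training_setup
        model = he_init(build_model(mcfg), seed=1)
        tcfg = TrainConfig(epochs=2, batch_size=8, seed=3)
        _, hist = train(model, x, y, folds, tcfg, range(1, 9), [9])
        assert len(hist) == 2
        for entry in hist:
            assert {"epoch", "train_loss", "val_loss",
                    "val_macro_auc"} <= set(entry)

    def test_same_seed_reproduces_final_loss_exactly(self, tiny_training_setup):
        x, y, folds, mcfg = tiny_training_setup
        runs = []
        for _ in range(2):
            model = he_init(build_model(mcfg), seed=1)
            tcfg = TrainConfig(epochs=1, batch_size=8, seed=3)
            _, hist = train(model, x, y, folds, tcfg, range(1, 9), [9])
            runs.append(hist[-1])
        assert runs[0]["train_loss"] == runs[1]["train_loss"]
        assert runs[0]["val_macro_auc"] == runs[1]["val_macro_auc"]

    def test_loss_decreases_on_separable_data(self, tiny_training_setup):
        x, y, folds, mcfg = tiny_training_setup
        model = he_init(build_model(mcfg), seed=2)
        tcfg = TrainConfig(epochs=4, batch_size=8, lr0=3e-3, seed=4)
        _, hist = train(model, x, y, folds, tcfg, range(1, 9), [9])
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_validation_inputs_never_augmented(self, tiny_training_setup):
        from ecgcoattn.augment import AugmentConfig, Augmenter
        x, y, folds, mcfg = tiny_training_setup
        x = x.copy()
        before = x.copy()
        model = he_init(build_model(mcfg), seed=1)
        tcfg = TrainConfig(epochs=1, batch_size=8, seed=3)
        aug = Augmenter(AugmentConfig(apply_prob=1.0), fs=100)
        train(model, x, y, folds, tcfg, range(1, 9), [9], augmenter=aug)
        np.testing.assert_array_equal(x, before)

    def test_best_checkpoint_matches_history_max(self, tiny_training_setup):
        from ecgcoattn.metrics_eval import macro_auc_score
        x, y, folds, mcfg = tiny_training_setup
        model = he_init(build_model(mcfg), seed=1)
        tcfg = TrainConfig(epochs=3, batch_size=8, seed=3)
        model, hist = train(model, x, y, folds, tcfg, range(1, 9), [9])
        va = np.flatnonzero(folds == 9)
        auc = macro_auc_score(predict_scores(model, x[va]), y[va])
        assert auc == pytest.approx(max(h["val_macro_auc"] for h in hist))

    def test_empty_fold_selection_rejected(self, tiny_training_setup):
        x, y, folds, mcfg = tiny_training_setup
        model = build_model(mcfg)
        with pytest.raises(ValueError):
            train(model, x, y, folds, TrainConfig(epochs=1), [99], [9])


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, tmp_path, tiny_model_cfg, rng):
        model = he_init(build_model(tiny_model_cfg), seed=4).eval()
        x = rng.normal(size=(2, 1, 4, 64)).astype(np.float32)
        expect = model(x).data
        path = save_checkpoint(tmp_path / "ck.npz", model, tiny_model_cfg,
                               extra={"note": "test"})
        loaded, cfg, extra = load_checkpoint(path)
        assert extra["note"] == "test"
        assert cfg.to_dict() == tiny_model_cfg.to_dict()
        np.testing.assert_array_equal(loaded(x).data, expect)
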