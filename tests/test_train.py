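"""Training schedule: loss decomposition, poly decay, seeded determinism."""

import numpy as np
import pytest

from bodycomp.phantom import PhantomParams, generate_phantom
from bodycomp.train import (TrainConfig, _loss_and_grad, composite_loss,
                            default_ds_weights, poly_lr, train_model)
from bodycomp.unet import NetConfig, build_unet


# -- independent single-purpose oracles --------------------------------------

def softmax_oracle(z):
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def ce_oracle(scores, target):
    p = softmax_oracle(scores)
    b, k, h, w = scores.shape
    total = 0.0
    for i in range(b):
        for r in range(h):
            for c in range(w):
                total -= np.log(p[i, target[i, r, c], r, c])
    return total / (b * h * w)


def dice_loss_oracle(scores, target, eps=1e-5):
    p = softmax_oracle(scores)
    k = scores.shape[1]
    dices = []
    for c in range(1, k):
        t = (target == c).astype(float)
        inter = (p[:, c] * t).sum()
        denom = p[:, c].sum() + t.sum()
        dices.append((2 * inter + eps) / (denom + eps))
    return 1.0 - float(np.mean(dices))


# -- composite loss ----------------------------------------------------------

class TestCompositeLoss:
    def test_equals_sum_of_independent_oracles(self, rng):
        scores = rng.normal(0, 2, (2, 4, 6, 6))
        target = rng.integers(0, 4, (2, 6, 6))
        expected = ce_oracle(scores, target) + dice_loss_oracle(scores, target)
        assert composite_loss(scores, target) == pytest.approx(expected, abs=1e-6)

    def test_uniform_scores_ce_is_log_k(self):
        for k in (2, 5, 8):
            scores = np.zeros((1, k, 4, 4))
            target = np.zeros((1, 4, 4), dtype=int)
            dice_part = dice_loss_oracle(scores, target)
            assert composite_loss(scores, target) - dice_part == pytest.approx(
                np.log(k), abs=1e-9)

    def test_perfect_prediction_limit(self, rng):
        target = rng.integers(0, 3, (1, 8, 8))
        scores = np.full((1, 3, 8, 8), -50.0)
        for c in range(3):
            scores[0, c][target[0] == c] = 50.0
        assert composite_loss(scores, target) < 1e-6

    def test_class_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            composite_loss(np.zeros((1, 3, 4, 4)), np.full((1, 4, 4), 3))

    def test_gradient_matches_finite_differences(self, rng):
        scores = rng.normal(0, 1, (1, 3, 4, 4))
        target = rng.integers(0, 3, (1, 4, 4))
        loss, grad = _loss_and_grad(scores, target)
        eps = 1e-6
        for idx in [(0, 0, 0, 0), (0, 1, 2, 3), (0, 2, 3, 1)]:
            sp = scores.copy(); sp[idx] += eps
            sm = scores.copy(); sm[idx] -= eps
            numeric = (composite_loss(sp, target) - composite_loss(sm, target)) / (2 * eps)
            assert grad[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8)


class TestPolyLR:
    def test_endpoints_and_midpoint(self):
        cfg = TrainConfig(epochs=200)
        assert poly_lr(0, cfg) == 0.01
        assert poly_lr(200, cfg) == 0.0
        assert poly_lr(100, cfg) == pytest.approx(0.01 * 0.5 ** 0.9, abs=1e-9)
        assert poly_lr(100, cfg) == pytest.approx(0.005359, abs=5e-7)

    def test_monotone_non_increasing(self):
        cfg = TrainConfig(epochs=50)
        lrs = [poly_lr(e, cfg) for e in range(51)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_out_of_range_rejected(self):
        cfg = TrainConfig(epochs=10)
        with pytest.raises(ValueError):
            poly_lr(11, cfg)
        with pytest.raises(ValueError):
            poly_lr(-1, cfg)


def test_ds_weights_halve_and_normalize():
    w = default_ds_weights(3)
    assert np.isclose(sum(w), 1.0)
    assert w[0] == pytest.approx(2 * w[1]) and w[1] == pytest.approx(2 * w[2])


# -- training loop -----------------------------------------------------------

def _micro_cohort(n, seed=0, imat=0.1):
    return [generate_phantom(PhantomParams(
        region="thigh", grid_shape=(8, 32, 32), imat_fraction=imat, seed=seed + i))
        for i in range(n)]


def _micro_model(seed=0, deep_supervision=False):
    cfg = NetConfig(in_channels=2, out_channels=5,
                    encoder_filters=((8, 8), (16, 16)), bottleneck_filters=(16, 16),
                    input_size=(32, 32), deep_supervision=deep_supervision)
    return build_unet(cfg, seed=seed)


class TestTrainLoop:
    def test_seeded_run_reproduces_loss_log(self):
        cohort = _micro_cohort(4)
        cfg = TrainConfig(epochs=2, minibatches_per_epoch=3, batch_size=2,
                          val_every=0, seed=21)
        _, log_a = train_model(_micro_model(seed=3), cohort, cfg)
        _, log_b = train_model(_micro_model(seed=3), cohort, cfg)
        assert log_a["train_loss"].tolist() == log_b["train_loss"].tolist()

    def test_logged_lr_follows_poly_schedule(self):
        cohort = _micro_cohort(2)
        cfg = TrainConfig(epochs=3, minibatches_per_epoch=2, batch_size=2,
                          val_every=0, seed=0)
        _, log = train_model(_micro_model(), cohort, cfg)
        for _, row in log.iterrows():
            assert row["lr"] == poly_lr(int(row["epoch"]), cfg)

    def test_single_case_overfit_loss_decreases(self):
        cohort = _micro_cohort(1)
        cfg = TrainConfig(epochs=8, minibatches_per_epoch=4, batch_size=2,
                          val_every=0, seed=1)
        _, log = train_model(_micro_model(seed=1), cohort, cfg)
        assert log["train_loss"].iloc[-1] < log["train_loss"].iloc[0]

    def test_disabling_deep_supervision_reduces_to_top_term(self):
        """Aux heads present but unsupervised: trajectory identical to the
        plain model, since their gradients are exactly zero."""
        cohort = _micro_cohort(2)
        cfg = TrainConfig(epochs=2, minibatches_per_epoch=2, batch_size=2,
                          val_every=0, seed=5)
        _, log_aux = train_model(_micro_model(seed=2, deep_supervision=True),
                                 cohort, cfg)
        _, log_plain = train_model(_micro_model(seed=2), cohort, cfg)
        assert log_aux["train_loss"].tolist() == log_plain["train_loss"].tolist()

    def test_deep_supervision_requires_aux_heads(self):
        cfg = TrainConfig(epochs=1, minibatches_per_epoch=1, batch_size=1,
                          deep_supervision=True, val_every=0)
        with pytest.raises(ValueError):
            train_model(_micro_model(), _micro_cohort(1), cfg)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            train_model(_micro_model(), [],
                        TrainConfig(epochs=1, minibatches_per_epoch=1, batch_size=1))

    def test_single_channel_ablations_train(self):
        cohort = _micro_cohort(2)
        for mode in ("fat", "water"):
            cfg = NetConfig(in_channels=1, out_channels=5,
                            encoder_filters=((8, 8), (16, 16)),
                            bottleneck_filters=(16, 16), input_size=(32, 32))
            model = build_unet(cfg, seed=0)
            tcfg = TrainConfig(epochs=1, minibatches_per_epoch=2, batch_size=2,
                               input_mode=mode, val_every=0, seed=0)
            _, log = train_model(model, cohort, tcfg)
            assert np.isfinite(log["train_loss"]).all()
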