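"""Architecture family: receptive field, shapes, gradients, toy training."""

import numpy as np
import pytest

from octrack import (
    AScan,
    UNetConfig,
    build_model,
    load_model,
    predict_mask,
    receptive_field,
    save_model,
)
from octrack.nn import softmax
from octrack.train_eval import _gdl_and_grad, _one_hot
from octrack.unet1d import normalize, predict_masks


class TestReceptiveField:
    @pytest.mark.parametrize(
        "k,s,b,expected",
        [
            (15, 2, 4, 449),  # full-depth design with 2x sampling
            (3, 2, 1, 7),
            (15, 4, 3, 1841),  # reduced-depth design with 4x sampling
        ],
    )
    def test_formula(self, k, s, b, expected):
        assert receptive_field(k, s, b) == expected

    def test_default_configs_cover_the_input(self):
        # design intent: receptive field larger than the 320-px image; the
        # 3-block/sampling-2 variant does not reach it, which is why the
        # sampling size is raised to 4 when depth is reduced
        for s, b in [(2, 4), (4, 3)]:
            assert receptive_field(15, s, b) >= 320
        assert receptive_field(15, 2, 3) < 320

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            receptive_field(0, 2, 4)


class TestBuildModel:
    @pytest.mark.parametrize("skip", [False, True])
    @pytest.mark.parametrize("b,s", [(4, 2), (3, 2), (3, 4)])
    def test_forward_shape_and_finiteness(self, b, s, skip):
        cfg = UNetConfig(n_blocks=b, n_channels=4, sampling_size=s, skip_concat=skip)
        model = build_model(cfg, seed=0)
        logits = model.forward(np.zeros((2, 1, 320), dtype=np.float32), train=False)
        assert logits.shape == (2, 8, 320)
        assert np.all(np.isfinite(logits))

    def test_selected_architecture_builds(self):
        # the configuration chosen for the tremor-cancellation system:
        # 3 blocks, 12 channels, sampling 4, no skip concatenation
        cfg = UNetConfig(n_blocks=3, n_channels=12, sampling_size=4, skip_concat=False)
        model = build_model(cfg)
        assert model.forward(np.zeros((1, 1, 320), np.float32), False).shape == (1, 8, 320)

    def test_skip_toggle_changes_params_not_shapes(self):
        a = build_model(UNetConfig(skip_concat=False), seed=0)
        b = build_model(UNetConfig(skip_concat=True), seed=0)
        assert a.n_parameters() != b.n_parameters()
        x = np.zeros((1, 1, 320), np.float32)
        assert a.forward(x, False).shape == b.forward(x, False).shape

    def test_param_count_monotone_in_channels(self):
        counts = [
            build_model(UNetConfig(n_channels=c)).n_parameters() for c in (4, 8, 12, 16)
        ]
        assert all(a < b for a, b in zip(counts, counts[1:]))

    def test_indivisible_length_rejected(self):
        with pytest.raises(ValueError, match="not divisible"):
            build_model(UNetConfig(n_blocks=4, sampling_size=4, input_length=320))

    def test_softmax_normalized_per_pixel(self, rng):
        model = build_model(UNetConfig(n_channels=4), seed=1)
        logits = model.forward(rng.random((2, 1, 320)).astype(np.float32), False)
        probs = softmax(logits, axis=1)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestGradients:
    @pytest.mark.parametrize("skip", [False, True])
    def test_backward_matches_numeric_gradient(self, rng, skip):
        """End-to-end gradient check through conv/BN/pool/tconv/concat,
        against central differences of a linear functional of the logits."""
        cfg = UNetConfig(n_blocks=2, n_channels=3, conv_kernel=5,
                         sampling_size=2, skip_concat=skip, input_length=16)
        model = build_model(cfg, seed=1)
        x = rng.normal(size=(2, 1, 16)).astype(np.float32)
        dy = rng.normal(size=(2, 8, 16)).astype(np.float32)

        def f():
            return float((model.forward(x, train=True) * dy).sum())

        f()
        model.backward(dy)
        grads = [(layer, layer.dW.copy())
                 for layer in (model.down[0]["conv"], model.up[0]["tconv"],
                               model.up[1]["conv"], model.head)]
        eps = 1e-3
        for layer, dW in grads:
            W = layer.W
            flat = W.reshape(-1)
            dflat = dW.reshape(-1)
            # max-pool argmax flips make single central differences one-sided
            # at isolated kinks, so judge by the median over several weights
            rel_errs = []
            for j in np.linspace(0, flat.size - 1, 5).astype(int):
                w0 = float(flat[j])
                flat[j] = w0 + eps
                fp = f()
                flat[j] = w0 - eps
                fm = f()
                flat[j] = w0
                num = (fp - fm) / (2 * eps)
                rel_errs.append(abs(num - dflat[j]) / max(abs(dflat[j]), 1e-3))
            assert np.median(rel_errs) < 0.02

    def test_dice_gradient_matches_numeric(self, rng):
        """The generalized-dice gradient w.r.t. probabilities, float64."""
        labels = rng.integers(0, 4, size=(2, 12))
        r = _one_hot(labels)
        p = rng.random((2, 8, 12))
        p /= p.sum(axis=1, keepdims=True)
        _, g = _gdl_and_grad(p, r)
        eps = 1e-6
        for idx in [(0, 0, 3), (1, 2, 7), (0, 7, 11)]:
            pp = p.copy(); pp[idx] += eps
            pm = p.copy(); pm[idx] -= eps
            lp, _ = _gdl_and_grad(pp, r)
            lm, _ = _gdl_and_grad(pm, r)
            assert (lp - lm) / (2 * eps) == pytest.approx(float(g[idx]), rel=1e-4, abs=1e-9)


class TestPredictMask:
    def test_untrained_model_valid_range(self, rng):
        model = build_model(UNetConfig(n_channels=4), seed=0)
        mask = predict_mask(model, AScan(rng.random(320)))
        assert len(mask) == 320
        assert mask.labels.min() >= 0 and mask.labels.max() <= 7

    def test_wrong_length_rejected(self, rng):
        model = build_model(UNetConfig(n_channels=4), seed=0)
        with pytest.raises(ValueError, match="length"):
            predict_mask(model, AScan(rng.random(100)))

    def test_batched_equals_single_predictions(self, rng):
        model = build_model(UNetConfig(n_channels=4), seed=2)
        batch = rng.random((16, 320)).astype(np.float32)
        batched = predict_masks(model, batch)
        singles = np.stack(
            [predict_mask(model, AScan(batch[i])).labels for i in range(16)]
        )
        assert np.array_equal(batched, singles)

    def test_normalization_scale_invariant(self, rng):
        v = rng.random((3, 320))
        assert np.allclose(normalize(v), normalize(10.0 * v))
        assert np.allclose(normalize(np.zeros((1, 320))), 0.0)

    def test_two_layer_toy_step_boundary_recovered(self, rng):
        """A short training run on clean two-class steps localizes the
        boundary to within a pixel."""
        from octrack import ArrayDataset, TrainConfig, train

        n, L = 96, 64
        edges = rng.integers(20, 44, size=n)
        x = np.zeros((n, L), dtype=np.float32)
        y = np.zeros((n, L), dtype=np.int64)
        for i, e in enumerate(edges):
            x[i, e:] = 1.0
            y[i, e:] = 1
        cfg = UNetConfig(n_blocks=2, n_channels=6, conv_kernel=9,
                         sampling_size=2, input_length=L)
        model = build_model(cfg, seed=3)
        # small dataset -> few optimizer steps per epoch, so stretch the
        # schedule to give a comparable number of full-rate steps
        train(model, ArrayDataset(x, y),
              TrainConfig(max_epochs=60, batch_size=16, lr_drop_epoch=50, seed=3))
        xe = np.zeros((1, L), dtype=np.float32)
        xe[0, 32:] = 1.0
        pred = predict_masks(model, xe)[0]
        change = np.flatnonzero(np.diff(pred)) + 1
        assert len(change) == 1 and abs(int(change[0]) - 32) <= 1

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        model = build_model(UNetConfig(n_channels=4), seed=4)
        model.trained = True
        p = tmp_path / "ckpt.npz"
        save_model(model, p)
        back = load_model(p)
        assert back.config == model.config
        x = rng.random((2, 1, 320)).astype(np.float32)
        assert np.allclose(back.forward(x, False), model.forward(x, False))
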