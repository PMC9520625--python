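import numpy as np
import pytest

from sonocrack.encoder import EncodedImage
from sonocrack.nn import (
    AttentionInputs,
    MobileViT,
    MobileViTBlock,
    PatchTensorShapes,
    Tensor,
    ViTConfig,
    attention,
    fold,
    load_model,
    predict,
    save_model,
    small_vit_config,
    train,
    unfold,
)
from sonocrack.nn import autograd as ag
from sonocrack.nn.autograd import cross_entropy


class TestAttention:
    def test_weights_rows_sum_to_one_via_uniform_value(self, rng):
        """With V = 1 every output entry is exactly 1 (weights normalise)."""
        q = rng.normal(size=(5, 4))
        k = rng.normal(size=(6, 4))
        v = np.ones((6, 3))
        out = attention(AttentionInputs(q, k, v, 4))
        np.testing.assert_allclose(out, 1.0, atol=1e-12)

    def test_identical_keys_give_query_independent_output(self, rng):
        k = np.tile(rng.normal(size=(1, 4)), (6, 1))
        v = rng.normal(size=(6, 3))
        q1, q2 = rng.normal(size=(2, 5, 4))
        out1 = attention(AttentionInputs(q1, k, v, 4))
        out2 = attention(AttentionInputs(q2, k, v, 4))
        np.testing.assert_allclose(out1, out2, atol=1e-12)
        np.testing.assert_allclose(out1[0], v.mean(axis=0), atol=1e-12)

    def test_identity_inputs_match_scalar_oracle(self):
        """Q = K = V = I2, d_k = 2 against an independently coded softmax."""
        eye = np.eye(2)
        out = attention(AttentionInputs(eye, eye, eye, 2))
        import math
        s = 1.0 / math.sqrt(2.0)
        row = [math.exp(s), math.exp(0.0)]
        w = [r / sum(row) for r in row]
        expected = np.array([[w[0], w[1]], [w[1], w[0]]])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            attention(AttentionInputs(rng.normal(size=(2, 3)),
                                      rng.normal(size=(2, 4)),
                                      rng.normal(size=(2, 4)), 3))


class TestUnfoldFold:
    def test_round_trip_identity(self, rng):
        shapes = PatchTensorShapes(H=8, W=8, d=3, h=2, w=2)
        x = rng.normal(size=(8, 8, 3))
        assert np.array_equal(fold(unfold(x, shapes), shapes), x)

    def test_patch_counts(self):
        shapes = PatchTensorShapes(H=4, W=4, d=5, h=2, w=2)
        assert shapes.P == 4
        assert shapes.N == 4
        assert shapes.P * shapes.N == 16

    def test_single_patch_flattens(self, rng):
        shapes = PatchTensorShapes(H=3, W=4, d=2, h=3, w=4)
        x = rng.normal(size=(3, 4, 2))
        u = unfold(x, shapes)
        assert u.shape == (12, 1, 2)
        np.testing.assert_array_equal(u[:, 0, :], x.reshape(12, 2))

    def test_position_gathering(self):
        # 4x4 map, 2x2 patches: position (0,0) of each patch = strided view
        x = np.arange(16.0).reshape(4, 4, 1)
        shapes = PatchTensorShapes(H=4, W=4, d=1, h=2, w=2)
        u = unfold(x, shapes)
        np.testing.assert_array_equal(u[0, :, 0], [0, 2, 8, 10])

    def test_indivisible_dims_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            PatchTensorShapes(H=5, W=4, d=1, h=2, w=2)


class TestGradients:
    """Finite-difference checks of the autodiff primitives."""

    @staticmethod
    def _fd(f, tensors, rng, tol=1e-4):
        for t in tensors:
            t.grad = None
        out = f()
        w = Tensor(rng.normal(size=out.shape))
        ag.mean_axes(ag.mul(out, w), tuple(range(out.data.ndim))).backward()
        eps = 1e-5
        for t in tensors:
            idx = tuple(rng.integers(0, d) for d in t.shape)
            orig = t.data[idx]
            t.data[idx] = orig + eps
            up = ag.mean_axes(ag.mul(f(), w), tuple(range(out.data.ndim))).data
            t.data[idx] = orig - eps
            dn = ag.mean_axes(ag.mul(f(), w), tuple(range(out.data.ndim))).data
            t.data[idx] = orig
            numeric = (up - dn) / (2 * eps)
            assert abs(numeric - t.grad[idx]) < tol * max(1.0, abs(numeric))

    def test_conv2d(self, rng):
        x = Tensor(rng.normal(size=(2, 6, 6, 3)), requires_grad=True)
        w = Tensor(rng.normal(size=(3, 3, 3, 4)) * 0.3, requires_grad=True)
        b = Tensor(rng.normal(size=4), requires_grad=True)
        self._fd(lambda: ag.conv2d(x, w, b, stride=2, padding=1), [x, w, b], rng)

    def test_depthwise_conv2d(self, rng):
        x = Tensor(rng.normal(size=(2, 6, 6, 5)), requires_grad=True)
        w = Tensor(rng.normal(size=(3, 3, 5)) * 0.3, requires_grad=True)
        self._fd(lambda: ag.depthwise_conv2d(x, w, None, 1, 1), [x, w], rng)

    def test_batchnorm_training_mode(self, rng):
        x = Tensor(rng.normal(size=(3, 4, 4, 5)), requires_grad=True)
        g = Tensor(np.abs(rng.normal(size=5)) + 0.5, requires_grad=True)
        b = Tensor(rng.normal(size=5), requires_grad=True)
        rm, rv = np.zeros(5), np.ones(5)
        self._fd(lambda: ag.batchnorm(x, g, b, rm, rv, True), [x, g, b], rng)

    def test_layernorm(self, rng):
        x = Tensor(rng.normal(size=(4, 7, 3)), requires_grad=True)
        g = Tensor(np.abs(rng.normal(size=3)) + 0.5, requires_grad=True)
        b = Tensor(rng.normal(size=3), requires_grad=True)
        self._fd(lambda: ag.layernorm(x, g, b), [x, g, b], rng)

    @pytest.mark.parametrize("op", ["silu", "softmax"])
    def test_pointwise(self, rng, op):
        x = Tensor(rng.normal(size=(4, 7, 3)), requires_grad=True)
        f = {"silu": lambda: ag.silu(x),
             "softmax": lambda: ag.softmax(x, axis=-1)}[op]
        self._fd(f, [x], rng)

    def test_batched_matmul(self, rng):
        a = Tensor(rng.normal(size=(4, 5, 6)), requires_grad=True)
        b = Tensor(rng.normal(size=(4, 6, 7)), requires_grad=True)
        self._fd(lambda: ag.matmul(a, b), [a, b], rng)

    def test_cross_entropy(self, rng):
        logits = Tensor(rng.normal(size=(6, 3)), requires_grad=True)
        labels = rng.integers(0, 3, size=6)
        cross_entropy(logits, labels).backward()
        eps = 1e-6
        idx = (2, 1)
        orig = logits.data[idx]
        logits.data[idx] = orig + eps
        up = float(cross_entropy(logits, labels).data)
        logits.data[idx] = orig - eps
        dn = float(cross_entropy(logits, labels).data)
        logits.data[idx] = orig
        assert abs((up - dn) / (2 * eps) - logits.grad[idx]) < 1e-6


class TestMobileViTBlock:
    def test_output_shape_preserved(self, rng):
        block = MobileViTBlock(8, dim=16, depth=1, heads=2, mlp_dim=32,
                               rng=np.random.default_rng(0))
        x = Tensor(rng.normal(size=(2, 8, 8, 8)).astype(np.float32))
        block.set_training(True)
        assert block(x).shape == (2, 8, 8, 8)

    def test_identity_transformer_hook(self, rng):
        """With the transformer removed the block is its convolutional path."""
        seed_rng = np.random.default_rng(3)
        block = MobileViTBlock(4, dim=8, depth=1, heads=2, mlp_dim=16,
                               rng=seed_rng, transformer=None)
        assert block.transformer is None
        x = Tensor(rng.normal(size=(1, 4, 4, 4)).astype(np.float32))
        block.set_training(False)
        out = block(x)
        # conv path only: local conv -> to_dim -> from_dim -> concat -> fuse
        y = block.local(x)
        y = block.to_dim(y)
        y = block.from_dim(y)
        y = ag.concat([x, y], axis=-1)
        expected = block.fuse(y)
        np.testing.assert_allclose(out.data, expected.data, atol=1e-6)

    def test_gradient_reaches_every_parameter(self, rng):
        block = MobileViTBlock(4, dim=8, depth=1, heads=2, mlp_dim=16,
                               rng=np.random.default_rng(1))
        block.set_training(True)
        x = Tensor(rng.normal(size=(2, 8, 8, 4)).astype(np.float32),
                   requires_grad=True)
        out = block(x)
        loss = ag.mean_axes(ag.mul(out, out), (0, 1, 2, 3))
        loss.backward()
        for p in block.parameters():
            assert p.grad is not None
            assert np.all(np.isfinite(p.grad))
            assert float(np.abs(p.grad).sum()) > 0.0


def _toy_images(rng, n_per_class=6, size=32):
    """Well-separated classes: vertical vs horizontal color bars."""
    images = []
    for label in (0, 1):
        for i in range(n_per_class):
            px = np.full((size, size, 3), 255, dtype=np.uint8)
            pos = 4 + 2 * i
            if label == 0:
                px[:, pos:pos + 3] = (230, 25, 75)
            else:
                px[pos:pos + 3, :] = (0, 130, 200)
            images.append(EncodedImage(px, label=label, sample_id=f"{label}_{i}"))
    return images


@pytest.fixture(scope="module")
def toy():
    return _toy_images(np.random.default_rng(0))


@pytest.fixture(scope="module")
def toy_config():
    return ViTConfig(input_size=32, channel_plan="small", epochs=10,
                     batch_size=4, seed=0)


class TestTraining:
    def test_fits_separable_data(self, toy, toy_config):
        model, history = train(toy, toy_config)
        assert history[-1]["accuracy"] >= 0.9
        assert [h["epoch"] for h in history] == list(range(1, 11))

    def test_zero_learning_rate_freezes_parameters(self, toy):
        config = ViTConfig(input_size=32, channel_plan="small", epochs=1,
                           batch_size=4, learning_rate=0.0, seed=0)
        model, _ = train(toy, config)
        fresh = MobileViT(plan="small", n_classes=2, patch=(2, 2), seed=0)
        for (k1, p1), (k2, p2) in zip(model.named_state(), fresh.named_state()):
            if isinstance(p1, Tensor):
                assert np.array_equal(p1.data, p2.data), k1

    def test_same_seed_reproduces_final_loss(self, toy):
        config = ViTConfig(input_size=32, channel_plan="small", epochs=2,
                           batch_size=4, seed=9)
        _, h1 = train(toy, config)
        _, h2 = train(toy, config)
        assert h1[-1]["loss"] == h2[-1]["loss"]

    def test_single_class_rejected(self, toy):
        ones = [im for im in toy if im.label == 1]
        with pytest.raises(ValueError, match="2 classes"):
            train(ones, ViTConfig(input_size=32, channel_plan="small"))

    def test_predict_probabilities(self, toy, toy_config):
        model, _ = train(toy, toy_config)
        probs = predict(model, toy, toy_config.input_size)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        # duplicate image -> identical probabilities
        dup = predict(model, [toy[0], toy[0]], toy_config.input_size)
        np.testing.assert_allclose(dup[0], dup[1])

    def test_checkpoint_round_trip(self, toy, toy_config, tmp_path):
        model, _ = train(toy, toy_config)
        path = tmp_path / "model.npz"
        save_model(model, toy_config, path)
        loaded, config = load_model(path)
        a = predict(model, toy[:3], toy_config.input_size)
        b = predict(loaded, toy[:3], config.input_size)
        np.testing.assert_allclose(a, b, atol=1e-6)


def test_config_divisibility_validation():
    with pytest.raises(ValueError, match="divisible"):
        ViTConfig(input_size=100, channel_plan="small")
    reduced = small_vit_config()
    assert reduced.input_size == 32
    assert reduced.head == "flatten"
    assert reduced.crop_box is not None
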