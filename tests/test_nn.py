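"""Autodiff engine and model-zoo contracts."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.signal import correlate

from turnsignal.nn import (
    FAMILIES, ModelSpec, Tensor, build_model, conv1d, cross_entropy,
    predict_proba, spec_from_name,
)
from turnsignal.training import TrainConfig, train_model


class TestAutograd:
    def test_numeric_gradient_composite_expression(self, rng):
        """Autodiff matches central-difference gradients on a mixed graph."""
        x = Tensor(rng.standard_normal((4, 6)).astype(np.float32), requires_grad=True)
        w = Tensor(rng.standard_normal((6, 3)).astype(np.float32), requires_grad=True)

        def f():
            h = (x @ w).tanh()
            return ((h * h).sum(axis=1) + h.sigmoid().mean(axis=1)).sum()

        f().backward()
        eps = 1e-3
        for i in [(0, 0), (2, 3)]:
            g = x.grad[i]
            x.data[i] += eps
            up = float(f().data)
            x.data[i] -= 2 * eps
            dn = float(f().data)
            x.data[i] += eps
            assert g == pytest.approx((up - dn) / (2 * eps), rel=5e-2, abs=1e-3)

    def test_conv1d_matches_scipy_correlate(self, rng):
        x = rng.standard_normal((2, 3, 20)).astype(np.float32)
        w = rng.standard_normal((4, 3, 5)).astype(np.float32)
        out = conv1d(Tensor(x), Tensor(w), None).data
        for b in range(2):
            for f in range(4):
                ref = sum(correlate(x[b, c], w[f, c], mode="valid") for c in range(3))
                np.testing.assert_allclose(out[b, f], ref, rtol=1e-4, atol=1e-4)

    def test_conv1d_gradient_numeric(self, rng):
        x = Tensor(rng.standard_normal((2, 2, 12)).astype(np.float32), requires_grad=True)
        w = Tensor(rng.standard_normal((3, 2, 3)).astype(np.float32), requires_grad=True)
        y = np.array([0, 1])

        def loss():
            return cross_entropy(conv1d(x, w, None, pad=(1, 1)).mean(axis=2), y)

        loss().backward()
        eps = 1e-2
        for t in (x, w):
            i = (0,) * t.data.ndim
            g = t.grad[i]
            t.data[i] += eps
            up = float(loss().data)
            t.data[i] -= 2 * eps
            dn = float(loss().data)
            t.data[i] += eps
            assert g == pytest.approx((up - dn) / (2 * eps), rel=5e-2, abs=1e-3)

    def test_cross_entropy_uniform_logits(self):
        logits = Tensor(np.zeros((3, 2), dtype=np.float32), requires_grad=True)
        loss = cross_entropy(logits, np.array([0, 1, 0]))
        assert float(loss.data) == pytest.approx(np.log(2), rel=1e-5)

    def test_class_weights_reweight_loss(self):
        logits = Tensor(np.array([[2.0, 0.0], [0.0, 2.0]], dtype=np.float32))
        y = np.array([1, 1])
        plain = float(cross_entropy(logits, y).data)
        up = float(cross_entropy(logits, y, np.array([1.0, 5.0])).data)
        assert up == pytest.approx(plain)  # all-positive batch: weights cancel


class TestModelContracts:
    def test_output_shape(self):
        m = build_model(ModelSpec("tiny_fcn", in_channels=10, seq_len=64))
        out = m(np.zeros((4, 10, 64), dtype=np.float32))
        assert out.data.shape == (4, 2)

    def test_seeded_build_reproducible(self):
        spec = ModelSpec("inception_lite")
        a = build_model(spec, seed=3).checksum()
        b = build_model(spec, seed=3).checksum()
        c = build_model(spec, seed=4).checksum()
        assert a == b
        assert a != c

    def test_dual_concat_head_width_is_sum_of_latents(self):
        m = build_model(ModelSpec("tiny_fcn", dual=True, fusion="concat"))
        d = m.trip_encoder.latent_dim
        assert m.head.w.shape[0] == 2 * d

    def test_invalid_combinations_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("tiny_fcn", attention="single")
        with pytest.raises(ValueError):
            ModelSpec("gru", attention="self")
        with pytest.raises(ValueError):
            ModelSpec("tiny_fcn", in_channels=7)

    def test_predict_proba_rows_sum_to_one(self, rng):
        m = build_model(ModelSpec("cnn1d", in_channels=10))
        x = rng.standard_normal((9, 10, 40)).astype(np.float32)
        p = predict_proba(m, x)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()

    def test_duplicated_rows_give_duplicated_outputs(self, rng):
        m = build_model(ModelSpec("tcn", in_channels=10))
        x = rng.standard_normal((1, 10, 30)).astype(np.float32)
        p = predict_proba(m, np.repeat(x, 3, axis=0))
        np.testing.assert_allclose(p[0], p[1], atol=1e-6)
        np.testing.assert_allclose(p[0], p[2], atol=1e-6)

    def test_batch_permutation_equivariance(self, rng):
        m = build_model(ModelSpec("gru", attention="single", in_channels=10))
        x = rng.standard_normal((6, 10, 20)).astype(np.float32)
        perm = rng.permutation(6)
        p = predict_proba(m, x)
        p2 = predict_proba(m, x[perm])
        np.testing.assert_allclose(p2, p[perm], atol=1e-5)

    def test_gated_fusion_with_saturated_gate_matches_trip_branch(self, rng):
        """Forcing the gate to 1 reduces the dual model to its trip encoder."""
        dual = build_model(ModelSpec("tiny_fcn", dual=True, fusion="gated"), seed=5)
        dual.gate.w.data[:] = 0.0
        dual.gate.b.data[:] = 50.0  # sigmoid saturates at 1 -> pure trip latent
        single = build_model(ModelSpec("tiny_fcn"), seed=11)
        # copy trip-branch encoder and head weights into the single-view model
        for p_src, p_dst in zip(dual.trip_encoder.parameters(),
                                single.encoder.parameters()):
            p_dst.data[:] = p_src.data
        for m_src, m_dst in zip(dual.trip_encoder.modules(), single.encoder.modules()):
            for name in ("run_mean", "run_var"):
                if hasattr(m_src, name):
                    setattr(m_dst, name, getattr(m_src, name).copy())
        single.head.w.data[:] = dual.head.w.data
        single.head.b.data[:] = dual.head.b.data
        x_trip = rng.standard_normal((3, 10, 40)).astype(np.float32)
        x_turn = rng.standard_normal((3, 10, 40)).astype(np.float32)
        np.testing.assert_allclose(
            predict_proba(dual, (x_trip, x_turn)), predict_proba(single, x_trip),
            atol=1e-5)


class TestSanityFit:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_family_fits_separable_toy(self, family, rng):
        """Every family reaches low training loss on separable data."""
        n, C, L = 64, 10, 30
        y = np.repeat([0, 1], n // 2)
        x = rng.standard_normal((n, C, L)) + y[:, None, None] * 1.5
        epochs = 120 if family in ("gru", "lstm") else 50
        spec = ModelSpec(family, in_channels=C, seq_len=L)
        _, hist = train_model(spec, x, y, TrainConfig(epochs=epochs, seed=0))
        assert hist[-1] < 0.1
        assert len(hist) == epochs


@pytest.mark.parametrize("name,family,dual,attention", [
    ("TinyFCN", "tiny_fcn", False, "none"),
    ("GRU and attention", "gru", False, "single"),
    ("GRU and multiattention", "gru", False, "multihead"),
    ("InceptionTimeSmall", "inception_time_small", False, "none"),
    ("ResNet TSC", "resnet_tsc", False, "none"),
    ("DualTCN Attn", "tcn", True, "self"),
    ("Dual Tiny FCN", "tiny_fcn", True, "none"),
    ("1D-CNN", "cnn1d", False, "none"),
])
def test_spec_from_table_names(name, family, dual, attention):
    spec = spec_from_name(name)
    assert (spec.family, spec.dual, spec.attention) == (family, dual, attention)
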