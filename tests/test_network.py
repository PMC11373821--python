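"""Architecture contracts: shapes, attention behavior, ablations, determinism."""

import numpy as np
import pytest

from icrbp._autodiff import Tensor
from icrbp.encoders import EncodingConfig
from icrbp.network import (
    ChannelAttention, ConfigurationError, Model, ModelConfig, SpatialAttention,
    assemble_model,
)

ENC = EncodingConfig(doc2vec_dim=100)  # channel layout (3, 100, 1, 3, 1) -> 108
ENC_SMALL = EncodingConfig(doc2vec_dim=8)


def shape_oracle(cfg: ModelConfig, length: int) -> tuple[int, int]:
    """Independent shape propagation: same-padded convs keep length, pooling
    floor-halves it; channel count follows the declared widths."""
    if "no_lkcnn" in cfg.ablation:
        return length, 5 * cfg.per_scheme_filters
    L = length
    L //= 2          # average pool
    L //= 2          # max pool after the mid kernel
    L //= 2          # max pool after the kernel-3 layer
    C = cfg.width_c
    return L, C


class TestShapes:
    def test_default_stack_101(self):
        model = assemble_model(ModelConfig(), ENC, input_length=101, seed=0)
        assert model.total_channels == 108
        assert (model.out_length, model.out_channels) == (12, 128)
        assert shape_oracle(ModelConfig(), 101) == (12, 128)

    @pytest.mark.parametrize("length", [64, 101, 128])
    @pytest.mark.parametrize("flags", [frozenset(), frozenset({"no_lkcnn"}),
                                       frozenset({"minus2_layers"})])
    def test_oracle_agreement(self, length, flags):
        cfg = ModelConfig.small(ablation=flags)
        model = assemble_model(cfg, ENC_SMALL, input_length=length, seed=0)
        assert (model.out_length, model.out_channels) == shape_oracle(cfg, length)

    def test_forward_probability_shape(self):
        cfg = ModelConfig.small()
        model = assemble_model(cfg, ENC_SMALL, input_length=101, seed=0)
        x = np.random.default_rng(0).normal(size=(3, 101, model.total_channels))
        p = model.forward(x).data
        assert p.shape == (3, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(p >= 0)

    def test_too_short_input_names_minimum(self):
        with pytest.raises(ConfigurationError, match="at least"):
            assemble_model(ModelConfig.small(), ENC_SMALL, input_length=4)


class TestAblations:
    ALL_FLAGS = ["no_lkcnn", "no_cbam", "no_bigru", "cbam_standard",
                 "lkcnn_plain_cnn", "plus2_layers", "minus2_layers"]

    @pytest.mark.parametrize("flag", ALL_FLAGS)
    def test_every_variant_builds_and_runs(self, flag):
        cfg = ModelConfig.small(ablation={flag})
        model = assemble_model(cfg, ENC_SMALL, input_length=48, seed=0)
        x = np.random.default_rng(1).normal(size=(2, 48, model.total_channels))
        p = model.forward(x).data
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_combined_bypass_variant(self):
        cfg = ModelConfig.small(ablation={"no_lkcnn", "no_cbam"})
        model = assemble_model(cfg, ENC_SMALL, input_length=48, seed=0)
        assert model.out_length == 48

    def test_no_lkcnn_keeps_post_concat_shape(self):
        cfg = ModelConfig.small(ablation={"no_lkcnn"})
        model = assemble_model(cfg, ENC_SMALL, input_length=101, seed=0)
        assert (model.out_length, model.out_channels) == \
            (101, 5 * cfg.per_scheme_filters)

    def test_minus2_removes_two_kernel1_layers(self):
        def n_k1(model):
            return sum(1 for st in model.lkcnn
                       if hasattr(st, "conv") and st.conv.kernel == 1)
        full = assemble_model(ModelConfig.small(), ENC_SMALL, 101)
        minus = assemble_model(ModelConfig.small(ablation={"minus2_layers"}),
                               ENC_SMALL, 101)
        plus = assemble_model(ModelConfig.small(ablation={"plus2_layers"}),
                              ENC_SMALL, 101)
        assert n_k1(minus) == n_k1(full) - 2
        assert n_k1(plus) == n_k1(full) + 2

    def test_plain_cnn_replaces_large_kernels(self):
        cfg = ModelConfig.small(ablation={"lkcnn_plain_cnn"})
        model = assemble_model(cfg, ENC_SMALL, 101)
        kernels = [st.conv.kernel for st in model.lkcnn if hasattr(st, "conv")]
        assert 7 not in kernels and 5 not in kernels

    def test_exclusive_depth_flags_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(ablation={"plus2_layers", "minus2_layers"})

    def test_unknown_flag_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(ablation={"no_everything"})

    def test_empty_ablation_is_default_stack(self):
        a = assemble_model(ModelConfig.small(), ENC_SMALL, 101, seed=3)
        b = assemble_model(ModelConfig.small(ablation=frozenset()), ENC_SMALL,
                           101, seed=3)
        assert a.n_parameters() == b.n_parameters()
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)


class TestAttention:
    def _fm(self, rng, shape=(2, 12, 16)):
        return Tensor(rng.normal(size=shape))

    def test_channel_attention_preserves_shape(self):
        rng = np.random.default_rng(0)
        att = ChannelAttention(16, ModelConfig.small(), rng)
        x = self._fm(rng)
        assert att(x).shape == x.shape

    def test_channel_attention_zero_input_zero_output(self):
        rng = np.random.default_rng(0)
        att = ChannelAttention(16, ModelConfig.small(), rng)
        out = att(Tensor(np.zeros((1, 12, 16))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_sigmoid_weights_bound_output(self):
        rng = np.random.default_rng(1)
        cfg = ModelConfig.small()
        from dataclasses import replace
        cfg = replace(cfg, cbam_channel_activation="sigmoid")
        att = ChannelAttention(16, cfg, rng)
        x = self._fm(rng)
        out = att(x)
        assert np.all(np.abs(out.data) <= np.abs(x.data) + 1e-12)

    def test_spatial_attention_shape_and_bounds(self):
        rng = np.random.default_rng(2)
        att = SpatialAttention(ModelConfig.small(), rng)
        x = self._fm(rng)
        out = att(x)
        assert out.shape == x.shape
        # sigmoid gate: |out| <= |in| elementwise
        assert np.all(np.abs(out.data) <= np.abs(x.data) + 1e-12)

    def test_spatial_weights_equal_on_constant_input(self):
        rng = np.random.default_rng(3)
        att = SpatialAttention(ModelConfig.small(), rng)
        x = Tensor(np.ones((1, 12, 16)))
        w = att.conv(Tensor(np.concatenate(
            [np.ones((1, 12, 1)), np.ones((1, 12, 1))], axis=2))).sigmoid().data
        # interior positions (full receptive field) share one weight
        interior = w[0, 3:-3, 0]
        np.testing.assert_allclose(interior, interior[0])


class TestDeterminismAndPersistence:
    def test_same_seed_same_parameters(self):
        a = assemble_model(ModelConfig.small(), ENC_SMALL, 101, seed=5)
        b = assemble_model(ModelConfig.small(), ENC_SMALL, 101, seed=5)
        assert a.n_parameters() == b.n_parameters()
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_eval_forward_deterministic(self):
        model = assemble_model(ModelConfig.small(), ENC_SMALL, 101, seed=5)
        model.set_training(False)
        x = np.random.default_rng(0).normal(size=(2, 101, model.total_channels))
        np.testing.assert_array_equal(model.forward(x).data, model.forward(x).data)

    def test_gradient_reaches_every_stage(self):
        model = assemble_model(ModelConfig.small(), ENC_SMALL, input_length=16,
                               seed=0)
        model.set_training(True)
        x = np.random.default_rng(0).normal(size=(8, 16, model.total_channels))
        y = np.array([0, 1] * 4)
        from icrbp.train_eval import _cross_entropy
        loss = _cross_entropy(model.logits(x), y)
        loss.backward()
        for p in model.parameters():
            assert p.grad is not None
            assert np.any(p.grad != 0) or p.data.size <= 2  # tiny biases may be 0

    def test_checkpoint_round_trip(self, tmp_path):
        model = assemble_model(ModelConfig.small(), ENC_SMALL, 101, seed=8)
        model.set_training(False)
        x = np.random.default_rng(4).normal(size=(2, 101, model.total_channels))
        before = model.forward(x).data
        p = tmp_path / "ckpt.npz"
        model.save(p)
        back = Model.load(p)
        back.set_training(False)
        np.testing.assert_allclose(back.forward(x).data, before, atol=1e-12)
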