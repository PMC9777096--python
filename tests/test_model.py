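import numpy as np
import pytest

from pcgkit.model import (
    CVTNet,
    ModelConfig,
    build_model,
    interpolate_pos_embed,
    paper_profile,
    test_profile as desk_profile,
)
from pcgkit.nn.autodiff import Tensor


def tiny_profile(**overrides):
    """A minimal config for fast structural tests."""
    defaults = dict(
        input_size=64,
        stage_widths=(4, 8, 8, 8, 8, 8),
        convs_per_stage=(1, 1, 1, 1, 1, 1),
        embed_dim=16,
        heads=4,
        ffn_hidden=32,
        head_hidden=32,
    )
    defaults.update(overrides)
    return ModelConfig(**defaults)


def walk_parameter_count(cfg: ModelConfig) -> int:
    """Independent layer-walk oracle for the total parameter count."""
    total = 0

    def conv(cin, cout, k=3, bn=True):
        n = k * k * cin * cout + cout
        if bn:
            n += 2 * cout
        return n

    cin = 3
    for w, n_convs in zip(cfg.stage_widths, cfg.convs_per_stage):
        for _ in range(n_convs):
            total += conv(cin, w)
            cin = w
    C = cfg.stage_widths[-1]
    cin = 1
    for w in cfg.stage_widths[:5]:
        total += conv(cin, w)
        cin = w
    total += conv(cin, C)
    total += 3 * (C * C + C)  # WL, WC, local context 1x1 convs
    r = cfg.bottleneck_reduction
    total += C * (C // r) + C // r + (C // r) * C + C  # global bottleneck
    T, D = cfg.num_tokens, cfg.embed_dim
    total += (T * C) * D + D  # strip projection (h = T for a square map)
    total += T * D  # position embeddings
    per_block = 2 * D + 4 * (D * D + D) + 2 * D \
        + D * cfg.ffn_hidden + cfg.ffn_hidden + cfg.ffn_hidden * D + D
    total += cfg.encoder_depth * per_block
    total += 2 * D  # final norm
    total += D * cfg.head_hidden + cfg.head_hidden
    total += cfg.head_hidden * cfg.num_classes + cfg.num_classes
    return total


class TestBuild:
    def test_seeded_construction_is_deterministic(self):
        a = build_model(desk_profile(seed=0))
        b = build_model(desk_profile(seed=0))
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_lone_conv_closed_form_count(self):
        from pcgkit.model import ConvBNReLU

        layer = ConvBNReLU(2, 4, np.random.default_rng(0), k=3, bn=False)
        assert sum(p.data.size for p in layer.parameters()) == 9 * 2 * 4 + 4

    @pytest.mark.parametrize("profile", [desk_profile, paper_profile, tiny_profile])
    def test_count_matches_walk_oracle(self, profile):
        cfg = profile()
        assert build_model(cfg).parameter_count() == walk_parameter_count(cfg)

    def test_invalid_config_lists_violations(self):
        cfg = ModelConfig(input_size=100, embed_dim=30, heads=8, encoder_depth=0)
        with pytest.raises(ValueError) as err:
            cfg.validate()
        msg = str(err.value)
        assert "32" in msg and "divisible" in msg and "encoder_depth" in msg

    def test_seventeen_convs_in_paper_profile(self):
        assert paper_profile().total_convs == 17


class TestBackbone:
    def test_224_input_gives_7x7_map(self):
        cfg = tiny_profile(input_size=224)
        net = build_model(cfg)
        img = np.random.default_rng(0).uniform(size=(1, 224, 224, 3))
        fmap = net.backbone_forward(img)
        assert fmap.shape == (1, cfg.stage_widths[-1], 7, 7)

    def test_384_input_gives_12x12_map(self):
        cfg = tiny_profile(input_size=384)
        net = build_model(cfg)
        img = np.random.default_rng(0).uniform(size=(1, 384, 384, 3))
        assert net.backbone_forward(img).shape[2:] == (12, 12)

    def test_outputs_nonnegative_after_relu(self):
        net = build_model(tiny_profile())
        img = np.random.default_rng(1).uniform(size=(2, 64, 64, 3))
        assert np.all(net.backbone_forward(img).data >= 0)

    def test_size_mismatch_rejected(self):
        net = build_model(tiny_profile())
        with pytest.raises(ValueError, match="64"):
            net.backbone_forward(np.zeros((1, 32, 32, 3)))


class TestATTSF:
    def test_nulled_cnn_weights_give_pure_lbp_path(self, rng):
        net = build_model(tiny_profile())
        C = net.cfg.stage_widths[-1]
        net.wc.weight.data[:] = 0.0
        net.wc.bias.data[:] = 0.0
        cnn = Tensor(rng.normal(size=(1, C, 2, 2)))
        lbp = Tensor(rng.normal(size=(1, C, 2, 2)))
        fused = net.attsf_fuse(cnn, lbp)
        wl = net.wl(lbp, False)
        u = wl  # WC contributes nothing
        gvec = net.global_fc2(net.global_fc1(u.mean(axis=(2, 3))).relu())
        gate = (gvec.reshape(1, C, 1, 1) + net.local_ctx(u, False)).sigmoid()
        assert np.allclose(fused.data, (gate * wl).data, atol=1e-6)

    @pytest.mark.parametrize("shape", [(4, 4), (7, 7)])
    def test_output_shape_preserved(self, rng, shape):
        net = build_model(tiny_profile())
        C = net.cfg.stage_widths[-1]
        cnn = Tensor(rng.normal(size=(2, C, *shape)))
        lbp = Tensor(rng.normal(size=(2, C, *shape)))
        assert net.attsf_fuse(cnn, lbp).shape == (2, C, *shape)

    @staticmethod
    def _naive_mean(data):
        n_, c_, h_, w_ = data.shape
        naive = np.zeros((n_, c_))
        for n in range(n_):
            for c in range(c_):
                s = 0.0
                for i in range(h_):
                    for j in range(w_):
                        s += data[n, c, i, j]
                naive[n, c] = s / (h_ * w_)
        return naive

    def test_global_context_equals_naive_mean(self, rng):
        # dyadic values on a power-of-two window: both routes are exact
        x = Tensor(rng.integers(-128, 128, size=(2, 3, 4, 4)) / 64.0)
        pooled = x.mean(axis=(2, 3)).data
        assert np.max(np.abs(pooled - self._naive_mean(x.data))) <= 1e-9
        # arbitrary data: agreement to float32 round-off
        y = Tensor(rng.normal(size=(2, 3, 5, 4)))
        pooled = y.mean(axis=(2, 3)).data
        assert np.allclose(pooled, self._naive_mean(y.data), atol=1e-5)

    def test_gate_strictly_inside_unit_interval(self, rng):
        net = build_model(tiny_profile())
        C = net.cfg.stage_widths[-1]
        u = Tensor(rng.normal(size=(1, C, 2, 2)))
        gvec = net.global_fc2(net.global_fc1(u.mean(axis=(2, 3))).relu())
        gate = (gvec.reshape(1, C, 1, 1) + net.local_ctx(u, False)).sigmoid().data
        assert np.all(gate > 0.0) and np.all(gate < 1.0)

    def test_half_gate_reduces_to_plain_sum(self, rng):
        """With the gate forced to 1/2 the fusion is the averaged 1x1 mix."""
        net = build_model(tiny_profile())
        # zero the context aggregators so sigmoid(0) = 0.5 everywhere
        for layer in (net.local_ctx,):
            layer.weight.data[:] = 0.0
            layer.bias.data[:] = 0.0
        net.global_fc2.weight.data[:] = 0.0
        net.global_fc2.bias.data[:] = 0.0
        C = net.cfg.stage_widths[-1]
        cnn = Tensor(rng.normal(size=(1, C, 3, 3)))
        lbp = Tensor(rng.normal(size=(1, C, 3, 3)))
        fused = net.attsf_fuse(cnn, lbp)
        expected = 0.5 * (net.wl(lbp, False).data + net.wc(cnn, False).data)
        assert np.allclose(fused.data, expected, atol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        net = build_model(tiny_profile())
        C = net.cfg.stage_widths[-1]
        with pytest.raises(ValueError, match="shapes"):
            net.attsf_fuse(
                Tensor(np.zeros((1, C, 2, 2))), Tensor(np.zeros((1, C, 4, 4)))
            )


class TestTokenizer:
    def test_paper_profile_token_geometry(self):
        cfg = paper_profile()
        assert cfg.num_tokens == 7
        assert cfg.embed_dim == 1024

    def test_zero_map_gives_bias_plus_positions(self):
        net = build_model(tiny_profile())
        C = net.cfg.stage_widths[-1]
        T = net.cfg.num_tokens
        tokens = net.tokenize(Tensor(np.zeros((1, C, T, T))))
        expected = net.token_proj.bias.data + net.pos_embed.data
        assert np.allclose(tokens.data[0], expected, atol=1e-7)

    def test_strip_permutation_equivariance_without_positions(self, rng):
        net = build_model(tiny_profile())
        net.pos_embed.data[:] = 0.0
        C = net.cfg.stage_widths[-1]
        T = net.cfg.num_tokens
        fmap = rng.normal(size=(1, C, T, T)).astype(np.float32)
        perm = np.array([1, 0])[: T] if T == 2 else rng.permutation(T)
        tok = net.tokenize(Tensor(fmap)).data
        tok_p = net.tokenize(Tensor(fmap[:, :, :, perm])).data
        assert np.allclose(tok[:, perm], tok_p, atol=1e-6)


class TestEncoder:
    def test_attention_rows_sum_to_one(self, rng):
        net = build_model(tiny_profile())
        tokens = Tensor(rng.normal(size=(2, net.cfg.num_tokens, net.cfg.embed_dim)))
        net.transformer_encode(tokens)
        attn = net.blocks[0].attn.last_attention_
        assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_two_token_closed_form_single_head(self):
        """Identity Q=K=V=O weights: attention is a softmax-weighted average."""
        from pcgkit.model import MultiHeadSelfAttention

        msa = MultiHeadSelfAttention(2, 1, np.random.default_rng(0))
        for lin in (msa.wq, msa.wk, msa.wv, msa.wo):
            lin.weight.data = np.eye(2, dtype=np.float32)
            lin.bias.data[:] = 0.0
        x = np.array([[[1.0, 0.0], [0.0, 2.0]]], dtype=np.float32)
        out = msa(Tensor(x)).data[0]
        scores = x[0] @ x[0].T / np.sqrt(2.0)
        attn = np.exp(scores) / np.exp(scores).sum(axis=1, keepdims=True)
        assert np.allclose(out, attn @ x[0], atol=1e-6)

    def test_shape_unchanged(self, rng):
        net = build_model(tiny_profile())
        tokens = Tensor(rng.normal(size=(3, net.cfg.num_tokens, net.cfg.embed_dim)))
        out = net.transformer_encode(tokens)
        assert out.shape == tokens.shape

    def test_permutation_equivariance_of_encoder(self, rng):
        net = build_model(tiny_profile())
        T, D = net.cfg.num_tokens, net.cfg.embed_dim
        x = rng.normal(size=(1, T, D)).astype(np.float32)
        perm = rng.permutation(T)
        out = net.transformer_encode(Tensor(x)).data
        out_p = net.transformer_encode(Tensor(x[:, perm])).data
        assert np.allclose(out[:, perm], out_p, atol=1e-5)


class TestClassify:
    def test_probabilities_sum_to_one(self, rng):
        net = build_model(tiny_profile())
        tokens = Tensor(rng.normal(size=(4, net.cfg.num_tokens, net.cfg.embed_dim)))
        probs = net.classify(tokens).data
        assert probs.shape == (4, 5)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_equal_logits_give_uniform(self):
        net = build_model(tiny_profile())
        net.head_fc2.weight.data[:] = 0.0
        net.head_fc2.bias.data[:] = 0.0
        tokens = Tensor(np.random.default_rng(0).normal(
            size=(2, net.cfg.num_tokens, net.cfg.embed_dim)))
        probs = net.classify(tokens).data
        assert np.allclose(probs, 0.2, atol=1e-7)


class TestForward:
    def test_eval_forward_is_bit_deterministic(self, rng):
        net = build_model(tiny_profile())
        img = rng.uniform(size=(2, 64, 64, 3))
        a = net.forward(img)
        b = net.forward(img)
        assert np.array_equal(a, b)

    def test_batch_of_probability_rows(self, rng):
        net = build_model(tiny_profile())
        img = rng.uniform(size=(3, 64, 64, 3))
        probs = net.forward(img)
        assert probs.shape == (3, 5)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_gradients_flow_to_every_parameter(self, rng):
        from pcgkit.nn.autodiff import cross_entropy

        net = build_model(tiny_profile())
        img = rng.uniform(size=(2, 64, 64, 3))
        logits = net.forward_logits(img, training=True)
        loss = cross_entropy(logits, np.array([0, 3]))
        loss.backward()
        for p in net.parameters():
            assert p.grad is not None
            assert np.all(np.isfinite(p.grad))

    def test_save_load_roundtrip(self, rng, tmp_path):
        net = build_model(tiny_profile())
        img = rng.uniform(size=(1, 64, 64, 3))
        before = net.forward(img)
        net.save(tmp_path / "m.ckpt")
        loaded = CVTNet.load(tmp_path / "m.ckpt")
        assert np.array_equal(loaded.forward(img), before)


class TestPosEmbedInterpolation:
    def test_identity_at_same_length(self, rng):
        pos = rng.normal(size=(7, 16))
        assert np.array_equal(interpolate_pos_embed(pos, 7), pos)

    def test_endpoints_preserved_7_to_12(self, rng):
        pos = rng.normal(size=(7, 16))
        out = interpolate_pos_embed(pos, 12)
        assert out.shape == (12, 16)
        assert np.allclose(out[0], pos[0]) and np.allclose(out[-1], pos[-1])
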