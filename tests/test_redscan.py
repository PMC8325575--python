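import numpy as np
import pytest

from casct.autodiff import Tensor
from casct.errors import ContractError
from casct.redscan import (
    ChannelAttention,
    RedSCAN,
    RedSCANConfig,
    SpatialAttention,
    build_redscan,
    channel_attention,
    count_parameters,
    redscab_forward,
    sca_fuse,
    spatial_attention,
)


def small_config(**kw):
    base = dict(n_features=4, n_blocks=2, n_dense_convs=3, growth=3,
                ca_reduction=2, seed=11)
    base.update(kw)
    return RedSCANConfig(**base)


# ---------------------------------------------------------------------------
# straight-line oracle: explicit-loop evaluation of the block equations

def conv_loops(x, w, b, pad):
    cin, h, wd = x.shape
    cout, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    out = np.zeros((cout, h, wd))
    for o in range(cout):
        for i in range(h):
            for j in range(wd):
                acc = b[o]
                for c in range(cin):
                    for u in range(kh):
                        for v in range(kw):
                            acc += w[o, c, u, v] * xp[c, i + u, j + v]
                out[o, i, j] = acc
    return out


def sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


def oracle_channel_attention(f, w1, b1, w2, b2):
    c = f.shape[0]
    v = np.array([f[z].mean() for z in range(c)])
    vhat = sigmoid(w2 @ np.maximum(w1 @ v + b1, 0.0) + b2)
    return np.stack([f[z] * vhat[z] for z in range(c)]), vhat


def oracle_spatial_attention(f, w3, b3):
    m = conv_loops(f, w3, b3, 0)[0]
    mhat = sigmoid(m)
    return f * mhat[None], mhat


def oracle_redscab(f_prev, block, slope):
    feats = [f_prev]
    for conv in block.dense:
        z = conv_loops(np.concatenate(feats, axis=0), conv.w.data, conv.b.data, 1)
        feats.append(np.where(z > 0, z, slope * z))
    f_lf = conv_loops(np.concatenate(feats, axis=0), block.lff.w.data,
                      block.lff.b.data, 0)
    f_ca, _ = oracle_channel_attention(
        f_lf, block.ca.fc1.w.data, block.ca.fc1.b.data,
        block.ca.fc2.w.data, block.ca.fc2.b.data,
    )
    f_sa, _ = oracle_spatial_attention(
        f_lf, block.sa.conv.w.data, block.sa.conv.b.data
    )
    return f_ca + f_sa + f_prev


class TestAttention:
    def test_channel_attention_matches_oracle(self):
        rng = np.random.default_rng(0)
        ca = ChannelAttention(4, 2, rng)
        f = rng.normal(size=(4, 3, 3))
        ref, vhat = oracle_channel_attention(
            f, ca.fc1.w.data, ca.fc1.b.data, ca.fc2.w.data, ca.fc2.b.data
        )
        out = channel_attention(f, ca)
        assert np.allclose(out, ref, rtol=1e-7, atol=1e-12)
        assert np.all((vhat > 0) & (vhat < 1))

    def test_channel_attention_zero_weights_halves_features(self):
        rng = np.random.default_rng(1)
        ca = ChannelAttention(4, 2, rng)
        for p in ca.parameters():
            p.data[...] = 0.0
        f = rng.normal(size=(4, 5, 5))
        assert np.allclose(channel_attention(f, ca), 0.5 * f)

    def test_channel_squeeze_of_constant_channel(self):
        rng = np.random.default_rng(2)
        ca = ChannelAttention(2, 2, rng)
        f = np.stack([np.full((3, 3), 4.2), np.zeros((3, 3))])
        v = ca.calibration(Tensor(f[None]))  # just ensure pooling sees 4.2
        pooled = f.mean(axis=(1, 2))
        assert pooled[0] == 4.2

    def test_spatial_attention_matches_oracle(self):
        rng = np.random.default_rng(3)
        sa = SpatialAttention(4, rng)
        f = rng.normal(size=(4, 3, 5))
        ref, mhat = oracle_spatial_attention(f, sa.conv.w.data, sa.conv.b.data)
        out = spatial_attention(f, sa)
        assert np.allclose(out, ref, rtol=1e-7, atol=1e-12)
        assert np.all((mhat > 0) & (mhat < 1))

    def test_spatial_attention_zero_weights_halves_features(self):
        rng = np.random.default_rng(4)
        sa = SpatialAttention(3, rng)
        for p in sa.parameters():
            p.data[...] = 0.0
        f = rng.normal(size=(3, 4, 4))
        assert np.allclose(spatial_attention(f, sa), 0.5 * f)

    def test_sca_fuse_sum_and_shapes(self):
        f = np.random.default_rng(5).normal(size=(3, 2, 2))
        assert np.allclose(sca_fuse(0.5 * f, 0.5 * f), f)
        with pytest.raises(ContractError):
            sca_fuse(f, f[:2])


class TestRedSCAB:
    def test_matches_loop_oracle(self):
        cfg = small_config()
        net = build_redscan(cfg)
        block = net.blocks[0]
        rng = np.random.default_rng(6)
        f = rng.normal(size=(4, 5, 6))
        ref = oracle_redscab(f, block, cfg.leaky_slope)
        out = redscab_forward(f, block)
        denom = np.abs(ref).max()
        assert np.abs(out - ref).max() <= 1e-5 * denom

    def test_zero_weight_block_is_identity(self):
        net = build_redscan(small_config())
        block = net.blocks[1]
        block.zero_()
        f = np.random.default_rng(7).normal(size=(4, 6, 6))
        assert np.array_equal(redscab_forward(f, block), f)

    def test_output_shape_preserved(self):
        net = build_redscan(small_config())
        for shape in [(4, 3, 3), (4, 7, 12)]:
            f = np.zeros(shape)
            assert redscab_forward(f, net.blocks[0]).shape == shape

    def test_disabled_attention_passes_lff_through(self):
        """With both attentions off the block is a plain residual dense block."""
        cfg_off = small_config(use_channel_attention=False,
                               use_spatial_attention=False)
        net_off = build_redscan(cfg_off)
        block = net_off.blocks[0]
        rng = np.random.default_rng(8)
        f = rng.normal(size=(4, 5, 5))
        # oracle without attention: LFF output + residual
        feats = [f]
        for conv in block.dense:
            z = conv_loops(np.concatenate(feats, 0), conv.w.data, conv.b.data, 1)
            feats.append(np.where(z > 0, z, cfg_off.leaky_slope * z))
        ref = conv_loops(np.concatenate(feats, 0), block.lff.w.data,
                         block.lff.b.data, 0) + f
        assert np.allclose(redscab_forward(f, block), ref, rtol=1e-7, atol=1e-12)


class TestRedSCAN:
    def test_fully_convolutional_shape(self):
        net = build_redscan(small_config())
        x = np.random.default_rng(9).normal(size=(64, 64))
        assert net.forward_array(x).shape == (64, 64)

    def test_zero_weight_network_is_zero_map(self):
        net = build_redscan(small_config())
        net.zero_()
        x = np.random.default_rng(10).normal(size=(16, 16))
        assert np.all(net.forward_array(x) == 0)

    def test_default_parameter_count_in_millions(self):
        """The stated architecture has 0.51M learnable scalars."""
        n = count_parameters(build_redscan(RedSCANConfig()))
        assert int(n / 1e6 * 100) / 100 == 0.51

    def test_hand_counted_minimal_config(self):
        # C=1, one block, growth 1, 4 dense convs, reduction 1:
        # IFE 10+10; dense convs 10+19+28+37; LFF 6; CA 2+2; SA 2;
        # GFF 2+10; final 10  => 148
        cfg = RedSCANConfig(n_features=1, n_blocks=1, growth=1, ca_reduction=1)
        assert count_parameters(build_redscan(cfg)) == 148

    def test_seeded_init_is_reproducible(self):
        a = build_redscan(small_config())
        b = build_redscan(small_config())
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_invalid_config_rejected(self):
        with pytest.raises(ContractError):
            RedSCANConfig(n_features=5, ca_reduction=2)
        with pytest.raises(ContractError):
            RedSCANConfig(n_blocks=0)
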