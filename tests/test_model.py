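"""Split-Attention block correctness (loop oracle), variant topologies, top-k."""

import numpy as np
import pytest

from dsnetax.model import (
    SplitAttnConfig, SplitAttentionBlock, build_model,
    load_checkpoint, predict_topk, rsoftmax, save_checkpoint,
)
from dsnetax.nn import Tensor, softmax_cross_entropy
from dsnetax.pipeline import desk_model_config


# ---------------------------------------------------------------- oracles ----

def naive_conv2d(x, w, b, stride, padding, groups=1):
    """Straight-loop convolution oracle (no im2col, no vectorization)."""
    B, Cin, H, W = x.shape
    Cout, Cin_g, kh, kw = w.shape
    sh, sw = stride
    ph, pw = padding
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    out = np.zeros((B, Cout, Ho, Wo))
    cpg_out = Cout // groups
    for bi in range(B):
        for co in range(Cout):
            g = co // cpg_out
            for ho in range(Ho):
                for wo in range(Wo):
                    patch = xp[bi, g * Cin_g:(g + 1) * Cin_g,
                               ho * sh:ho * sh + kh, wo * sw:wo * sw + kw]
                    out[bi, co, ho, wo] = (patch * w[co]).sum()
            if b is not None:
                out[bi, co] += b[co]
    return out


def naive_bn(x, bn):
    mu, var = bn.running_mean, bn.running_var
    return bn.gamma.data * (x - mu) / np.sqrt(var + bn.eps) + bn.beta.data


def naive_split_attention(block: SplitAttentionBlock, x: np.ndarray) -> np.ndarray:
    """Per-group, per-radix loop re-implementation using the block's weights.

    The block must be in eval mode so batch normalization uses its stored
    statistics, which this oracle replays.
    """
    cfg = block.cfg
    radix, card, width = cfg.radix, cfg.cardinality, block.width
    s = (block.stride, block.stride)
    y = naive_conv2d(x, block.conv_reduce.weight.data, None, (1, 1), (0, 0))
    y = np.maximum(naive_bn(y, block.bn1), 0)
    y = naive_conv2d(y, block.conv_radix.weight.data, None, s, (1, 1),
                     groups=card * radix)
    y = np.maximum(naive_bn(y, block.bn2), 0)
    B, _, H, W = y.shape
    splits = [y[:, r * width:(r + 1) * width] for r in range(radix)]
    gathered = np.sum(splits, axis=0)
    pooled = gathered.mean(axis=(2, 3))[:, :, None, None]
    gate = naive_conv2d(pooled, block.fc1.weight.data, block.fc1.bias.data,
                        (1, 1), (0, 0), groups=card)
    gate = np.maximum(gate, 0)
    gate = naive_conv2d(gate, block.fc2.weight.data, block.fc2.bias.data,
                        (1, 1), (0, 0), groups=card)[:, :, 0, 0]
    # r-softmax by explicit loops over (group, channel)
    per_group = width // card
    attn = np.zeros((B, radix, width))
    for bi in range(B):
        for g in range(card):
            for c in range(per_group):
                logits = np.array([
                    gate[bi, g * radix * per_group + r * per_group + c]
                    for r in range(radix)
                ])
                if radix > 1:
                    e = np.exp(logits - logits.max())
                    w = e / e.sum()
                else:
                    w = 1.0 / (1.0 + np.exp(-logits))
                for r in range(radix):
                    attn[bi, r, g * per_group + c] = w[r]
    out = np.zeros_like(splits[0])
    for r in range(radix):
        out += splits[r] * attn[:, r][:, :, None, None]
    out = naive_conv2d(out, block.conv_expand.weight.data, None, (1, 1), (0, 0))
    out = naive_bn(out, block.bn3)
    if block.downsample is not None:
        conv_d, bn_d = block.downsample.layers
        identity = naive_bn(naive_conv2d(x, conv_d.weight.data, None, s, (0, 0)), bn_d)
    else:
        identity = x
    return np.maximum(out + identity, 0)


# ------------------------------------------------------------------ tests ----

class TestRSoftmax:
    @pytest.mark.parametrize("radix,card,width", [(2, 1, 8), (2, 2, 8), (4, 1, 8), (3, 2, 12)])
    def test_weights_sum_to_one_over_radix(self, radix, card, width):
        rng = np.random.default_rng(0)
        logits = Tensor(rng.standard_normal((5, width * radix)) * 3)
        w = rsoftmax(logits, radix, card).data
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)

    def test_radix_one_is_sigmoid_gate(self):
        rng = np.random.default_rng(1)
        logits = rng.standard_normal((4, 8))
        w = rsoftmax(Tensor(logits), 1, 1).data
        np.testing.assert_allclose(w[:, 0], 1 / (1 + np.exp(-logits)), atol=1e-12)


class TestSplitAttentionBlock:
    @pytest.mark.parametrize("radix,card,stride", [(2, 1, 1), (2, 2, 1), (2, 1, 2), (4, 1, 1), (3, 1, 2)])
    def test_vectorized_equals_naive_loop_oracle(self, radix, card, stride):
        rng = np.random.default_rng(7)
        cfg = SplitAttnConfig(cardinality=card, radix=radix, reduction=4)
        block = SplitAttentionBlock(8, 12 if radix == 3 else 8, rng, cfg, stride=stride)
        # push the BN running stats off their init so the oracle replays real stats
        block.train()
        for _ in range(3):
            block(Tensor(rng.standard_normal((4, 8, 8, 8))))
        block.eval()
        x = rng.standard_normal((2, 8, 8, 8))
        got = block(Tensor(x)).data
        want = naive_split_attention(block, x)
        assert np.max(np.abs(got - want)) < 1e-5

    def test_radix_one_matches_se_style_gate_oracle(self):
        """At radix 1 the recombination is a squeeze-excite sigmoid gate."""
        rng = np.random.default_rng(8)
        cfg = SplitAttnConfig(cardinality=1, radix=1, reduction=4)
        block = SplitAttentionBlock(8, 8, rng, cfg, stride=1)
        block.eval()
        x = rng.standard_normal((2, 8, 6, 6))
        got = block(Tensor(x)).data
        # SE oracle: y -> y * sigmoid(fc2(relu(fc1(gap(y)))))
        y = naive_conv2d(x, block.conv_reduce.weight.data, None, (1, 1), (0, 0))
        y = np.maximum(naive_bn(y, block.bn1), 0)
        y = naive_conv2d(y, block.conv_radix.weight.data, None, (1, 1), (1, 1))
        y = np.maximum(naive_bn(y, block.bn2), 0)
        pooled = y.mean(axis=(2, 3))[:, :, None, None]
        gate = np.maximum(naive_conv2d(pooled, block.fc1.weight.data,
                                       block.fc1.bias.data, (1, 1), (0, 0)), 0)
        gate = naive_conv2d(gate, block.fc2.weight.data, block.fc2.bias.data,
                            (1, 1), (0, 0))
        se = y * (1 / (1 + np.exp(-gate)))
        out = naive_bn(naive_conv2d(se, block.conv_expand.weight.data, None,
                                    (1, 1), (0, 0)), block.bn3)
        want = np.maximum(out + x, 0)
        assert np.max(np.abs(got - want)) < 1e-5

    def test_incompatible_width_rejected_at_build(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="divisible"):
            SplitAttentionBlock(8, 10, rng, SplitAttnConfig(cardinality=2, radix=2))


class TestTopologies:
    def test_default_deep_branch_has_nine_split_attention_blocks(self):
        model = build_model(desk_model_config(n_classes=5))
        counts = model.count_blocks()
        assert counts["split_attention"] == 9  # stages 2+3+2+2
        assert counts["shallow_convs"] == 3

    def test_resnet34_variant_block_count(self):
        model = build_model(desk_model_config(n_classes=5, variant="resnet34"))
        counts = model.count_blocks()
        assert counts["basic"] == 16  # 3+4+6+3
        assert counts["split_attention"] == 0

    def test_cnn3_variant_is_three_convs(self):
        model = build_model(desk_model_config(n_classes=5, variant="cnn3"))
        counts = model.count_blocks()
        assert counts == {"split_attention": 0, "basic": 0, "shallow_convs": 3}

    @pytest.mark.parametrize("layers", [3, 4, 5])
    def test_shallow_depth_ablation(self, layers):
        model = build_model(desk_model_config(n_classes=5, shallow_layers=layers))
        assert model.count_blocks()["shallow_convs"] == layers

    def test_output_length_independent_of_sequence_length(self):
        model = build_model(desk_model_config(n_classes=7))
        model.eval()
        outs = [model(Tensor(np.random.default_rng(i).standard_normal((2, 1, L, 16)))).data
                for i, L in enumerate((64, 128, 256))]
        assert all(o.shape == (2, 7) for o in outs)

    def test_batch_equivariance(self):
        model = build_model(desk_model_config(n_classes=4))
        model.eval()
        x = np.random.default_rng(3).standard_normal((4, 1, 64, 16))
        z = model(Tensor(x)).data
        perm = np.array([2, 0, 3, 1])
        z_perm = model(Tensor(x[perm])).data
        np.testing.assert_allclose(z_perm, z[perm], atol=1e-9)

    def test_shallow_branch_outputs_nonnegative(self):
        model = build_model(desk_model_config(n_classes=4, variant="cnn3"))
        model.eval()
        x = np.random.default_rng(4).standard_normal((2, 1, 64, 16))
        assert (model.shallow(Tensor(x)).data >= -1e-12).all()

    def test_gradients_reach_both_branches(self):
        model = build_model(desk_model_config(n_classes=6))
        x = Tensor(np.random.default_rng(5).standard_normal((4, 1, 64, 16)))
        loss = softmax_cross_entropy(model(x), np.array([0, 1, 2, 3]))
        loss.backward()
        deep_w = model.deep.stem.conv.weight
        shallow_w = model.shallow.convs.layers[0].weight
        assert np.abs(deep_w.grad).max() > 0
        assert np.abs(shallow_w.grad).max() > 0


class TestPredictTopk:
    def test_ranked_labels(self):
        assert list(predict_topk(np.array([0.1, 0.9, 0.5]), 2)) == [1, 2]

    def test_full_k_is_permutation(self):
        z = np.random.default_rng(0).standard_normal(9)
        assert sorted(predict_topk(z, 9)) == list(range(9))

    def test_ties_break_by_ascending_label(self):
        assert list(predict_topk(np.zeros(6), 3)) == [0, 1, 2]

    def test_out_of_range_k_rejected(self):
        with pytest.raises(ValueError):
            predict_topk(np.zeros(3), 4)
        with pytest.raises(ValueError):
            predict_topk(np.zeros(3), 0)

    def test_batched_input(self):
        z = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert predict_topk(z, 1).tolist() == [[1], [0]]


class TestCheckpoint:
    def test_round_trip_and_fingerprint_guard(self, tmp_path):
        model = build_model(desk_model_config(n_classes=4, seed=2))
        model.eval()
        x = np.random.default_rng(0).standard_normal((2, 1, 64, 16))
        before = model(Tensor(x)).data
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, "kmer-vocab/k=3/size=69")
        back = load_checkpoint(path, expect_vocab_fingerprint="kmer-vocab/k=3/size=69")
        back.eval()
        np.testing.assert_allclose(back(Tensor(x)).data, before, atol=1e-12)
        with pytest.raises(ValueError, match="fingerprint"):
            load_checkpoint(path, expect_vocab_fingerprint="kmer-vocab/k=4/size=261")
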