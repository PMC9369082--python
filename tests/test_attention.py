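"""Attention arithmetic against independent nested-loop oracles."""

import math

import numpy as np
import pytest

from csatdta.attention import (
    AttentionSpec,
    aaconv,
    count_params_delta,
    init_attention_weights,
    multi_head_attention,
    relative_logits,
    single_head_attention,
)


# ---------------------------------------------------------------------------
# scalar oracles: explicit loops, no vectorisation shared with the package


def single_head_oracle(x, w_q, w_k, w_v, dkh, rel=None):
    """Triple-nested-loop scaled dot-product attention for one head."""
    w, f = x.shape
    q = [[sum(x[i][c] * w_q[c][d] for c in range(f)) for d in range(dkh)]
         for i in range(w)]
    k = [[sum(x[i][c] * w_k[c][d] for c in range(f)) for d in range(dkh)]
         for i in range(w)]
    dv = w_v.shape[1]
    v = [[sum(x[i][c] * w_v[c][d] for c in range(f)) for d in range(dv)]
         for i in range(w)]
    out = np.zeros((w, dv))
    attn = np.zeros((w, w))
    centre = rel.shape[0] // 2 if rel is not None else 0
    for i in range(w):
        logits = []
        for j in range(w):
            l = sum(q[i][d] * k[j][d] for d in range(dkh))
            if rel is not None:
                l += sum(q[i][d] * rel[j - i + centre][d] for d in range(dkh))
            logits.append(l / math.sqrt(dkh))
        m = max(logits)
        exps = [math.exp(l - m) for l in logits]
        s = sum(exps)
        for j in range(w):
            attn[i][j] = exps[j] / s
            for d in range(dv):
                out[i][d] += attn[i][j] * v[j][d]
    return out, attn


def conv1d_same_oracle(x, kernel):
    """Explicit sliding-window 'same' convolution, scalar loops."""
    w, cin = x.shape
    k, _, cout = kernel.shape
    left = (k - 1) // 2
    out = np.zeros((w, cout))
    for pos in range(w):
        for t in range(k):
            src = pos + t - left
            if 0 <= src < w:
                for ci in range(cin):
                    for co in range(cout):
                        out[pos][co] += x[src][ci] * kernel[t][ci][co]
    return out


def small_spec(**kw):
    base = dict(f_in=8, f_out=12, d_k=4, d_v=4, n_heads=2, kernel_size=3,
                use_relative=False)
    base.update(kw)
    return AttentionSpec(**base)


class TestAttentionSpec:
    def test_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            AttentionSpec(8, 12, 5, 4, 2, 3)

    def test_ratios(self):
        s = small_spec()
        assert s.kappa == pytest.approx(4 / 12)
        assert s.v_ratio == pytest.approx(4 / 12)
        assert (s.d_k_head, s.d_v_head) == (2, 2)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            AttentionSpec(0, 12, 4, 4, 2, 3)


class TestSingleHead:
    def test_single_position_passes_through_value_projection(self, rng):
        spec = small_spec(n_heads=1)
        x = rng.normal(size=(1, 8))
        wq, wk = rng.normal(size=(8, 4)), rng.normal(size=(8, 4))
        wv = rng.normal(size=(8, 4))
        out = single_head_attention(x, wq, wk, wv, spec)
        np.testing.assert_allclose(out, x @ wv, atol=1e-12)

    def test_zero_query_gives_uniform_attention(self, rng):
        spec = small_spec(n_heads=1)
        x = rng.normal(size=(6, 8))
        wv = rng.normal(size=(8, 4))
        out, attn = single_head_attention(
            x, np.zeros((8, 4)), rng.normal(size=(8, 4)), wv, spec,
            return_attention=True,
        )
        np.testing.assert_allclose(attn, 1 / 6, atol=1e-12)
        np.testing.assert_allclose(
            out, np.tile((x @ wv).mean(axis=0), (6, 1)), atol=1e-12
        )

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(42)
        spec = small_spec()
        x = rng.normal(size=(4, 8))
        wq, wk = rng.normal(size=(8, 2)), rng.normal(size=(8, 2))
        wv = rng.normal(size=(8, 2))
        out, attn = single_head_attention(
            x, wq, wk, wv, spec, return_attention=True
        )
        exp_out, exp_attn = single_head_oracle(x, wq, wk, wv, 2)
        np.testing.assert_allclose(out, exp_out, atol=1e-6)
        np.testing.assert_allclose(attn, exp_attn, atol=1e-6)

    def test_rejects_non_finite_input(self, rng):
        spec = small_spec()
        x = rng.normal(size=(4, 8))
        x[1, 2] = np.nan
        with pytest.raises(ValueError, match="finite"):
            single_head_attention(x, np.zeros((8, 2)), np.zeros((8, 2)),
                                  np.zeros((8, 2)), spec)

    def test_rejects_channel_mismatch(self, rng):
        with pytest.raises(ValueError, match="channels"):
            single_head_attention(rng.normal(size=(4, 5)), np.zeros((8, 2)),
                                  np.zeros((8, 2)), np.zeros((8, 2)),
                                  small_spec())


class TestMultiHead:
    def test_single_head_with_identity_projection_degenerates(self, rng):
        spec = small_spec(n_heads=1)
        w = init_attention_weights(spec, rng)
        w.w_o = np.eye(spec.d_v)
        out = multi_head_attention(rng2 := rng.normal(size=(5, 8)), w, spec)
        single = single_head_attention(rng2, w.w_q[0], w.w_k[0], w.w_v[0], spec)
        np.testing.assert_allclose(out, single, atol=1e-12)

    def test_output_reshaped_to_feature_map_with_dv_channels(self, rng):
        spec = AttentionSpec(16, 24, 8, 8, 2, 3, use_relative=False)
        w = init_attention_weights(spec, rng)
        out = multi_head_attention(rng.normal(size=(1, 10, 16)), w, spec)
        assert out.shape == (1, 10, 8)

    def test_matches_concat_then_project_oracle(self):
        rng = np.random.default_rng(7)
        spec = small_spec()
        w = init_attention_weights(spec, rng)
        x = rng.normal(size=(5, 8))
        heads = [
            single_head_oracle(x, w.w_q[h], w.w_k[h], w.w_v[h], 2)[0]
            for h in range(2)
        ]
        expected = np.concatenate(heads, axis=-1) @ w.w_o
        np.testing.assert_allclose(
            multi_head_attention(x, w, spec), expected, atol=1e-6
        )

    def test_vectorised_equals_oracle_on_many_random_tensors(self):
        # 20 random (shape, seed) combinations, rows of every attention
        # matrix summing to one
        for trial in range(20):
            rng = np.random.default_rng(1000 + trial)
            nh = int(rng.integers(1, 4))
            dkh = int(rng.integers(1, 4))
            dvh = int(rng.integers(1, 4))
            f_in = int(rng.integers(2, 10))
            w_len = int(rng.integers(2, 9))
            spec = AttentionSpec(
                f_in, 4 * nh * max(dkh, dvh), nh * dkh, nh * dvh, nh, 3,
                use_relative=False,
            )
            weights = init_attention_weights(spec, rng)
            x = rng.normal(size=(w_len, f_in)) * 3
            out = multi_head_attention(x, weights, spec)
            heads = []
            for h in range(nh):
                o, attn = single_head_oracle(
                    x, weights.w_q[h], weights.w_k[h], weights.w_v[h], dkh
                )
                heads.append(o)
                np.testing.assert_allclose(
                    attn.sum(axis=1), 1.0, atol=1e-6
                )
            expected = np.concatenate(heads, axis=-1) @ weights.w_o
            np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_attention_rows_sum_to_one_for_large_logits(self, rng):
        spec = small_spec(n_heads=1)
        x = rng.normal(size=(5, 8)) * 50  # logits around 1e3-1e4
        _, attn = single_head_attention(
            x, np.eye(8)[:, :2] * 10, np.eye(8)[:, :2] * 10,
            rng.normal(size=(8, 2)), spec, return_attention=True,
        )
        assert np.isfinite(attn).all()
        np.testing.assert_allclose(attn.sum(axis=1), 1.0, atol=1e-6)


class TestRelativeLogits:
    def test_zero_embeddings_leave_attention_unchanged(self, rng):
        spec = small_spec(use_relative=True)
        q = rng.normal(size=(4, 2))
        np.testing.assert_array_equal(
            relative_logits(q, np.zeros((7, 2)), spec), np.zeros((4, 4))
        )

    def test_single_position_uses_zero_offset_only(self, rng):
        spec = small_spec(use_relative=True)
        q = rng.normal(size=(1, 2))
        emb = rng.normal(size=(1, 2))
        np.testing.assert_allclose(
            relative_logits(q, emb, spec), (q @ emb.T), atol=1e-12
        )

    def test_unit_offset_embedding_hits_superdiagonal(self):
        spec = small_spec(use_relative=True)
        w = 3
        emb = np.zeros((2 * w - 1, 2))
        emb[w] = [1.0, 1.0]  # offset +1 only
        q = np.ones((w, 2))
        logits = relative_logits(q, emb, spec)
        expected = np.zeros((w, w))
        for i in range(w):  # hand-enumerated offsets
            for j in range(w):
                if j - i == 1:
                    expected[i, j] = q[i] @ emb[w]
        np.testing.assert_array_equal(logits, expected)

    def test_missing_offsets_raise(self, rng):
        spec = small_spec(use_relative=True)
        with pytest.raises(ValueError, match="offsets"):
            relative_logits(rng.normal(size=(5, 2)), np.zeros((7, 2)), spec)

    def test_full_attention_with_relative_matches_oracle(self):
        rng = np.random.default_rng(3)
        spec = small_spec(use_relative=True)
        w = init_attention_weights(spec, rng, max_width=6)
        x = rng.normal(size=(6, 8))
        out = single_head_attention(
            x, w.w_q[0], w.w_k[0], w.w_v[0], spec, w.relative_embeddings
        )
        exp, _ = single_head_oracle(
            x, w.w_q[0], w.w_k[0], w.w_v[0], 2, rel=w.relative_embeddings
        )
        np.testing.assert_allclose(out, exp, atol=1e-6)


class TestAAConv:
    def test_output_channel_count_is_f_out(self, rng):
        spec = small_spec()
        w = init_attention_weights(spec, rng)
        kern = rng.normal(size=(3, 8, 12 - 4))
        out = aaconv(rng.normal(size=(10, 8)), kern, w, spec)
        assert out.shape == (10, 12)

    def test_all_attention_limit_equals_mha(self, rng):
        spec = small_spec(d_v=12, d_k=4, n_heads=2)  # v_ratio == 1
        w = init_attention_weights(spec, rng)
        x = rng.normal(size=(7, 8))
        np.testing.assert_allclose(
            aaconv(x, np.zeros((3, 8, 0)), w, spec),
            multi_head_attention(x, w, spec),
            atol=1e-12,
        )

    def test_conv_part_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(11)
        spec = AttentionSpec(16, 24, 8, 8, 4, 3, use_relative=False)
        w = init_attention_weights(spec, rng)
        x = rng.normal(size=(20, 16))
        kern = rng.normal(size=(3, 16, 16))
        out = aaconv(x, kern, w, spec)
        assert out.shape == (20, 24)
        np.testing.assert_allclose(
            out[:, :16], conv1d_same_oracle(x, kern), atol=1e-6
        )
        np.testing.assert_allclose(
            out[:, 16:], multi_head_attention(x, w, spec), atol=1e-12
        )

    def test_excess_value_depth_is_configuration_error(self):
        with pytest.raises(ValueError, match="d_v"):
            spec = small_spec(d_v=14, n_heads=2)
            aaconv(np.zeros((4, 8)), np.zeros((3, 8, 0)),
                   init_attention_weights(spec, np.random.default_rng(0)), spec)

    def test_deterministic_given_seed(self):
        spec = small_spec()
        a = init_attention_weights(spec, np.random.default_rng(5))
        b = init_attention_weights(spec, np.random.default_rng(5))
        for wa, wb in ((a.w_q, b.w_q), (a.w_k, b.w_k), (a.w_v, b.w_v)):
            np.testing.assert_array_equal(wa, wb)


class TestParameterAccounting:
    @staticmethod
    def counted_delta(spec, spatial_dims):
        """Construct plain and augmented layers; count weight entries."""
        taps = (spec.kernel_size,) * spatial_dims
        plain = np.zeros(taps + (spec.f_in, spec.f_out))
        reduced = np.zeros(taps + (spec.f_in, spec.f_out - spec.d_v))
        w_qkv = np.zeros((spec.f_in, 2 * spec.d_k + spec.d_v))
        w_o = np.zeros((spec.d_v, spec.d_v))
        return (reduced.size + w_qkv.size + w_o.size) - plain.size

    def test_delta_decomposes_into_added_and_removed_weights(self):
        # added q/k/v/o weights minus removed conv weights; the delta
        # vanishes in the no-augmentation limit d_k = d_v = 0
        spec = small_spec()
        delta = count_params_delta(spec).delta
        formula = spec.f_in * (2 * spec.d_k + spec.d_v) + spec.d_v**2 \
            - spec.kernel_size**2 * spec.f_in * spec.d_v
        assert delta == formula

    @pytest.mark.parametrize("k", [1, 3, 5])
    @pytest.mark.parametrize("kappa", [0.1, 0.25, 0.5])
    @pytest.mark.parametrize("v", [0.1, 0.25, 0.5])
    def test_formula_equals_constructed_layer_count(self, k, kappa, v):
        f_in = f_out = 40  # 40 * {0.1, 0.25, 0.5} are all integers
        spec = AttentionSpec.from_ratios(
            f_in, f_out, kappa, v, n_heads=2, kernel_size=k,
            use_relative=False,
        )
        for dims in (1, 2):
            assert count_params_delta(spec, spatial_dims=dims).delta == \
                self.counted_delta(spec, dims)

    def test_one_by_one_replacement_increases_parameters(self):
        spec = AttentionSpec.from_ratios(64, 64, 0.25, 0.25, 4, kernel_size=1)
        assert count_params_delta(spec).delta > 0

    def test_three_by_three_replacement_decreases_parameters(self):
        spec = AttentionSpec.from_ratios(64, 64, 0.25, 0.25, 4, kernel_size=3)
        delta = count_params_delta(spec).delta
        assert delta < 0
        assert delta == -5888  # 4096 * (0.5 - 8*0.25 + 0.0625)

    def test_matches_printed_closed_form(self):
        for k, kappa, v in [(1, 0.25, 0.25), (3, 0.5, 0.1), (5, 0.1, 0.5)]:
            spec = AttentionSpec.from_ratios(40, 40, kappa, v, 2, k)
            closed = spec.f_in * spec.f_out * (
                2 * kappa + (1 - k**2) * v + (spec.f_out / spec.f_in) * v**2
            )
            assert count_params_delta(spec).delta == round(closed)
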