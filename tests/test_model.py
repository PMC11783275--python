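"""Prediction-head stages: closed forms, oracle equivalence, gradients."""

import numpy as np
import pytest

from embddg import ModelConfig, ModelParams, PRESETS
from embddg.model import (
    attention_weights,
    backward_batch,
    conv1d_forward,
    forward,
    forward_batch,
    forward_state,
    im2col,
    load_checkpoint,
    multi_head_attention,
    output_head,
    pool_concat,
    position_ffn,
    save_checkpoint,
)
from conftest import random_cfg_and_instance
from oracles import (
    naive_attention,
    naive_conv,
    naive_ffn,
    naive_forward,
    naive_output,
    naive_pool,
)


class TestConfig:
    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(m=10, h=4)

    def test_presets_match_published_grid(self):
        grid = {
            "model0": (32, 2, 128), "model1": (64, 2, 256), "model2": (64, 4, 256),
            "model3": (128, 4, 512), "model4": (128, 8, 512), "model5": (256, 8, 1024),
        }
        for name, (m, h, s) in grid.items():
            cfg = PRESETS[name]
            assert (cfg.m, cfg.h, cfg.s) == (m, h, s)
            assert cfg.w == 15

    def test_production_head_dimension(self):
        assert PRESETS["model4"].r == 16


class TestConvStage:
    def test_zero_input_zero_bias_gives_zero(self, tiny_cfg, tiny_params):
        tiny_params.bc[:] = 0.0
        C = conv1d_forward(np.zeros((5, 5)), tiny_params, tiny_cfg)
        assert np.array_equal(C, np.zeros((5, tiny_cfg.m)))

    def test_zero_input_unit_bias_gives_ones(self, tiny_cfg, tiny_params):
        tiny_params.bc[:] = 1.0
        C = conv1d_forward(np.zeros((5, 5)), tiny_params, tiny_cfg)
        assert np.array_equal(C, np.ones((5, tiny_cfg.m)))

    def test_output_non_negative_and_length_preserving(self, tiny_cfg, tiny_params, rng):
        for L in (1, 2, 7):  # also shorter than the filter width
            C = conv1d_forward(rng.standard_normal((L, 5)), tiny_params, tiny_cfg)
            assert C.shape == (L, tiny_cfg.m)
            assert (C >= 0).all()

    def test_channel_mismatch_is_error(self, tiny_cfg, tiny_params, rng):
        with pytest.raises(ValueError, match="channel mismatch"):
            conv1d_forward(rng.standard_normal((4, 9)), tiny_params, tiny_cfg)

    def test_matches_naive_loops(self, rng):
        for _ in range(10):
            cfg, params, D = random_cfg_and_instance(rng)
            got = conv1d_forward(D, params, cfg)
            np.testing.assert_allclose(got, naive_conv(D, params, cfg), atol=1e-10)


class TestAttentionStage:
    def test_single_position_closed_form(self, tiny_cfg, tiny_params, rng):
        """With L=1 the softmax collapses to 1, so Z = [V_1..V_h] AO + C."""
        C = rng.standard_normal((1, tiny_cfg.m))
        V = np.concatenate(
            [C @ tiny_params.AV[i] for i in range(tiny_cfg.h)], axis=1
        )
        expected = V @ tiny_params.AO + C
        np.testing.assert_allclose(
            multi_head_attention(C, tiny_params, tiny_cfg), expected, atol=1e-12
        )

    def test_identical_rows_stay_identical(self, tiny_cfg, tiny_params, rng):
        row = rng.standard_normal(tiny_cfg.m)
        Z = multi_head_attention(np.tile(row, (5, 1)), tiny_params, tiny_cfg)
        assert np.allclose(Z, Z[0])

    def test_rows_are_stochastic(self, tiny_cfg, tiny_params, rng):
        A = attention_weights(rng.standard_normal((6, tiny_cfg.m)), tiny_params, tiny_cfg)
        assert (A >= 0).all()
        np.testing.assert_allclose(A.sum(axis=-1), 1.0, atol=1e-12)

    def test_matches_naive_loops(self, rng):
        for _ in range(10):
            cfg, params, _ = random_cfg_and_instance(rng)
            C = rng.standard_normal((4, cfg.m))
            np.testing.assert_allclose(
                multi_head_attention(C, params, cfg),
                naive_attention(C, params, cfg),
                atol=1e-8,
            )

    def test_plain_r_scaling_flag(self, rng):
        cfg_sqrt = ModelConfig(m=8, w=3, h=2, s=6, sqrt_scale=True)
        cfg_plain = ModelConfig(m=8, w=3, h=2, s=6, sqrt_scale=False)
        params = ModelParams.init(cfg_sqrt, d=5, rng=rng)
        C = rng.standard_normal((5, 8))
        a = multi_head_attention(C, params, cfg_sqrt)
        b = multi_head_attention(C, params, cfg_plain)
        assert not np.allclose(a, b)
        np.testing.assert_allclose(b, naive_attention(C, params, cfg_plain), atol=1e-8)


class TestFFNStage:
    def test_zero_second_layer_is_pure_residual(self, tiny_cfg, tiny_params, rng):
        tiny_params.W2[:] = 0.0
        tiny_params.b2[:] = 0.0
        Z = rng.standard_normal((4, tiny_cfg.m))
        np.testing.assert_allclose(position_ffn(Z, tiny_params, tiny_cfg), Z)

    def test_single_row_hand_computation(self):
        cfg = ModelConfig(m=2, w=1, h=1, s=2)
        params = ModelParams.init(cfg, d=1, rng=np.random.default_rng(0))
        params.W1[:] = [[1.0, -1.0], [0.5, 2.0]]
        params.b1[:] = [0.0, 1.0]
        params.W2[:] = [[1.0, 0.0], [2.0, -1.0]]
        params.b2[:] = [0.5, -0.5]
        z = np.array([[2.0, -1.0]])
        # hidden = ReLU([2*1 - 0.5, -2 - 2 + 1]) = [1.5, 0]
        # out = [1.5, 0] W2 + b2 + z = [1.5 + 0.5 + 2, 0 - 0.5 - 1] = [4, -1.5]
        np.testing.assert_allclose(position_ffn(z, params, cfg), [[4.0, -1.5]])

    def test_row_permutation_equivariance(self, tiny_cfg, tiny_params, rng):
        Z = rng.standard_normal((6, tiny_cfg.m))
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            position_ffn(Z, tiny_params, tiny_cfg)[perm],
            position_ffn(Z[perm], tiny_params, tiny_cfg),
        )

    def test_matches_naive_loops(self, rng):
        for _ in range(10):
            cfg, params, _ = random_cfg_and_instance(rng)
            Z = rng.standard_normal((5, cfg.m))
            np.testing.assert_allclose(
                position_ffn(Z, params, cfg), naive_ffn(Z, params), atol=1e-10
            )


class TestPoolingAndOutput:
    def test_constant_rows_pool_to_row(self, rng):
        f = rng.standard_normal(4)
        P = pool_concat(np.tile(f, (7, 1)))
        np.testing.assert_allclose(P, np.concatenate([f, f]))

    def test_hand_example(self):
        P = pool_concat(np.array([[1.0, -2.0], [3.0, 0.0]]))
        np.testing.assert_allclose(P, [2.0, -1.0, 3.0, 0.0])

    def test_row_permutation_invariance(self, rng):
        F = rng.standard_normal((9, 5))
        np.testing.assert_allclose(pool_concat(F), pool_concat(F[rng.permutation(9)]))

    def test_all_masked_is_error(self, rng):
        with pytest.raises(ValueError, match="masked"):
            pool_concat(rng.standard_normal((3, 2)), mask=np.zeros(3, bool))

    def test_output_head_closed_forms(self, tiny_params, rng):
        m2 = tiny_params.wO.shape[0]
        tiny_params.bO[...] = 2.5
        assert output_head(np.zeros(m2), tiny_params) == 2.5
        tiny_params.wO[:] = 0.0
        assert output_head(rng.standard_normal(m2), tiny_params) == 2.5

    def test_output_matches_scalar_loop(self, tiny_params, rng):
        P = rng.standard_normal(tiny_params.wO.shape[0])
        np.testing.assert_allclose(
            output_head(P, tiny_params), naive_output(P, tiny_params)
        )
        np.testing.assert_allclose(
            pool_concat(F := rng.standard_normal((4, 3))), naive_pool(F)
        )


class TestFullForward:
    def test_deterministic(self, tiny_cfg, tiny_params, rng):
        D = rng.standard_normal((7, 5))
        assert forward(D, tiny_params, tiny_cfg) == forward(D, tiny_params, tiny_cfg)

    def test_matches_naive_composition(self, rng):
        for _ in range(5):
            cfg, params, D = random_cfg_and_instance(rng)
            np.testing.assert_allclose(
                forward(D, params, cfg), naive_forward(D, params, cfg), atol=1e-8
            )

    def test_post_conv_permutation_invariance(self, tiny_cfg, tiny_params, rng):
        """No positional encoding + pooling: permuting C's rows keeps y."""
        C = np.abs(rng.standard_normal((8, tiny_cfg.m)))
        def head(Cmat):
            F = position_ffn(
                multi_head_attention(Cmat, tiny_params, tiny_cfg),
                tiny_params, tiny_cfg,
            )
            return output_head(pool_concat(F), tiny_params)
        y = head(C)
        for _ in range(5):
            assert abs(head(C[rng.permutation(8)]) - y) < 1e-9

    def test_batched_equals_unbatched(self, tiny_cfg, tiny_params, rng):
        lengths = [3, 6, 1, 5]
        Ds = [rng.standard_normal((L, 5)) for L in lengths]
        Lmax = max(lengths)
        X = np.zeros((len(Ds), Lmax, 5))
        mask = np.zeros((len(Ds), Lmax), bool)
        for i, D in enumerate(Ds):
            X[i, : len(D)] = D
            mask[i, : len(D)] = True
        batched = forward_batch(X, mask, tiny_params, tiny_cfg)
        singles = [forward(D, tiny_params, tiny_cfg) for D in Ds]
        np.testing.assert_allclose(batched, singles, atol=1e-12)

    def test_finite_output_under_extreme_inputs(self, tiny_cfg, tiny_params):
        D = np.full((4, 5), 1e4)  # would overflow a naive softmax
        assert np.isfinite(forward(D, tiny_params, tiny_cfg))

    def test_forward_state_shapes(self, tiny_cfg, tiny_params, rng):
        state = forward_state(rng.standard_normal((6, 5)), tiny_params, tiny_cfg)
        m = tiny_cfg.m
        assert state.C.shape == (6, m) and state.Z.shape == (6, m)
        assert state.F.shape == (6, m) and state.P.shape == (2 * m,)
        assert state.attn.shape == (tiny_cfg.h, 6, 6)
        assert np.isfinite(state.y_hat)


class TestGradients:
    def test_backward_matches_finite_differences(self, tiny_cfg, rng):
        params = ModelParams.init(tiny_cfg, d=4, rng=rng)
        B, L = 3, 5
        X = rng.standard_normal((B, L, 4))
        mask = np.ones((B, L), bool)
        mask[0, 3:] = False
        X[0, 3:] = 0
        y = rng.standard_normal(B)

        def loss():
            y_hat = forward_batch(X, mask, params, tiny_cfg)
            return float(np.mean((y_hat - y) ** 2))

        y_hat, cache = forward_batch(X, mask, params, tiny_cfg, return_cache=True)
        grads = backward_batch(2 * (y_hat - y) / B, cache, params)
        eps = 1e-6
        for name, g in grads.items():
            arr = getattr(params, name)
            flat_indices = (
                [()] if arr.shape == () else
                [np.unravel_index(i, arr.shape)
                 for i in rng.choice(arr.size, size=min(4, arr.size), replace=False)]
            )
            for idx in flat_indices:
                orig = arr[idx]
                arr[idx] = orig + eps
                up = loss()
                arr[idx] = orig - eps
                down = loss()
                arr[idx] = orig
                fd = (up - down) / (2 * eps)
                an = float(g[idx]) if g.shape else float(g)
                assert abs(fd - an) < 1e-5 * max(1.0, abs(fd)), (name, idx)


class TestCheckpoint:
    def test_roundtrip_preserves_weights_and_config(self, tmp_path, tiny_cfg, rng):
        params = ModelParams.init(tiny_cfg, d=5, rng=rng)
        path = tmp_path / "model.npz"
        save_checkpoint(path, params, tiny_cfg, meta={"model": "tiny"})
        loaded, cfg, meta = load_checkpoint(path)
        assert cfg == tiny_cfg
        assert meta["model"] == "tiny"
        D = rng.standard_normal((6, 5))
        assert forward(D, params, tiny_cfg) == forward(D, loaded, cfg)

    def test_precomputed_windows_match_internal(self, tiny_cfg, tiny_params, rng):
        X = rng.standard_normal((4, 7, 5))
        win = im2col(X, tiny_cfg.w)
        np.testing.assert_array_equal(
            forward_batch(X, None, tiny_params, tiny_cfg),
            forward_batch(X, None, tiny_params, tiny_cfg, win=win),
        )
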