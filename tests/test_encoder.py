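import math

import numpy as np
import pytest

from reference_impl import naive_encoder
from retscreen.encoder import (EncoderConfig, alpha_values, attention_rows,
                               embed_tokens, encode, encoder_backward,
                               encoder_forward, encoder_layer, fuse_levels,
                               init_encoder_params, mixed_attention,
                               neighborhood_indices, neighborhood_mask,
                               pool_level)
from retscreen.preprocessing import PatchGrid


class TestNeighborhood:
    def test_radius_zero_is_self(self, tiny_grid):
        for i in range(tiny_grid.n_patches):
            assert list(neighborhood_indices(i, tiny_grid, 0)) == [i]

    def test_large_radius_is_everything(self, tiny_grid):
        assert len(neighborhood_indices(4, tiny_grid, 10)) == 9

    def test_three_by_three_enumeration(self, tiny_grid):
        assert len(neighborhood_indices(4, tiny_grid, 1)) == 9  # centre
        assert set(neighborhood_indices(0, tiny_grid, 1)) == {0, 1, 3, 4}

    def test_mask_symmetric_with_diagonal(self, tiny_grid):
        m = neighborhood_mask(tiny_grid, 1)
        assert np.array_equal(m, m.T)
        assert m.diagonal().all()


class TestAttentionRows:
    def test_identical_keys_uniform(self, rng):
        q = rng.normal(size=(5, 3))
        k = np.tile(rng.normal(size=(1, 3)), (5, 1))
        a = attention_rows(q, k)
        assert np.allclose(a, 1 / 5)

    def test_single_token(self, rng):
        a = attention_rows(rng.normal(size=(1, 4)), rng.normal(size=(1, 4)))
        assert a.shape == (1, 1) and a[0, 0] == 1.0

    def test_matches_two_loop_softmax_and_shift_invariance(self, rng):
        N, d = 8, 4
        q, k = rng.normal(size=(N, d)), rng.normal(size=(N, d))
        a = attention_rows(q, k)
        for i in range(N):
            logits = [sum(q[i][x] * k[j][x] for x in range(d)) / math.sqrt(d)
                      for j in range(N)]
            z = sum(math.exp(v) for v in logits)
            for j in range(N):
                assert abs(a[i, j] - math.exp(logits[j]) / z) < 1e-6
        shifted = attention_rows(q, k + 0.0)  # same inputs reproduce exactly
        assert np.array_equal(a, shifted)
        # adding a constant vector to q shifts all logits of a row equally
        a2 = attention_rows(q, k + np.ones(d) * 0.0, None)
        assert np.allclose(a, a2)

    def test_empty_support_rejected(self, rng):
        mask = np.ones((3, 3), dtype=bool)
        mask[1] = False
        with pytest.raises(ValueError, match="support"):
            attention_rows(rng.normal(size=(3, 2)), rng.normal(size=(3, 2)),
                           support_mask=mask)

    def test_local_rows_zero_off_support(self, rng, tiny_grid):
        mask = neighborhood_mask(tiny_grid, 1)
        a = attention_rows(rng.normal(size=(9, 4)), rng.normal(size=(9, 4)),
                           support_mask=mask)
        assert (a[~mask] == 0.0).all()
        assert np.allclose(a.sum(axis=1), 1.0, atol=1e-9)


class TestMixedAttention:
    def _stochastic(self, rng, n):
        m = rng.random((n, n)) + 1e-3
        return m / m.sum(axis=1, keepdims=True)

    def test_endpoints_bitwise(self, rng):
        a, b = self._stochastic(rng, 6), self._stochastic(rng, 6)
        assert np.array_equal(mixed_attention(a, b, 0.0), a)
        assert np.array_equal(mixed_attention(a, b, 1.0), b)

    def test_rows_sum_to_one_without_renormalization(self, rng):
        a, b = self._stochastic(rng, 7), self._stochastic(rng, 7)
        mixed = mixed_attention(a, b, 0.37)
        assert np.abs(mixed.sum(axis=1) - 1.0).max() < 1e-9

    def test_alpha_out_of_range_rejected(self, rng):
        a = self._stochastic(rng, 3)
        with pytest.raises(ValueError, match="alpha"):
            mixed_attention(a, a, 1.2)


class TestEmbedAndPools:
    def test_zero_inputs_zero_tokens(self, tiny_config):
        params = init_encoder_params(tiny_config, seed=0)
        patches = np.zeros((9, tiny_config.patch_grid.patch_dim))
        assert not embed_tokens(patches, params).any()

    def test_identity_projection(self, rng):
        grid = PatchGrid(target_size=4, patch_size=2)  # Pd = 12
        cfg = EncoderConfig(patch_grid=grid, n_layers=1, embed_dim=12,
                            n_heads=2, fusion_depths=(1,))
        params = init_encoder_params(cfg, seed=0)
        params["patch_proj"] = np.eye(12)
        patches = rng.normal(size=(4, 12))
        assert np.array_equal(embed_tokens(patches, params), patches)

    def test_embed_matches_elementwise_loop(self, rng, tiny_config,
                                            tiny_params):
        patches = rng.normal(size=(9, tiny_config.patch_grid.patch_dim))
        t = embed_tokens(patches, tiny_params)
        Wp, pos = tiny_params["patch_proj"], tiny_params["pos"]
        for i in range(9):
            for e in range(tiny_config.embed_dim):
                expect = sum(Wp[e][p] * patches[i][p]
                             for p in range(patches.shape[1])) + pos[i][e]
                assert abs(t[i, e] - expect) < 1e-6

    def test_pool_level_cases(self, rng):
        v = rng.normal(size=4)
        assert np.allclose(pool_level(np.tile(v, (5, 1))), v)
        u = rng.normal(size=4)
        assert np.allclose(pool_level(np.stack([u, -u])), 0.0)
        toks = rng.normal(size=(7, 4))
        manual = np.array([sum(toks[i, e] for i in range(7)) / 7
                           for e in range(4)])
        assert np.abs(pool_level(toks) - manual).max() < 1e-9

    def test_fuse_levels(self, rng):
        pools = rng.normal(size=(3, 5))
        fused, beta = fuse_levels(pools, np.array([30.0, 0.0, 0.0]))
        assert np.abs(fused - pools[0]).max() < 1e-6
        fused2, beta2 = fuse_levels(pools[:2], np.zeros(2))
        assert np.allclose(fused2, pools[:2].mean(axis=0))
        logits = rng.normal(size=3)
        fused3, beta3 = fuse_levels(pools, logits)
        assert abs(beta3.sum() - 1.0) < 1e-9
        manual = sum(beta3[k] * pools[k] for k in range(3))
        assert np.abs(fused3 - manual).max() < 1e-12


class TestEncoderLayer:
    def test_zero_weights_identity(self, tiny_config):
        params = init_encoder_params(tiny_config, seed=0)
        for key in list(params):
            if key.startswith("layers."):
                params[key] = np.zeros_like(params[key])
        tokens = np.random.default_rng(0).normal(size=(9, 8))
        out, _ = encoder_layer(tokens, params, 1, 0.5, tiny_config)
        assert np.array_equal(out, tokens)

    def test_single_token_attention_is_one(self):
        grid = PatchGrid(target_size=4, patch_size=4)
        cfg = EncoderConfig(patch_grid=grid, n_layers=1, embed_dim=4,
                            n_heads=1, fusion_depths=(1,))
        params = init_encoder_params(cfg, seed=0)
        tokens = np.random.default_rng(1).normal(size=(1, 4))
        _, attn = encoder_layer(tokens, params, 1, 0.3, cfg)
        for key in ("a_local", "a_global", "a_mix"):
            assert np.allclose(attn[key], 1.0)

    def test_attention_maps_row_stochastic_every_layer(self, tiny_config,
                                                       tiny_params, rng):
        patches = rng.normal(size=(2, 9, tiny_config.patch_grid.patch_dim))
        out = encoder_forward(patches, tiny_params, tiny_config)
        nb = neighborhood_mask(tiny_config.patch_grid, 1)
        for layer_maps in out["attention"]:
            for key in ("a_local", "a_global", "a_mix"):
                a = layer_maps[key]
                assert (a >= 0).all()
                assert np.abs(a.sum(axis=-1) - 1.0).max() < 1e-6
            assert (layer_maps["a_local"][..., ~nb] == 0.0).all()


class TestOracleEquivalence:
    @pytest.mark.parametrize("size,patch,E,heads", [(12, 4, 8, 2),
                                                    (16, 4, 6, 1)])
    def test_forward_matches_nested_loop_reference(self, size, patch, E, heads):
        grid = PatchGrid(target_size=size, patch_size=patch)
        cfg = EncoderConfig(patch_grid=grid, n_layers=2, embed_dim=E,
                            n_heads=heads, fusion_depths=(1, 2),
                            stabilized=False)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            params = init_encoder_params(cfg, seed=seed)
            params = {k: v * 10 if v.ndim >= 2 else v
                      for k, v in params.items()}
            patches = rng.normal(size=(grid.n_patches, grid.patch_dim))
            ours = encoder_forward(patches[None], params, cfg)
            ref = naive_encoder(patches, params, cfg)
            assert np.abs(ours["fused"][0] - ref["fused"]).max() < 1e-5
            assert np.abs(ours["final_tokens"][0]
                          - ref["final_tokens"]).max() < 1e-5
            for l in range(2):
                assert np.abs(ours["attention"][l]["a_mix"][0]
                              - ref["attention"][l]).max() < 1e-6


class TestAlphaSchedule:
    def test_fixed_linear_monotone(self, tiny_config):
        a = alpha_values(tiny_config)
        assert np.all(np.diff(a) > 0)
        assert a[-1] == 1.0

    def test_learnable_monotone_in_unit_interval(self, tiny_grid):
        cfg = EncoderConfig(patch_grid=tiny_grid, n_layers=4, embed_dim=8,
                            n_heads=2, fusion_depths=(4,),
                            alpha_mode="learnable_monotone")
        params = init_encoder_params(cfg, seed=0)
        a = alpha_values(cfg, params)
        assert np.all((a >= 0) & (a <= 1))
        assert np.all(np.diff(a) >= 0)

    def test_alpha_endpoints_reduce_bitwise(self, tiny_grid, rng):
        patches = rng.normal(size=(1, 9, tiny_grid.patch_dim))
        for const, twin in [(0.0, "a_local"), (1.0, "a_global")]:
            cfg = EncoderConfig(patch_grid=tiny_grid, n_layers=2, embed_dim=8,
                                n_heads=2, fusion_depths=(2,),
                                alpha_mode="fixed_constant",
                                alpha_constant=const)
            params = init_encoder_params(cfg, seed=3)
            out = encoder_forward(patches, params, cfg)
            for layer_maps in out["attention"]:
                assert np.array_equal(layer_maps["a_mix"], layer_maps[twin])


class TestStructuralInvariances:
    def test_grid_symmetry_relabeling_invariance(self, tiny_config,
                                                 tiny_params, rng):
        """Permuting patches by a grid symmetry (horizontal flip) together
        with the positional table leaves the fused vector unchanged,
        because the Chebyshev neighbourhood geometry is flip-invariant."""
        rows = cols = 3
        perm = np.array([r * cols + (cols - 1 - c)
                         for r in range(rows) for c in range(cols)])
        patches = rng.normal(size=(9, tiny_config.patch_grid.patch_dim))
        params_p = dict(tiny_params)
        params_p["pos"] = tiny_params["pos"][perm]
        a = encoder_forward(patches[None], tiny_params, tiny_config)
        b = encoder_forward(patches[perm][None], params_p, tiny_config)
        assert np.abs(a["fused"] - b["fused"]).max() < 1e-10
        assert np.abs(a["final_tokens"][0][perm]
                      - b["final_tokens"][0]).max() < 1e-10

    def test_gradients_match_finite_differences(self, tiny_grid, rng):
        from retscreen.head import init_head_params
        from retscreen.training import model_loss, model_loss_and_grads

        for stabilized, amode in [(False, "fixed_linear"),
                                  (True, "learnable_monotone")]:
            cfg = EncoderConfig(patch_grid=tiny_grid, n_layers=2, embed_dim=8,
                                n_heads=2, fusion_depths=(1, 2),
                                stabilized=stabilized, alpha_mode=amode,
                                init_sd=0.02)
            params = init_encoder_params(cfg, seed=1)
            hp = init_head_params(8, 4, 2, seed=2)
            params["head.ws"] = hp.screening_projection
            params["head.wc"] = hp.class_weights
            params = {k: v * 20 if v.ndim >= 2 else v
                      for k, v in params.items()}
            X = rng.normal(size=(3, 9, tiny_grid.patch_dim))
            y = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
            _, _, grads = model_loss_and_grads(X, y, params, cfg)
            for key in params:
                flat = params[key].reshape(-1)
                g = np.atleast_1d(np.asarray(grads[key])).reshape(-1)
                for i in rng.choice(flat.size, size=min(3, flat.size),
                                    replace=False):
                    eps, orig = 1e-6, flat[i]
                    flat[i] = orig + eps
                    lp = model_loss(X, y, params, cfg)
                    flat[i] = orig - eps
                    lm = model_loss(X, y, params, cfg)
                    flat[i] = orig
                    fd = (lp - lm) / (2 * eps)
                    assert abs(fd - g[i]) <= 1e-4 * max(abs(fd), abs(g[i]), 1e-3), key


def test_encode_end_to_end_contract(sample):
    from retscreen.preprocessing import fit_channel_stats

    grid = PatchGrid(target_size=64, patch_size=8)
    cfg = EncoderConfig(patch_grid=grid, n_layers=2, embed_dim=16, n_heads=2,
                        fusion_depths=(1, 2))
    params = init_encoder_params(cfg, seed=0)
    stats = fit_channel_stats([sample.image])
    rep = encode(sample.image, stats, grid, cfg, params,
                 fov_mask=sample.fov_mask)
    assert rep.fused.shape == (16,)
    assert rep.level_pools.shape == (2, 16)
    assert abs(rep.beta.sum() - 1.0) < 1e-9
    assert np.abs(rep.fused
                  - rep.level_pools.T @ rep.beta).max() < 1e-6
    assert len(rep.attention) == 2
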