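import dataclasses
import itertools

import numpy as np
import pytest

from retscreen.evaluation import (MetricsReport, PerturbationSpec,
                                  attention_alignment, binary_auroc,
                                  compute_metrics, perturb, retention)
from retscreen.preprocessing import PatchGrid


def pairwise_auroc(scores, labels):
    """Independent oracle: exhaustive pair counting with half credit."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array([[1], [0], [1], [0]])
        probs = np.array([[0.9], [0.1], [0.8], [0.2]])
        rep = compute_metrics(y, probs, y)
        for field in ("accuracy", "macro_f1", "sensitivity", "specificity",
                      "auroc"):
            assert getattr(rep, field) == 1.0

    def test_complete_separation_auroc(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert binary_auroc(scores, labels) == 1.0

    def test_three_of_four_concordant_pairs(self):
        scores = np.array([0.6, 0.4, 0.5, 0.3])
        labels = np.array([1, 1, 0, 0])
        assert binary_auroc(scores, labels) == pytest.approx(0.75)

    def test_matches_pair_counting_oracle_small_n(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 13))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 1)  # provoke ties
            assert binary_auroc(scores, labels) == pytest.approx(
                pairwise_auroc(scores, labels), abs=1e-12)

    def test_macro_f1_invariant_to_class_relabeling(self, rng):
        n, C = 40, 3
        y = rng.integers(0, 2, size=(n, C))
        dec = rng.integers(0, 2, size=(n, C))
        probs = rng.random((n, C))
        perm = np.array([2, 0, 1])
        a = compute_metrics(dec, probs, y)
        b = compute_metrics(dec[:, perm], probs[:, perm], y[:, perm])
        assert a.macro_f1 == pytest.approx(b.macro_f1, abs=1e-12)

    def test_macro_is_unweighted_class_mean(self, rng):
        n, C = 30, 4
        y = rng.integers(0, 2, size=(n, C))
        dec = rng.integers(0, 2, size=(n, C))
        probs = rng.random((n, C))
        rep = compute_metrics(dec, probs, y)
        assert rep.macro_f1 == pytest.approx(
            rep.per_class["f1"].mean(), abs=1e-12)

    def test_single_class_auroc_excluded_with_warning(self):
        y = np.array([[1, 1], [1, 0], [1, 1]])
        dec = y.copy()
        probs = np.array([[0.9, 0.8], [0.8, 0.3], [0.7, 0.9]])
        with pytest.warns(UserWarning, match="AUROC undefined"):
            rep = compute_metrics(dec, probs, y)
        assert np.isnan(rep.per_class["auroc"].iloc[0])
        assert rep.auroc == pytest.approx(1.0)  # from the defined class only


class TestPerturb:
    KINDS = ("brightness_down", "brightness_up", "contrast_down",
             "gaussian_blur", "gaussian_noise")

    @pytest.mark.parametrize("kind", KINDS)
    def test_level_zero_is_identity(self, kind, sample):
        spec = PerturbationSpec(kind, (0.0, 0.5))
        out = perturb(sample.image, spec, 0, fov_mask=sample.fov_mask)
        assert np.array_equal(out, sample.image)

    def test_brightness_algebra_pre_clipping(self):
        img = np.full((8, 8, 3), 0.4)
        down = perturb(img, PerturbationSpec("brightness_down", (0.5,)), 0)
        up = perturb(down, PerturbationSpec("brightness_up", (1.0,)), 0)
        assert np.allclose(up, img)

    def test_noise_reproducible_from_seed(self, sample):
        spec = PerturbationSpec("gaussian_noise", (0.1,), seed=17)
        a = perturb(sample.image, spec, 0, fov_mask=sample.fov_mask)
        b = perturb(sample.image, spec, 0, fov_mask=sample.fov_mask)
        assert np.array_equal(a, b)

    def test_fov_background_untouched_by_intensity_kinds(self, sample):
        for kind in ("brightness_down", "brightness_up", "contrast_down",
                     "gaussian_noise"):
            spec = PerturbationSpec(kind, (0.4,))
            out = perturb(sample.image, spec, 0, fov_mask=sample.fov_mask)
            assert np.array_equal(out[~sample.fov_mask],
                                  sample.image[~sample.fov_mask])

    def test_levels_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            PerturbationSpec("gaussian_noise", (0.3, 0.1))


class TestAttentionAlignment:
    def _setup(self):
        grid = PatchGrid(target_size=16, patch_size=4)  # 4x4 patches
        fov = np.zeros((16, 16), dtype=bool)
        fov[2:14, 2:14] = True
        lesion = np.zeros((16, 16), dtype=bool)
        lesion[5, 5] = True  # exactly one patch (row 1, col 1)
        return grid, fov, lesion

    def test_uniform_attention_equals_patch_fraction(self):
        grid, fov, lesion = self._setup()
        N = grid.n_patches
        attn = [{"a_mix": np.full((2, N, N), 1.0 / N)}]
        out = attention_alignment(attn, lesion, fov, grid)
        assert out["relevant_region_coverage"] == pytest.approx(1.0 / N)
        assert out["lesion_patch_fraction"] == pytest.approx(1.0 / N)

    def test_all_mass_on_lesion_patch(self):
        grid, fov, lesion = self._setup()
        N = grid.n_patches
        a = np.zeros((1, N, N))
        a[:, :, 5] = 1.0  # token 5 = patch (1,1) receives everything
        out = attention_alignment([{"a_mix": a}], lesion, fov, grid)
        assert out["relevant_region_coverage"] == pytest.approx(1.0)

    def test_fractions_partition_unity(self, rng):
        grid, fov, lesion = self._setup()
        N = grid.n_patches
        for _ in range(50):
            raw = rng.random((3, N, N)) + 1e-6
            attn = [{"a_mix": raw / raw.sum(axis=-1, keepdims=True)}]
            out = attention_alignment(attn, lesion, fov, grid)
            total = (out["relevant_region_coverage"]
                     + out["misaligned_focus"] + out["diffuse_attention"])
            assert abs(total - 1.0) < 1e-9

    def test_no_lesion_sample_rejected(self):
        grid, fov, _ = self._setup()
        attn = [{"a_mix": np.full((1, 16, 16), 1 / 16)}]
        with pytest.raises(ValueError, match="no lesions"):
            attention_alignment(attn, np.zeros((16, 16), dtype=bool), fov,
                                grid)


class TestRetention:
    def test_equal_metrics_give_hundred(self):
        assert retention(0.8, 0.8) == 100.0

    def test_eighty_percent(self):
        assert retention(1.0, 0.8) == pytest.approx(80.0)

    def test_above_hundred_passes_through(self):
        assert retention(0.5, 0.6) == pytest.approx(120.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            retention(0.0, 0.5)


def test_constant_predictor_is_fully_stable():
    """A model whose head weights are zero always outputs probability 0.5;
    its decisions cannot change under any degradation, so the stability
    index is 1 and every performance drop is 0."""
    from retscreen.encoder import EncoderConfig
    from retscreen.evaluation import robustness_suite
    from retscreen.pipeline import build_model
    from retscreen.synthetic import SyntheticConfig, generate_dataset

    synth = SyntheticConfig(image_size=32, vessel_count=2)
    ds = generate_dataset(synth, 16, (0.6, 0.2, 0.2), seed=3)
    enc = EncoderConfig(patch_grid=PatchGrid(32, 8), n_layers=1, embed_dim=8,
                        n_heads=1, fusion_depths=(1,))
    model = build_model(enc, ds.train, ds.class_names, head_dim=4, seed=0)
    model.params["head.wc"] = np.zeros_like(model.params["head.wc"])
    model.thresholds = np.full(2, 0.4)
    specs = [PerturbationSpec("gaussian_noise", (0.05, 0.3), seed=1)]
    out = robustness_suite(model, ds.test, specs)
    assert out["stability_index"] == 1.0
    assert out["perturbations"]["gaussian_noise"]["drop_pp"]["accuracy"] == 0.0
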