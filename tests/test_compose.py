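"""Composite assembly, label weighting and the two mixing strategies."""

import numpy as np
import pytest

from camricap import (
    AnalyticLesionAdapter,
    AugmentConfig,
    ConfigError,
    ConstantCamAdapter,
    ImageSample,
    ShapeError,
    ValidationError,
    classic_ricap,
    compose_image,
    compute_cam,
    enhanced_ricap,
    label_weights,
    mix_labels,
    select_quadruple,
    upsample_cam,
)
from camricap.cam import cam_mass

from conftest import make_sample


class TestSelectQuadruple:
    def test_single_image_batch_degenerates(self, rng):
        quad = select_quadruple(1, rng)
        for vec in quad.indices:
            np.testing.assert_array_equal(vec, [0])

    def test_vectors_are_permutations_and_reproducible(self):
        a = select_quadruple(8, np.random.default_rng(5))
        b = select_quadruple(8, np.random.default_rng(5))
        for va, vb in zip(a.indices, b.indices):
            np.testing.assert_array_equal(va, vb)
            assert sorted(va) == list(range(8))

    def test_partner_pairing_is_uniform(self):
        rng = np.random.default_rng(11)
        counts = np.zeros(8)
        n_draws = 1000
        for _ in range(n_draws):
            quad = select_quadruple(8, rng)
            counts[quad.indices[1][0]] += 1  # partner of position 0 in shuffle 1
        freq = counts / n_draws
        np.testing.assert_allclose(freq, 1 / 8, atol=0.03)


class TestComposeImage:
    def test_solid_colors_land_in_stated_quadrants(self):
        colors = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (0, 0, 0)]
        patches = [np.full((20, 30, 3), c, dtype=float) for c in colors]
        out = compose_image(patches, "quadrant_resize", (64, 64))
        centers = [(16, 16), (16, 48), (48, 16), (48, 48)]  # TL, TR, BL, BR
        for color, (r, c) in zip(colors, centers):
            np.testing.assert_allclose(out[r, c], color)

    def test_half_size_patches_concatenate_exactly(self, rng):
        patches = [rng.random((32, 32, 3)) for _ in range(4)]
        out = compose_image(patches, "quadrant_resize", (64, 64))
        np.testing.assert_array_equal(out[:32, :32], patches[0])
        np.testing.assert_array_equal(out[:32, 32:], patches[1])
        np.testing.assert_array_equal(out[32:, :32], patches[2])
        np.testing.assert_array_equal(out[32:, 32:], patches[3])

    def test_identical_solid_patches_give_solid_composite(self):
        patches = [np.full((10, 10, 3), 0.3) for _ in range(4)]
        out = compose_image(patches, "quadrant_resize", (64, 64))
        np.testing.assert_allclose(out, 0.3)

    def test_anchored_overwrite_fills_from_canvas(self, rng):
        canvas = np.zeros((64, 64, 3))
        patches = [np.full((16, 16, 3), 1.0) for _ in range(4)]
        out = compose_image(patches, "anchored_overwrite", (64, 64), canvas=canvas)
        assert out[0, 0, 0] == 1.0 and out[0, 63, 0] == 1.0
        assert out[63, 0, 0] == 1.0 and out[63, 63, 0] == 1.0
        assert out[32, 32, 0] == 0.0  # centre untouched by 16px corner patches

    def test_odd_dims_rejected(self, rng):
        patches = [rng.random((4, 4, 3)) for _ in range(4)]
        with pytest.raises(ConfigError):
            compose_image(patches, "quadrant_resize", (63, 64))

    def test_wrong_patch_count_rejected(self, rng):
        with pytest.raises(ShapeError):
            compose_image([rng.random((4, 4, 3))] * 3, "quadrant_resize", (64, 64))


class TestLabelWeights:
    def test_uniform_masses_give_uniform_weights(self):
        lam = label_weights([0.25] * 4, [1.0] * 4, [12544] * 4, 50176)
        np.testing.assert_allclose(lam, 0.25)

    def test_normalisation_arithmetic(self):
        lam = label_weights([0.8, 0.4, 0.4, 0.4], [1, 1, 1, 1], [1] * 4, 4)
        np.testing.assert_allclose(lam, [0.4, 0.2, 0.2, 0.2])

    def test_zero_total_mass_falls_back_to_area(self):
        lam = label_weights([0.5, 0.0, 0.5, 0.5], [1, 0, 1, 1], [10, 30, 10, 10], 100)
        raw = np.array([0.5, 0.3, 0.5, 0.5])
        np.testing.assert_allclose(lam, raw / raw.sum())

    def test_all_zero_raw_gives_equal_split(self):
        lam = label_weights([0, 0, 0, 0], [1, 1, 1, 1], [0, 0, 0, 0], 100)
        np.testing.assert_allclose(lam, 0.25)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValidationError):
            label_weights([-0.1, 0, 0, 0], [1, 1, 1, 1], [1] * 4, 4)


class TestMixLabels:
    def test_distinct_classes(self):
        label = mix_labels([0.4, 0.3, 0.2, 0.1], [0, 1, 2, 3], 4)
        np.testing.assert_allclose(label, [0.4, 0.3, 0.2, 0.1])

    def test_duplicate_classes_accumulate(self):
        label = mix_labels([0.3, 0.3, 0.2, 0.2], [1, 1, 2, 3], 4)
        np.testing.assert_allclose(label, [0, 0.6, 0.2, 0.2])

    def test_degenerate_single_source(self):
        label = mix_labels([1, 0, 0, 0], [5, 0, 0, 0], 10)
        expected = np.zeros(10)
        expected[5] = 1
        np.testing.assert_allclose(label, expected)

    def test_invalid_class_rejected(self):
        with pytest.raises(ValidationError):
            mix_labels([0.25] * 4, [0, 1, 2, 9], 4)

    def test_unnormalised_lambdas_rejected(self):
        with pytest.raises(ValidationError):
            mix_labels([0.5, 0.5, 0.5, 0.5], [0, 1, 2, 3], 4)


class TestEnhancedRicap:
    def test_identical_sources_give_onehot(self, small_spec):
        batch = [make_sample(label=2, center=(30, 30)) for _ in range(4)]
        provider = AnalyticLesionAdapter(image_dims=(64, 64), sigma=6, num_classes=3)
        mixed = enhanced_ricap(batch, provider, AugmentConfig(), np.random.default_rng(0), 3)
        for m in mixed:
            np.testing.assert_allclose(m.soft_label, [0, 0, 1], atol=1e-12)

    def test_same_seed_reproduces_exactly(self, small_batch, small_spec):
        provider = AnalyticLesionAdapter(image_dims=(64, 64), sigma=6, num_classes=3)
        runs = []
        for _ in range(2):
            mixed = enhanced_ricap(
                small_batch, provider, AugmentConfig(), np.random.default_rng(77), 3
            )
            runs.append(mixed)
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a.image, b.image)
            np.testing.assert_array_equal(a.soft_label, b.soft_label)

    def test_soft_labels_are_distributions(self, small_batch):
        provider = AnalyticLesionAdapter(image_dims=(64, 64), sigma=6, num_classes=3)
        for seed in range(5):
            mixed = enhanced_ricap(
                small_batch, provider, AugmentConfig(0.1, 0.9), np.random.default_rng(seed), 3
            )
            for m in mixed:
                assert m.soft_label.min() >= -1e-12
                assert m.soft_label.sum() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_cam_reduces_to_area_weighting(self, small_batch):
        """With a constant CAM the method reproduces RICAP's area weights."""
        provider = ConstantCamAdapter(num_classes=3)
        mixed = enhanced_ricap(
            small_batch, provider, AugmentConfig(0.2, 0.9), np.random.default_rng(3), 3
        )
        for m in mixed:
            areas = np.array([region.area for _, region, _ in m.provenance], dtype=float)
            lambdas = np.array([lam for _, _, lam in m.provenance])
            np.testing.assert_allclose(lambdas, areas / areas.sum(), atol=1e-9)

    def test_lambda_matches_pixel_loop_oracle(self, small_batch):
        """Label weights agree with an explicit rectified-sum double loop."""
        provider = AnalyticLesionAdapter(image_dims=(64, 64), sigma=6, num_classes=3)
        mixed = enhanced_ricap(
            small_batch, provider, AugmentConfig(), np.random.default_rng(21), 3
        )
        m = mixed[0]
        raw = []
        for src, region, _ in m.provenance:
            sample = small_batch[src]
            cam_img = upsample_cam(
                compute_cam(provider.features(sample), provider.class_weights(sample.label)),
                sample.image_dims,
            ).values
            patch_sum, total_sum = 0.0, 0.0
            for v in range(64):
                for u in range(64):
                    val = max(0.0, cam_img[v, u])
                    total_sum += val
                    if region.u_l <= u < region.u_r and region.v_t <= v < region.v_b:
                        patch_sum += val
            raw.append(patch_sum / total_sum)
        expected = np.array(raw) / np.sum(raw)
        lambdas = np.array([lam for _, _, lam in m.provenance])
        np.testing.assert_allclose(lambdas, expected, rtol=1e-9)

    def test_composite_pixels_stay_within_source_range(self, small_batch):
        provider = AnalyticLesionAdapter(image_dims=(64, 64), sigma=6, num_classes=3)
        mixed = enhanced_ricap(
            small_batch, provider, AugmentConfig(), np.random.default_rng(4), 3
        )
        lo = min(s.image.min() for s in small_batch)
        hi = max(s.image.max() for s in small_batch)
        for m in mixed:
            assert m.image.min() >= lo - 1e-12
            assert m.image.max() <= hi + 1e-12

    def test_planted_lesion_recovered(self, small_batch):
        """With the oracle CAM and a half-size crop, every patch covers its lesion."""
        provider = AnalyticLesionAdapter(image_dims=(64, 64), sigma=6, num_classes=3)
        mixed = enhanced_ricap(
            small_batch, provider, AugmentConfig(0.5, 0.5), np.random.default_rng(9), 3
        )
        for m in mixed:
            for src, region, _ in m.provenance:
                u, v = small_batch[src].lesion_center
                assert region.contains(u, v)


class TestClassicRicap:
    def test_labels_are_area_fractions_of_boundary(self, small_batch):
        mixed = classic_ricap(small_batch, 0.3, np.random.default_rng(6), 3)
        H = W = 64
        for m in mixed:
            lambdas = np.array([lam for _, _, lam in m.provenance])
            assert lambdas.sum() == pytest.approx(1.0, abs=1e-9)
            # zero-area rectangles carry no region and no label weight;
            # the rest weigh exactly their area fraction
            areas = []
            for _, r, lam in m.provenance:
                if r is None:
                    assert lam == 0.0
                    areas.append(0)
                else:
                    assert lam == pytest.approx(r.area / (H * W), abs=1e-12)
                    areas.append(r.area)
            assert sum(areas) == H * W

    def test_degenerate_boundary_drops_sources(self, small_batch):
        # beta far below 1 concentrates draws at the edges, exercising
        # zero-area rectangles over many seeds
        saw_zero = False
        for seed in range(40):
            mixed = classic_ricap(small_batch, 0.05, np.random.default_rng(seed), 3)
            for m in mixed:
                lambdas = [lam for _, _, lam in m.provenance]
                assert sum(lambdas) == pytest.approx(1.0, abs=1e-9)
                saw_zero = saw_zero or any(lam == 0 for lam in lambdas)
        assert saw_zero

    def test_invalid_beta_rejected(self, small_batch):
        with pytest.raises(ValidationError):
            classic_ricap(small_batch, 0.0, np.random.default_rng(0), 3)
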