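"""Chip extraction, color-transform fitting, background removal, R/G feature."""

import numpy as np
import pytest

import palmripe as pr
from palmripe.color import (
    ChipLocalizationError,
    DegenerateChartError,
    NoForegroundError,
    UndefinedFeatureError,
)


def flat_chart_image(layout, size=(240, 320), background=235.0):
    """Render only the chart chips on a plain background."""
    img = np.full((*size, 3), background)
    for chip in layout.chips:
        x0, y0 = int(chip.x), int(chip.y)
        s = int(chip.size)
        img[y0 : y0 + s, x0 : x0 + s] = layout.reference_rgb[chip.chip_id]
    return img


def translation_homography(dx, dy):
    h = np.eye(3)
    h[0, 2], h[1, 2] = dx, dy
    return h


class TestExtractChips:
    def test_identity_homography_recovers_painted_values(self, chart_layout):
        img = flat_chart_image(chart_layout)
        chips = pr.extract_chips(img, chart_layout)
        assert [c.chip_id for c in chips] == [c.chip_id for c in chart_layout.chips]
        for chip in chips:
            assert chip.mean_rgb == pytest.approx(
                chart_layout.reference_rgb[chip.chip_id], abs=1e-9
            )

    def test_translated_chart_with_matching_homography(self, chart_layout):
        dx, dy = 40, 25
        shifted = pr.ChartLayout(
            chips=tuple(
                pr.ChipRegion(c.chip_id, c.x + dx, c.y + dy, c.size)
                for c in chart_layout.chips
            ),
            reference_rgb=chart_layout.reference_rgb,
        )
        img = flat_chart_image(shifted)
        chips = pr.extract_chips(img, chart_layout, translation_homography(dx, dy))
        for chip in chips:
            assert chip.mean_rgb == pytest.approx(
                chart_layout.reference_rgb[chip.chip_id], abs=1e-9
            )

    def test_partially_occluded_chip_matches_pixel_sum_oracle(self, chart_layout):
        img = flat_chart_image(chart_layout)
        first = chart_layout.chips[0]
        # paint the left half of chip 0's sampling region a different color
        # and exclude it via the occlusion mask
        occl = np.zeros(img.shape[:2], dtype=bool)
        xm = int(first.x + first.size / 2)
        occl[:, :xm] = True
        chips = pr.extract_chips(img, chart_layout, exclude_mask=occl)
        # oracle: direct sum over the remaining (right) half of the region
        corners = first.sample_corners()
        from skimage.draw import polygon

        rr, cc = polygon(corners[:, 1], corners[:, 0], shape=img.shape[:2])
        keep = cc >= xm
        oracle = img[rr[keep], cc[keep]].sum(axis=0) / keep.sum()
        assert chips[0].mean_rgb == pytest.approx(tuple(oracle))

    def test_region_outside_image_names_chip(self, chart_layout):
        img = flat_chart_image(chart_layout, size=(60, 60))
        with pytest.raises(ChipLocalizationError, match=r"chip \d+"):
            pr.extract_chips(img, chart_layout)


def random_affine(rng):
    m = np.column_stack(
        [np.diag(rng.uniform(0.85, 1.1, 3)) + rng.uniform(-0.03, 0.03, (3, 3)),
         rng.uniform(-8, 8, 3)]
    )
    return m


def map_chips(chips, matrix):
    return [
        pr.ChipSample(
            c.chip_id, tuple(matrix[:, :3] @ np.array(c.mean_rgb) + matrix[:, 3])
        )
        for c in chips
    ]


class TestFitColorTransform:
    def test_identity_when_observed_equals_reference(self, chart_layout):
        ref = chart_layout.reference_chips()
        t = pr.fit_color_transform(ref, ref)
        np.testing.assert_allclose(t.matrix, pr.ColorTransform.identity().matrix, atol=1e-9)
        assert t.residual_rms == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_affine_map(self, chart_layout, rng):
        ref = chart_layout.reference_chips()
        forward = random_affine(rng)
        observed = map_chips(ref, forward)
        t = pr.fit_color_transform(ref, observed)
        # fitted transform must invert the forward map on every chip
        for chip, obs in zip(ref, observed):
            corrected = t.matrix[:, :3] @ np.array(obs.mean_rgb) + t.matrix[:, 3]
            assert corrected == pytest.approx(np.array(chip.mean_rgb), abs=1e-6)
        assert t.residual_rms < 1e-6

    def test_noisy_fit_matches_normal_equations_oracle(self, chart_layout, rng):
        ref = chart_layout.reference_chips()
        observed = [
            pr.ChipSample(c.chip_id, tuple(np.array(c.mean_rgb) + rng.normal(0, 3, 3)))
            for c in ref
        ]
        t = pr.fit_color_transform(ref, observed)
        obs = np.array([c.mean_rgb for c in observed])
        tgt = np.array([c.mean_rgb for c in ref])
        design = np.column_stack([obs, np.ones(len(obs))])
        oracle = np.linalg.solve(design.T @ design, design.T @ tgt).T
        np.testing.assert_allclose(t.matrix, oracle, rtol=1e-9, atol=1e-9)

    def test_rank_deficient_chart_rejected(self, chart_layout):
        ref = chart_layout.reference_chips()
        flat = [pr.ChipSample(c.chip_id, (100.0, 100.0, 100.0)) for c in ref]
        with pytest.raises(DegenerateChartError):
            pr.fit_color_transform(ref, flat)

    def test_mismatched_chip_ids_rejected(self, chart_layout):
        ref = chart_layout.reference_chips()
        with pytest.raises(ValueError):
            pr.fit_color_transform(ref, list(reversed(ref)))


class TestApplyColorTransform:
    def test_identity_keeps_image(self, rng):
        img = rng.uniform(0, 255, (8, 9, 3))
        out = pr.apply_color_transform(img, pr.ColorTransform.identity())
        np.testing.assert_allclose(out, img)

    def test_red_offset_clips_at_255(self):
        img = np.zeros((1, 2, 3))
        img[0, 0] = (240, 50, 50)
        img[0, 1] = (250, 50, 50)
        m = pr.ColorTransform.identity().matrix.copy()
        m[0, 3] = 10.0
        out = pr.apply_color_transform(img, pr.ColorTransform(m))
        assert out[0, 0, 0] == pytest.approx(250.0)
        assert out[0, 1, 0] == pytest.approx(255.0)  # clipped
        np.testing.assert_allclose(out[..., 1:], img[..., 1:])

    def test_zero_matrix_blacks_out(self, rng):
        img = rng.uniform(0, 255, (5, 5, 3))
        out = pr.apply_color_transform(img, pr.ColorTransform(np.zeros((3, 4))))
        assert np.all(out == 0.0)


class TestRemoveBackground:
    def test_bright_pixel_zeroed(self):
        img = np.array([[[100.0, 100.0, 100.0]]])
        out, mask = pr.remove_background(img)
        assert np.all(out == 0.0) and not mask[0, 0]

    def test_and_semantics_keeps_mixed_pixel(self):
        img = np.array([[[100.0, 80.0, 100.0]]])
        out, mask = pr.remove_background(img)
        np.testing.assert_allclose(out, img)
        assert mask[0, 0]

    def test_dark_image_unchanged_and_idempotent(self, rng):
        img = rng.uniform(0, 90, (12, 7, 3))
        out1, mask1 = pr.remove_background(img)
        out2, mask2 = pr.remove_background(out1)
        np.testing.assert_allclose(out1, img)
        np.testing.assert_allclose(out2, out1)
        assert mask1.all() and mask2.all()

    def test_idempotence_and_partition_on_mixed_image(self, rng):
        img = rng.uniform(0, 255, (30, 40, 3))
        out1, mask = pr.remove_background(img)
        out2, mask2 = pr.remove_background(out1)
        # re-application never changes the image: black pixels fail the rule
        np.testing.assert_allclose(out2, out1)
        assert mask2.all()
        # foreground mask and zeroed background partition the frame
        background = ~mask
        assert not np.any(mask & background)
        assert np.all(out1[background] == 0.0)
        np.testing.assert_allclose(out1[mask], img[mask])


class TestAverageRgb:
    def test_uniform_region(self):
        img = np.tile(np.array([120.0, 60.0, 30.0]), (4, 5, 1))
        assert pr.average_rgb(img, np.ones((4, 5), bool)) == pytest.approx((120, 60, 30))

    def test_two_pixel_mean(self):
        img = np.array([[[10.0, 20.0, 30.0], [30.0, 20.0, 10.0]]])
        assert pr.average_rgb(img, np.ones((1, 2), bool)) == pytest.approx((20, 20, 20))

    def test_checkerboard_matches_direct_sum_oracle(self, rng):
        img = rng.uniform(0, 255, (16, 16, 3))
        mask = np.indices((16, 16)).sum(axis=0) % 2 == 0
        oracle = tuple(img[..., ch][mask].sum() / mask.sum() for ch in range(3))
        assert pr.average_rgb(img, mask) == pytest.approx(oracle)

    def test_empty_mask_raises(self):
        with pytest.raises(NoForegroundError):
            pr.average_rgb(np.zeros((3, 3, 3)), np.zeros((3, 3), bool))


class TestColorFeature:
    def test_uniform_foreground_ratio(self):
        img = np.tile(np.array([120.0, 60.0, 40.0]), (10, 10, 1))
        assert pr.color_feature(img) == pytest.approx(2.0)

    def test_equal_channels_give_unity(self):
        img = np.tile(np.array([80.0, 80.0, 40.0]), (5, 5, 1))
        assert pr.color_feature(img) == pytest.approx(1.0)

    def test_zero_green_raises(self):
        img = np.tile(np.array([50.0, 0.0, 0.0]), (5, 5, 1))
        with pytest.raises(UndefinedFeatureError):
            pr.color_feature(img)

    def test_all_background_raises(self):
        img = np.full((5, 5, 3), 200.0)
        with pytest.raises(NoForegroundError):
            pr.color_feature(img)

    def test_recovered_under_random_illumination(self, chart_layout):
        """Fixture with known ground-truth ratio 1.45: correction recovers
        the feature within 0.02 despite an unknown illumination."""
        rng = np.random.default_rng(42)
        illum = pr.random_illumination(rng)
        img, truth = pr.render_fruit_image(
            1.45, chart_layout, illumination=illum, seed=11, pixel_noise_sigma=0.0
        )
        observed = pr.extract_chips(img, chart_layout)
        t = pr.fit_color_transform(chart_layout.reference_chips(), observed)
        assert pr.color_feature(img, t) == pytest.approx(1.45, abs=0.02)
        np.testing.assert_allclose(truth.illumination, illum)

    def test_feature_invariant_to_illumination(self, chart_layout):
        """The corrected feature moves by < 0.02 across random illuminations
        of the same noiseless scene — the purpose of chart correction."""
        features = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            img, _ = pr.render_fruit_image(
                1.3, chart_layout, illumination=pr.random_illumination(rng),
                seed=3, pixel_noise_sigma=0.0,
            )
            obs = pr.extract_chips(img, chart_layout)
            t = pr.fit_color_transform(chart_layout.reference_chips(), obs)
            features.append(pr.color_feature(img, t))
        assert max(features) - min(features) < 0.02
        assert features[0] == pytest.approx(1.3, abs=0.02)


class TestLayoutSerialization:
    def test_json_round_trip(self, chart_layout):
        restored = pr.ChartLayout.from_json(chart_layout.to_json())
        assert restored == chart_layout

    def test_wrong_chip_count_rejected(self, chart_layout):
        with pytest.raises(ValueError):
            pr.ChartLayout(chips=chart_layout.chips[:10], reference_rgb=None)
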