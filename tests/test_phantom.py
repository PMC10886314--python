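"""Synthetic phantom generator: geometry, rasterization, rendering, perturbation."""
import numpy as np
import pytest
from scipy.spatial import cKDTree

import sonotriage as st
from sonotriage._geometry import Ellipse, RotRect, ellipse_rect_distance
from sonotriage.phantom import dataset_annotations
from sonotriage.annotations import annotations_to_label_mask

from conftest import small_spec


class TestGenerateScene:
    def test_seeded_reproducibility(self, spec96):
        s1 = st.generate_scene(spec96, np.random.default_rng(42))
        s2 = st.generate_scene(spec96, np.random.default_rng(42))
        assert s1.true_min_distances == s2.true_min_distances
        for name in s1.primitives:
            assert s1.primitives[name] == s2.primitives[name]

    def test_no_shrapnel_gives_empty_distances(self):
        spec = small_spec(feature_counts={"vein": 1, "artery": 1, "nerve": 1, "shrapnel": 0})
        scene = st.generate_scene(spec, np.random.default_rng(0))
        assert "shrapnel" not in scene.primitives
        assert scene.true_min_distances == {}
        assert scene.true_triage_score is None

    def test_distance_within_requested_range(self, spec96):
        for seed in range(10):
            scene = st.generate_scene(spec96, np.random.default_rng(seed))
            lo, hi = spec96.shrapnel_distance_range
            assert lo <= scene.true_triage_score <= hi

    def test_infeasible_spec_raises(self):
        spec = small_spec(shrapnel_distance_range=(0.001, 0.002))
        with pytest.raises(st.InfeasibleSpecError):
            st.generate_scene(spec, np.random.default_rng(0))

    def test_analytic_distance_matches_dense_sampling_oracle(self):
        # fixed axis-aligned rod (length 10, width 2) vs circular artery (r=5)
        rod = RotRect(cx=50.0, cy=50.0, length=10.0, width=2.0, angle=0.0)
        circle = Ellipse(cx=70.0, cy=58.0, a=5.0, b=5.0, angle=0.0)
        analytic = ellipse_rect_distance(circle, rod)
        # oracle: dense boundary sampling of both primitives, >= 1e4 each
        a = rod.boundary_points(12000)
        b = circle.boundary_points(12000)
        oracle = cKDTree(a).query(b)[0].min()
        assert analytic == pytest.approx(oracle, abs=1e-3)
        # nearest rod point is the corner (55, 51): exact corner-to-circle distance
        closed = np.hypot(70.0 - 55.0, 58.0 - 51.0) - 5.0
        assert analytic == pytest.approx(closed, abs=1e-3)


class TestRasterize:
    def test_empty_scene_is_all_background(self, spec96):
        scene = st.SceneGeometry(96, {}, {})
        mask = st.rasterize_mask(scene, spec96)
        assert (mask == 0).all()

    def test_axis_aligned_rect_on_pixel_boundaries_counts_exactly(self, spec96):
        rod = RotRect(cx=25.0, cy=10.0, length=10.0, width=2.0, angle=0.0)
        scene = st.SceneGeometry(96, {"shrapnel": [rod]}, {})
        mask = st.rasterize_mask(scene, spec96)
        assert (mask == 4).sum() == 20

    def test_circle_pixel_count_near_area(self, spec96):
        circ = Ellipse(cx=48.0, cy=48.0, a=10.0, b=10.0)
        scene = st.SceneGeometry(96, {"vein": [circ]}, {})
        mask = st.rasterize_mask(scene, spec96)
        count = int((mask == 1).sum())
        # brute-force center-inside count is the definition; area bound sanity
        yy, xx = np.mgrid[0:96, 0:96]
        brute = int(((xx + 0.5 - 48.0) ** 2 + (yy + 0.5 - 48.0) ** 2 <= 100.0).sum())
        assert count == brute
        assert abs(count - np.pi * 100.0) < 2 * np.pi * 10.0

    def test_overlap_priority_highest_label_wins(self, spec96):
        circ = Ellipse(cx=30.0, cy=30.0, a=8.0, b=8.0)
        rod = RotRect(cx=30.0, cy=30.0, length=6.0, width=2.0)
        scene = st.SceneGeometry(96, {"vein": [circ], "shrapnel": [rod]}, {})
        mask = st.rasterize_mask(scene, spec96)
        assert mask[30, 30] == 4  # shrapnel overrides vein where they overlap
        assert (mask == 1).sum() > 0


class TestRenderImage:
    def test_zero_noise_is_piecewise_constant(self, spec96):
        spec = small_spec(speckle_strength=0.0)
        scene = st.generate_scene(spec, np.random.default_rng(3))
        img = st.render_image(scene, spec, np.random.default_rng(4))
        mask = st.rasterize_mask(scene, spec)
        for name, label in spec.class_table.items():
            region = mask == label
            if region.any():
                assert (img[region] == round(spec.intensity_table[name])).all()

    def test_same_seed_identical(self, spec96):
        scene = st.generate_scene(spec96, np.random.default_rng(5))
        img1 = st.render_image(scene, spec96, np.random.default_rng(6))
        img2 = st.render_image(scene, spec96, np.random.default_rng(6))
        assert np.array_equal(img1, img2)

    def test_speckle_preserves_class_means(self):
        # Monte-Carlo check of the unit-mean multiplicative noise model on a
        # 256x256 frame: per-class sample mean within 3 standard errors for
        # every class with enough pixels to make the test meaningful.
        spec = st.PhantomSpec(speckle_strength=0.15)
        scene = st.generate_scene(spec, np.random.default_rng(7))
        mask = st.rasterize_mask(scene, spec)
        img = st.render_image(scene, spec, np.random.default_rng(8)).astype(float)
        for name, label in spec.class_table.items():
            region = mask == label
            n = int(region.sum())
            if n < 500:
                continue
            mu = spec.intensity_table[name]
            se = mu * spec.speckle_strength / np.sqrt(n)
            assert abs(img[region].mean() - mu) < 3 * se + 0.5  # +0.5 rounding


class TestPerturbMask:
    def test_zero_magnitude_is_identity(self, dataset96):
        mask = dataset96[0][0].mask
        for mode in ("dilate", "erode"):
            assert np.array_equal(st.perturb_mask(mask, mode, 0), mask)

    def test_single_pixel_dilate_radius_one_gives_cross(self):
        mask = np.zeros((9, 9), dtype=np.uint8)
        mask[4, 4] = 4
        out = st.perturb_mask(mask, "dilate", 1)
        assert (out == 4).sum() == 5
        assert out[4, 4] == out[3, 4] == out[5, 4] == out[4, 3] == out[4, 5] == 4

    def test_dilate_monotone_erode_antitone(self, dataset96, rng):
        samples, _ = dataset96
        for sample in samples[:5]:
            dil = st.perturb_mask(sample.mask, "dilate", 2)
            ero = st.perturb_mask(sample.mask, "erode", 2)
            for label in np.unique(sample.mask):
                if label == 0:
                    continue
                n0 = (sample.mask == label).sum()
                assert (dil == label).sum() >= n0
                assert (ero == label).sum() <= n0

    def test_erode_keep_nonempty_retains_interior_pixel(self):
        mask = np.zeros((9, 9), dtype=np.uint8)
        mask[4, 4] = 4  # single pixel would vanish under erosion
        out = st.perturb_mask(mask, "erode", 2, keep_nonempty=True)
        assert (out == 4).sum() == 1 and out[4, 4] == 4
        out2 = st.perturb_mask(mask, "erode", 2, keep_nonempty=False)
        assert (out2 == 4).sum() == 0

    def test_dilate_implies_perfect_recall(self, dataset96):
        samples, _ = dataset96
        sample = samples[0]
        dil = st.perturb_mask(sample.mask, "dilate", 2)
        counts = st.confusion_counts(dil, sample.mask, st.DEFAULT_CLASS_TABLE)
        rep = st.compute_metrics(counts)
        for name in ("vein", "artery", "nerve", "shrapnel"):
            assert rep.per_class[name]["recall"] == 1.0
            assert rep.per_class[name]["precision"] < 1.0

    def test_flip_changes_only_boundary_adjacent_pixels(self, dataset96, rng):
        samples, _ = dataset96
        mask = samples[1].mask
        out = st.perturb_mask(mask, "flip", 0.3, rng=rng)
        changed = out != mask
        padded = np.pad(mask, 1, mode="edge")
        neigh = np.stack([padded[:-2, 1:-1], padded[2:, 1:-1], padded[1:-1, :-2], padded[1:-1, 2:]])
        boundary = (neigh != mask[None]).any(axis=0)
        assert changed.sum() > 0
        assert (changed & ~boundary).sum() == 0

    def test_unknown_mode_raises(self, dataset96):
        with pytest.raises(ValueError):
            st.perturb_mask(dataset96[0][0].mask, "smudge", 1)


class TestGenerateDataset:
    def test_composition_matches_direct_chain(self, spec96):
        samples, _ = st.generate_dataset(spec96, 1, seed=21)
        rng = np.random.default_rng([21, 0])
        scene = st.generate_scene(spec96, rng)
        mask = st.rasterize_mask(scene, spec96)
        image = st.render_image(scene, spec96, rng)
        assert np.array_equal(samples[0].mask, mask)
        assert np.array_equal(samples[0].image, image)

    def test_ids_distinct_and_labels_valid(self, dataset96, spec96):
        samples, annset = dataset96
        ids = {s.sample_id for s in samples}
        assert len(ids) == 20
        valid = set(spec96.class_table.values())
        for s in samples:
            assert set(np.unique(s.mask)) <= valid

    def test_annotation_mask_round_trip_exact(self, dataset96, spec96):
        samples, annset = dataset96
        for i, sample in enumerate(samples):
            rebuilt = annotations_to_label_mask(annset, i + 1, spec96.class_table)
            assert np.array_equal(rebuilt, sample.mask)

    def test_bad_n_raises(self, spec96):
        with pytest.raises(ValueError):
            st.generate_dataset(spec96, 0)
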