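"""Clustering, nearest-centroid classification and composition reports."""

import numpy as np
import pytest

from flocia import (
    CATEGORY_NAMES,
    SyntheticFlowerSpec,
    classify_image,
    classify_pixels,
    cluster_dominant_colors,
    composition_report,
    generate_flower,
)
from flocia.classification import is_multicolored
from flocia.segmentation import DegenerateInputWarning


class TestClustering:
    def test_single_color_degenerates_to_one_cluster(self):
        pixels = np.tile([200.0, 140.0, 190.0], (50, 1))
        res = cluster_dominant_colors(pixels, k=3, seed=0)
        assert res.k_used == 1
        assert res.sizes.tolist() == [50]
        assert res.dominant == (0,)

    def test_two_color_mixture_sizes_recovered(self, rng):
        # 70/30 mixture of two well-separated chroma clusters
        a = np.column_stack([np.full(700, 200.0),
                             rng.normal(130, 2, 700), rng.normal(200, 2, 700)])
        b = np.column_stack([np.full(300, 150.0),
                             rng.normal(170, 2, 300), rng.normal(120, 2, 300)])
        pixels = np.vstack([a, b])
        res = cluster_dominant_colors(pixels, k=3, seed=1)
        sizes = sorted(res.sizes[list(res.dominant)], reverse=True)
        assert abs(sizes[0] / 10.0 - 70.0) <= 2.0
        assert abs(sizes[1] / 10.0 - 30.0) <= 2.0
        big, small = res.dominant
        assert np.allclose(res.centers[big], [130, 200], atol=3)
        assert np.allclose(res.centers[small], [170, 120], atol=3)

    def test_deterministic_for_fixed_seed(self, rng):
        pixels = np.column_stack(
            [np.full(200, 180.0), rng.uniform(120, 180, 200), rng.uniform(120, 200, 200)]
        )
        r1 = cluster_dominant_colors(pixels, seed=42)
        r2 = cluster_dominant_colors(pixels, seed=42)
        assert np.array_equal(r1.labels, r2.labels)
        assert np.array_equal(r1.centers, r2.centers)

    def test_clusters_ignore_lightness(self, rng):
        ab = np.column_stack([rng.normal(140, 2, 100), rng.normal(190, 2, 100)])
        lo = np.column_stack([np.full(100, 50.0), ab])
        hi = np.column_stack([np.full(100, 240.0), ab])
        res = cluster_dominant_colors(np.vstack([lo, hi]), k=3, seed=0)
        # same chroma at wildly different lightness stays one cluster
        assert res.sizes.max() == 200

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_dominant_colors(np.empty((0, 3)))


class TestClassifyPixels:
    def test_pixel_at_palette_mean_maps_to_its_category(self, palette):
        vecs = palette.vectors()
        cats = classify_pixels(vecs, palette)
        assert cats.tolist() == list(range(7))

    def test_tie_breaks_to_lowest_index(self, palette):
        ab = palette.ab_vectors()
        mid = (ab[2] + ab[3]) / 2.0  # equidistant from categories 2 and 3
        d = np.linalg.norm(ab - mid, axis=1)
        assert d[2] == pytest.approx(d[3])
        pixel = np.array([[150.0, mid[0], mid[1]]])
        assert classify_pixels(pixel, palette)[0] == 2

    def test_matches_brute_force_scan(self, palette, rng):
        pixels = rng.uniform(0, 255, (1000, 3))
        got = classify_pixels(pixels, palette)
        ab = palette.ab_vectors()
        for px, cat in zip(pixels, got):
            dists = [np.hypot(px[1] - v[0], px[2] - v[1]) for v in ab]
            assert cat == int(np.argmin(dists))

    def test_use_L_changes_metric(self, palette, rng):
        pixels = rng.uniform(0, 255, (500, 3))
        got = classify_pixels(pixels, palette, use_L=True)
        vecs = palette.vectors()
        for px, cat in zip(pixels, got):
            dists = np.linalg.norm(vecs - px, axis=1)
            assert cat == int(np.argmin(dists))

    def test_translation_invariance(self, palette, rng):
        from flocia.palette import ReferencePalette

        pixels = rng.uniform(60, 180, (300, 3))
        shift = np.array([5.0, 7.0, -4.0])
        shifted_pal = ReferencePalette(
            entries={n: palette[n] + shift for n in CATEGORY_NAMES}
        )
        a = classify_pixels(pixels, palette)
        b = classify_pixels(pixels + shift, shifted_pal)
        assert np.array_equal(a, b)


class TestCompositionReport:
    def test_single_category(self):
        pixels = np.tile([200.0, 140.0, 190.0], (10, 1))
        rep = composition_report(np.zeros(10, dtype=int), pixels)
        assert rep.percentages["yellowish white"] == 100.0
        assert sum(rep.percentages.values()) == pytest.approx(100.0)
        assert rep.dominant_category == "yellowish white"

    def test_three_quarters_one_quarter(self):
        cats = np.array([2, 2, 2, 4])
        pixels = np.tile([200.0, 140.0, 190.0], (4, 1))
        rep = composition_report(cats, pixels)
        assert rep.percentages["medium yellow"] == 75.0
        assert rep.percentages["orange"] == 25.0

    def test_mean_vector_is_pixel_mean(self, rng):
        pixels = rng.uniform(0, 255, (64, 3))
        rep = composition_report(rng.integers(0, 7, 64), pixels)
        assert np.allclose(rep.mean_vector, pixels.mean(axis=0))

    def test_percentages_conserved_on_random_inputs(self, rng):
        for _ in range(10):
            n = int(rng.integers(1, 500))
            rep = composition_report(rng.integers(0, 7, n), rng.uniform(0, 255, (n, 3)))
            assert sum(rep.percentages.values()) == pytest.approx(100.0, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            composition_report(np.empty(0, dtype=int), np.empty((0, 3)))

    def test_multicolored_judgment(self):
        cats = np.array([2] * 50 + [4] * 30 + [6] * 20)
        rep = composition_report(cats, np.tile([200.0, 140.0, 190.0], (100, 1)))
        assert is_multicolored(rep, threshold=20.0)
        assert not is_multicolored(rep, threshold=40.0)


class TestClassifyImage:
    def test_single_color_flower(self, palette):
        spec = SyntheticFlowerSpec(seed=9, composition={"orange": 1.0})
        img, _ = generate_flower(spec)
        rep, clus, seg = classify_image(img, palette, seed=0)
        assert rep.dominant_category == "orange"
        assert rep.percentages["orange"] >= 95.0

    def test_all_white_image_degenerates_with_warning(self, palette):
        img = np.full((32, 32, 3), 255, dtype=np.uint8)
        with pytest.warns(DegenerateInputWarning):
            rep, clus, seg = classify_image(img, palette)
        assert rep.n_pixels == 0
        assert rep.dominant_category is None
        assert clus is None

    def test_repeated_runs_identical(self, palette, mix_flower):
        _, img, _ = mix_flower
        r1, c1, _ = classify_image(img, palette, seed=3)
        r2, c2, _ = classify_image(img, palette, seed=3)
        assert r1.percentages == r2.percentages
        assert np.array_equal(c1.labels, c2.labels)
        assert np.array_equal(r1.mean_vector, r2.mean_vector)

    def test_recovers_fixture_composition(self, palette, mix_flower):
        _, img, truth = mix_flower
        rep, _, _ = classify_image(img, palette, seed=0)
        for name in CATEGORY_NAMES:
            expected = 100.0 * truth.composition.get(name, 0.0)
            assert abs(rep.percentages[name] - expected) <= 2.0
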