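"""Particle thresholding, pooled fluorescence, proliferation index, AFOG."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import heartregen as hr
from heartregen.imaging import (
    ChannelImage,
    SectionCellCounts,
    afog_composition,
    colocalization_ratio,
    mean_fluorescence,
    percent_area,
    proliferation_index,
    threshold_particles,
)


def brute_force_particles(binary, min_area):
    """Independent 8-connected labeling (BFS flood fill) + area filter."""
    h, w = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    particles = []
    for i in range(h):
        for j in range(w):
            if binary[i, j] and not seen[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                comp = []
                while stack:
                    y, x = stack.pop()
                    comp.append((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if 0 <= ny < h and 0 <= nx < w and binary[ny, nx] and not seen[ny, nx]:
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                if len(comp) > min_area:
                    particles.append(frozenset(comp))
    return set(particles)


class TestThresholdParticles:
    def test_zero_image_empty_mask(self):
        pm = threshold_particles(ChannelImage(np.zeros((20, 20))), threshold=1.0)
        assert pm.total_area == 0 and pm.empty_after_filter

    def test_single_square_survives(self):
        img = np.zeros((30, 30))
        img[5:15, 5:15] = 100.0
        pm = threshold_particles(ChannelImage(img), threshold=50, min_area=50)
        assert pm.n_particles == 1
        # the 3x3 median despeckle shaves the four single-pixel corners
        assert pm.total_area == 100 - 4

    def test_despeckle_removes_isolated_pixels(self):
        img = np.zeros((40, 40))
        img[2, 2] = 100.0  # lone speckle
        img[10:30, 10:30] = 100.0
        pm = threshold_particles(ChannelImage(img), threshold=50, min_area=10)
        assert pm.n_particles == 1
        assert not pm.mask[2, 2]

    def test_area_filter_matches_brute_force(self, rng):
        # random rectangles; compare the retained pixel sets against an
        # independently coded flood-fill + area filter on the same
        # despeckled mask
        from scipy import ndimage

        img = np.zeros((120, 120))
        for _ in range(20):
            y, x = rng.integers(0, 100, 2)
            hgt, wid = rng.integers(2, 15, 2)
            img[y : y + hgt, x : x + wid] = 100.0
        pm = threshold_particles(ChannelImage(img), threshold=50, min_area=30)
        despeckled = ndimage.median_filter((img >= 50).astype(np.uint8), size=3) > 0
        expected = brute_force_particles(despeckled, min_area=30)
        ours = {
            frozenset(map(tuple, np.argwhere(pm.labels == k)))
            for k in range(1, pm.n_particles + 1)
        }
        assert ours == expected

    def test_all_particles_exceed_min_area(self, rng):
        img = (rng.random((80, 80)) > 0.6) * 100.0
        pm = threshold_particles(ChannelImage(img), threshold=50, min_area=20)
        assert np.all(pm.particle_areas > 20)


class TestMeanFluorescence:
    def test_uniform_intensity(self):
        img = np.zeros((20, 20))
        img[0:10, 0:10] = 7.0
        roi = threshold_particles(ChannelImage(img), 1.0, min_area=10)
        measured = mean_fluorescence(ChannelImage(img), roi)
        assert measured == pytest.approx(7.0)

    def test_pooled_not_mean_of_means(self):
        # area 10 at intensity 10 + area 90 at intensity 0 -> pooled 1.0
        roi_img = np.zeros((40, 40))
        roi_img[0:1, 0:10] = 100.0  # would vanish under 3x3 median; build mask directly
        labels = np.zeros((40, 40), dtype=int)
        labels[0:1, 0:10] = 1
        labels[10:19, 10:20] = 2  # area 90
        roi = hr.ParticleMask(labels=labels, min_area=0)
        measure = np.zeros((40, 40))
        measure[0:1, 0:10] = 10.0
        assert mean_fluorescence(ChannelImage(measure), roi) == pytest.approx(1.0)

    def test_empty_roi_errors(self):
        roi = hr.ParticleMask(labels=np.zeros((5, 5), dtype=int), min_area=0)
        with pytest.raises(ValueError, match="empty_roi"):
            mean_fluorescence(ChannelImage(np.ones((5, 5))), roi)

    def test_translation_invariance(self, rng):
        img = rng.random((30, 30)) * 50
        labels = np.zeros((30, 30), dtype=int)
        labels[5:12, 5:12] = 1
        roi = hr.ParticleMask(labels, 0)
        shifted_img = np.roll(img, (7, 3), axis=(0, 1))
        shifted_roi = hr.ParticleMask(np.roll(labels, (7, 3), axis=(0, 1)), 0)
        assert mean_fluorescence(ChannelImage(img), roi) == pytest.approx(
            mean_fluorescence(ChannelImage(shifted_img), shifted_roi)
        )

    def test_intensity_scaling(self, rng):
        img = rng.random((20, 20)) * 10
        labels = (rng.random((20, 20)) > 0.5).astype(int)
        roi = hr.ParticleMask(labels, 0)
        m1 = mean_fluorescence(ChannelImage(img), roi)
        m3 = mean_fluorescence(ChannelImage(img * 3), roi)
        assert m3 == pytest.approx(3 * m1)


class TestColocalizationRatio:
    def test_identical_rois_give_unity(self, rng):
        img = ChannelImage(rng.random((20, 20)) * 100)
        labels = np.zeros((20, 20), dtype=int)
        labels[3:10, 3:10] = 1
        roi = hr.ParticleMask(labels, 0)
        assert colocalization_ratio(img, roi, roi) == 1.0

    def test_scaling_leaves_ratio_unchanged(self, image_set):
        ra = threshold_particles(image_set["marker_a"], 500, 50)
        rb = threshold_particles(image_set["marker_b"], 500, 50)
        g = image_set["gfp"]
        r1 = colocalization_ratio(g, ra, rb)
        r2 = colocalization_ratio(ChannelImage(g.data * 2.5, role="GFP"), ra, rb)
        assert r2 == pytest.approx(r1)

    def test_planted_ratio_recovered(self, image_set):
        ra = threshold_particles(image_set["marker_a"], 500, 50)
        rb = threshold_particles(image_set["marker_b"], 500, 50)
        r = colocalization_ratio(image_set["gfp"], ra, rb)
        truth = image_set["truth"]["intensity_ratio"]
        assert abs(r / truth - 1) < 0.05


class TestProliferationIndex:
    def test_all_zero_doubles(self):
        secs = [SectionCellCounts(f"s{i}", "h1", 100, 0) for i in range(3)]
        table = proliferation_index(secs)
        assert table["index"].iloc[0] == 0.0

    def test_mean_of_section_indices_not_pooled(self):
        secs = [
            SectionCellCounts("s1", "h1", 100, 10),
            SectionCellCounts("s2", "h1", 200, 30),
        ]
        table = proliferation_index(secs)
        assert table["index"].iloc[0] == pytest.approx(0.125)  # not 40/300

    def test_heart_index_bounded_by_section_indices(self, rng):
        secs, _ = hr.simulate_section_counts(hr.SimulationConfig(seed=5))
        per_sec = proliferation_index(secs, per_heart=False)
        per_heart = proliferation_index(secs, per_heart=True).set_index("heart_id")
        for heart, grp in per_sec.groupby("heart_id"):
            idx = per_heart.loc[heart, "index"]
            assert grp["index"].min() - 1e-12 <= idx <= grp["index"].max() + 1e-12

    def test_zero_mef2_section_excluded_with_warning(self):
        secs = [
            SectionCellCounts("s1", "h1", 0, 0),
            SectionCellCounts("s2", "h1", 100, 10),
            SectionCellCounts("s3", "h1", 100, 20),
        ]
        with pytest.warns(UserWarning, match="no Mef2"):
            table = proliferation_index(secs)
        assert table["index"].iloc[0] == pytest.approx(0.15)

    def test_double_positive_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            SectionCellCounts("s1", "h1", 10, 11)


class TestAfogComposition:
    @pytest.mark.parametrize(
        "red, blue, expected",
        [((100, 0), None, (100, 0, 0)), ((30, 20), None, (30, 20, 50))],
    )
    def test_subtraction_rule(self, red, blue, expected):
        assert afog_composition(*red) == expected

    def test_overfull_composition_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            afog_composition(60, 50)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0, 100), st.floats(0, 100))
    def test_always_sums_to_100(self, r, b):
        if r + b > 100:
            with pytest.raises(ValueError):
                afog_composition(r, b)
        else:
            assert sum(afog_composition(r, b)) == pytest.approx(100.0)

    def test_planted_tricolor_areas_recovered(self, rng):
        # 25% red / 35% blue / 40% orange planted as solid blocks
        h, w = 100, 100
        red = np.zeros((h, w))
        blue = np.zeros((h, w))
        red[:25, :] = 200.0
        blue[25:60, :] = 200.0
        red_pct = percent_area(threshold_particles(ChannelImage(red, "AFOG_red"), 100, 50))
        blue_pct = percent_area(threshold_particles(ChannelImage(blue, "AFOG_blue"), 100, 50))
        r, b, o = afog_composition(red_pct, blue_pct)
        assert r == pytest.approx(25, abs=1)
        assert b == pytest.approx(35, abs=1)
        assert o == pytest.approx(40, abs=1)
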