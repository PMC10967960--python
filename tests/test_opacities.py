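"""Opacity detection, shape descriptors, size taxonomy and aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octvit import (
    CLASS_NAMES,
    classify_size,
    detect_opacities,
    shape_features,
    summarise_eye,
    suppress_background,
)
from tests.oracles import brute_force_moments, filled_ellipse_mask, flood_fill_components

PIXEL_AREA = 3.815


class TestSuppressBackground:
    def test_forced_blob_on_constant_background(self):
        frame = np.full((50, 50), 0.05)
        frame[10, 10:13] = 0.9
        mask = np.ones_like(frame, dtype=bool)
        out = suppress_background(frame, mask, k_sigma=6.0)
        assert out.sum() == 3
        assert out[10, 10:13].all()

    def test_constant_region_yields_no_detections(self):
        frame = np.full((30, 30), 0.2)
        out = suppress_background(frame, np.ones_like(frame, bool), k_sigma=6.0)
        assert not out.any()

    def test_pure_speckle_specificity(self):
        # multiplicative gamma(4) speckle, no blobs: < 0.1% of pixels survive
        fractions = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            frame = 0.05 * rng.gamma(4.0, 0.25, size=(200, 500))
            out = suppress_background(frame, np.ones_like(frame, bool), k_sigma=6.0)
            fractions.append(out.mean())
        assert max(fractions) < 1e-3

    def test_pixels_outside_mask_never_selected(self):
        frame = np.full((20, 20), 0.05)
        frame[0, 0] = 1.0  # bright but outside the mask
        mask = np.zeros_like(frame, bool)
        mask[5:15, :] = True
        out = suppress_background(frame, mask, k_sigma=6.0)
        assert not out[0, 0]


class TestClassifySize:
    @pytest.mark.parametrize(
        "area,expected",
        [
            (3.815, "isolated"),
            (7.63, "isolated"),
            (9.999, "isolated"),
            (10.0, "non_activated"),  # boundary joins the upper class
            (49.9, "non_activated"),
            (50.0, "activated"),
            (249.9, "activated"),
            (250.0, "complex"),
            (251.0, "complex"),
            (1e6, "complex"),
        ],
    )
    def test_half_open_intervals(self, area, expected):
        assert classify_size(area) == expected

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan")])
    def test_non_positive_area_rejected(self, bad):
        with pytest.raises(ValueError):
            classify_size(bad)


class TestShapeFeatures:
    def test_single_pixel_is_round_by_convention(self):
        assert shape_features(np.array([[5, 7]])) == (0.0, 0.0)

    def test_filled_disc_is_round(self):
        mask = filled_ellipse_mask(8.0, 8.0, 0.0, span=10)
        pixels = np.column_stack(np.nonzero(mask))
        ecc, _ = shape_features(pixels)
        assert ecc <= 0.05

    def test_horizontal_line_is_maximally_elongated(self):
        pixels = np.array([[3, c] for c in range(20)])
        ecc, orient = shape_features(pixels)
        assert ecc >= 0.99
        assert orient == pytest.approx(0.0, abs=1e-9)

    def test_vertical_line_orientation_is_90(self):
        pixels = np.array([[r, 3] for r in range(20)])
        ecc, orient = shape_features(pixels)
        assert ecc >= 0.99
        assert orient == pytest.approx(90.0)

    def test_rotated_20x10_ellipse(self):
        # axes 20 x 10 px -> ecc = sqrt(1 - (1/2)^2) = sqrt(3)/2 = 0.866
        mask = filled_ellipse_mask(10.0, 5.0, 30.0, span=14)
        pixels = np.column_stack(np.nonzero(mask))
        ecc, orient = shape_features(pixels)
        assert ecc == pytest.approx(math.sqrt(3) / 2, abs=0.02)
        assert orient == pytest.approx(30.0, abs=2.0)

    @pytest.mark.parametrize("theta", [-80, -45, -10, 0, 15, 45, 60, 89])
    def test_rotation_equivariance_for_elongated_blobs(self, theta):
        mask = filled_ellipse_mask(12.0, 4.0, float(theta), span=16)  # ecc 0.94
        pixels = np.column_stack(np.nonzero(mask))
        _, orient = shape_features(pixels)
        delta = abs(orient - theta) % 180.0
        assert min(delta, 180.0 - delta) <= 2.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(dr=st.integers(-500, 500), dc=st.integers(-500, 500))
    def test_translation_invariance(self, dr, dc):
        base = np.column_stack(np.nonzero(filled_ellipse_mask(9.0, 4.0, 25.0, span=12)))
        ecc0, or0 = shape_features(base)
        ecc1, or1 = shape_features(base + np.array([dr, dc]))
        assert ecc1 == pytest.approx(ecc0, abs=1e-12)
        assert or1 == pytest.approx(or0, abs=1e-12)


class TestDetectOpacities:
    def test_two_disjoint_squares(self):
        b = np.zeros((12, 12), bool)
        b[1:3, 1:3] = True
        b[7:9, 7:9] = True
        recs = detect_opacities(b, b.astype(float), PIXEL_AREA)
        assert len(recs) == 2
        for r in recs:
            assert r.area_px == 4
            assert r.area_um2 == pytest.approx(15.26)
            assert r.size_class == "non_activated"

    def test_single_pixel_is_isolated_cell(self):
        b = np.zeros((5, 5), bool)
        b[2, 2] = True
        recs = detect_opacities(b, b.astype(float), PIXEL_AREA, min_area_px=1)
        assert len(recs) == 1
        assert recs[0].area_um2 == pytest.approx(3.815)
        assert recs[0].size_class == "isolated"
        assert recs[0].centroid == (2.0, 2.0)

    def test_min_area_filter(self):
        b = np.zeros((8, 8), bool)
        b[0, 0] = True
        b[4:6, 4:6] = True
        recs = detect_opacities(b, b.astype(float), PIXEL_AREA, min_area_px=2)
        assert len(recs) == 1
        assert recs[0].area_px == 4

    def test_diagonal_pair_split_by_connectivity(self):
        b = np.zeros((4, 4), bool)
        b[1, 1] = b[2, 2] = True
        assert len(detect_opacities(b, b.astype(float), PIXEL_AREA, connectivity=8)) == 1
        assert len(detect_opacities(b, b.astype(float), PIXEL_AREA, connectivity=4)) == 2

    def test_mean_intensity_from_source_frame(self):
        b = np.zeros((4, 4), bool)
        b[1, 1:3] = True
        frame = np.zeros((4, 4))
        frame[1, 1] = 0.4
        frame[1, 2] = 0.8
        recs = detect_opacities(b, frame, PIXEL_AREA)
        assert recs[0].mean_intensity == pytest.approx(0.6)


class TestOracleEquivalence:
    """Labelling + moments must agree with brute-force flood fill and sums."""

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_all_3x3_patches(self, connectivity):
        for bits in range(512):
            patch = np.array([(bits >> k) & 1 for k in range(9)], bool).reshape(3, 3)
            self._check(patch, connectivity)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_random_20x20_patches(self, connectivity):
        rng = np.random.default_rng(42)
        for density in (0.1, 0.35, 0.6):
            for _ in range(40):
                patch = rng.random((20, 20)) < density
                self._check(patch, connectivity)

    @staticmethod
    def _check(patch, connectivity):
        recs = detect_opacities(patch, patch.astype(float), PIXEL_AREA,
                                connectivity=connectivity)
        comps = flood_fill_components(patch, connectivity)
        got = {frozenset(map(tuple, r.pixels)) for r in recs}
        want = {frozenset(c) for c in comps}
        assert got == want
        by_pixels = {frozenset(map(tuple, r.pixels)): r for r in recs}
        for comp in comps:
            rec = by_pixels[frozenset(comp)]
            centroid, ecc, orient = brute_force_moments(comp)
            assert rec.centroid == pytest.approx(centroid)
            assert rec.eccentricity == pytest.approx(ecc, abs=1e-12)
            assert rec.orientation_deg == pytest.approx(orient, abs=1e-9)


def _rec(area_um2, size_class=None, ecc=0.5, orient=0.0, inten=0.5, frame=0):
    from octvit import OpacityRecord

    return OpacityRecord(
        frame_index=frame,
        pixels=np.array([[0, 0]]),
        area_px=max(1, round(area_um2 / PIXEL_AREA)),
        area_um2=area_um2,
        mean_intensity=inten,
        eccentricity=ecc,
        orientation_deg=orient,
        size_class=size_class or classify_size(area_um2),
        centroid=(0.0, 0.0),
    )


class TestSummariseEye:
    def test_mean_count_per_frame(self):
        recs = [_rec(20.0, frame=f) for f in range(3) for _ in range(10 * (f + 1))]
        s = summarise_eye(recs, n_frames=3)
        assert s.mean_n_opacities == pytest.approx(20.0)

    def test_one_per_class_gives_quarter_percentages(self):
        recs = [_rec(a) for a in (5.0, 30.0, 150.0, 400.0)]
        s = summarise_eye(recs, n_frames=1)
        assert all(s.class_percent[c] == pytest.approx(25.0) for c in CLASS_NAMES)
        assert sum(s.class_percent.values()) == pytest.approx(100.0, abs=1e-9)

    def test_zero_opacities_all_aggregates_zero(self):
        s = summarise_eye([], n_frames=5)
        assert not s.has_opacities
        assert s.total_area_um2 == 0.0
        assert all(v == 0.0 for v in s.class_percent.values())

    def test_total_area_is_sum_and_pixel_multiple(self):
        recs = [_rec(a) for a in (3.815, 15.26, 152.6)]
        s = summarise_eye(recs, n_frames=2)
        assert s.total_area_um2 == pytest.approx(sum(r.area_um2 for r in recs))
        ratio = s.total_area_um2 / PIXEL_AREA
        assert ratio == pytest.approx(round(ratio))

    def test_class_counts_conserved(self):
        rng = np.random.default_rng(3)
        recs = [_rec(float(a)) for a in rng.uniform(1, 600, size=50)]
        s = summarise_eye(recs, n_frames=4)
        assert sum(s.class_count.values()) == 50
        assert sum(s.class_percent.values()) == pytest.approx(100.0, abs=1e-9)

    def test_signed_mean_orientation_cancels(self):
        # mixed opposite tilts average back towards 0 (signed, not circular)
        recs = [_rec(30.0, orient=45.0), _rec(30.0, orient=-45.0)]
        s = summarise_eye(recs, n_frames=1)
        assert s.class_mean_orientation_deg["non_activated"] == pytest.approx(0.0)
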