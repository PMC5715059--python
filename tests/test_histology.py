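"""Birefringence classification, stain coverage and ROI scoring."""

import numpy as np
import pandas as pd
import pytest

from orgmatrix import histology as hist, simulate as sim
from orgmatrix.errors import (
    InvalidInputError,
    InvalidThresholdError,
    UndefinedStatisticError,
)


def classify_pixel_oracle(h, s, b):
    """Literal box membership in class order, independent of the vectorised path."""
    boxes = [
        ("red_orange", (0, 29), (0, 255), (70, 255)),
        ("yellow", (30, 44), (0, 255), (70, 255)),
        ("green", (45, 245), (0, 255), (70, 200)),
    ]
    for name, (h0, h1), (s0, s1), (b0, b1) in boxes:
        if h0 <= h <= h1 and s0 <= s <= s1 and b0 <= b <= b1:
            return hist.CLASS_CODES[name]
    return 0


def one_pixel(h, s, b):
    return np.array([[[h, s, b]]], dtype=np.uint8)


class TestClassifyBirefringence:
    @pytest.mark.parametrize(
        "hsb,expected",
        [
            ((29, 128, 128), "red_orange"),   # upper hue edge inclusive
            ((30, 0, 70), "yellow"),          # lower edges inclusive
            ((45, 100, 150), "green"),
            ((45, 100, 210), "none"),         # green brightness cap is 200
            ((100, 100, 60), "none"),         # below the brightness floor
        ],
    )
    def test_printed_threshold_edges(self, hsb, expected):
        label = hist.classify_birefringence(one_pixel(*hsb))[0, 0]
        assert label == hist.CLASS_CODES[expected]

    def test_matches_bruteforce_oracle_on_random_pixels(self, rng):
        hsb = rng.integers(0, 256, size=(100_000, 1, 3)).astype(np.uint8)
        got = hist.classify_birefringence(hsb)[:, 0]
        expected = np.array(
            [classify_pixel_oracle(*px) for px in hsb[:, 0, :]], dtype=np.uint8
        )
        assert np.array_equal(got, expected)

    def test_default_boxes_do_not_overlap(self, rng):
        # no pixel may satisfy two class boxes simultaneously
        hsb = rng.integers(0, 256, size=(100_000, 3))
        h, s, b = hsb[:, 0], hsb[:, 1], hsb[:, 2]
        thr = hist.DEFAULT_BIREFRINGENCE_THRESHOLDS
        members = np.stack([
            getattr(thr, name).contains(h, s, b)
            for name in ("red_orange", "yellow", "green")
        ])
        assert members.sum(axis=0).max() <= 1

    def test_malformed_threshold_rejected(self):
        with pytest.raises(InvalidThresholdError):
            hist.HsbBox((10, 5), (0, 255), (0, 255))


class TestRelativeAreas:
    def test_fixture_scene_thirds_of_total(self):
        frac = {k: 0.25 for k in sim.HISTOLOGY_CLASS_NAMES}
        scene = sim.generate_histology_scene(
            sim.HistologySceneSpec(frac, 512, 512, seed=0)
        )
        cmap = hist.classify_birefringence(scene.hsb)
        res = hist.relative_areas(cmap, hist.total_fibre_mask(scene.hsb))
        for name in ("red_orange", "yellow", "green"):
            assert res.relative_area_pct[name] == pytest.approx(100 / 3, abs=1.0)
        assert res.n_class_pixels_outside_total == 0

    def test_all_green_scene(self):
        scene = sim.generate_histology_scene(
            sim.HistologySceneSpec({"green": 1.0}, 64, 64, seed=1)
        )
        cmap = hist.classify_birefringence(scene.hsb)
        res = hist.relative_areas(cmap, hist.total_fibre_mask(scene.hsb))
        assert res.relative_area_pct["green"] == pytest.approx(100.0)

    def test_bright_red_counts_in_numerator_not_denominator(self):
        # B=220 sits inside the red-orange box (cap 255) but outside the
        # total-fibre box (cap 200): relative area exceeds the naive share
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[0, 0] = (10, 100, 220)   # red-orange, outside total
        img[0, 1] = (10, 100, 150)   # red-orange, inside total
        img[1, 0] = (100, 100, 150)  # green, inside total
        img[1, 1] = (100, 100, 30)   # background
        res = hist.relative_areas(
            hist.classify_birefringence(img), hist.total_fibre_mask(img)
        )
        assert res.total_fibre_pixels == 2
        assert res.pixel_counts["red_orange"] == 2
        assert res.relative_area_pct["red_orange"] == pytest.approx(100.0)
        assert res.n_class_pixels_outside_total == 1

    def test_no_total_pixels_undefined(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)  # all brightness 0
        with pytest.raises(UndefinedStatisticError):
            hist.relative_areas(
                hist.classify_birefringence(img), hist.total_fibre_mask(img)
            )


class TestCoverage:
    def test_blank_white_slide_zero(self):
        white = np.full((16, 16, 3), 255, dtype=np.uint8)
        assert hist.picrosirius_coverage(white) == 0.0

    def test_full_and_half_stained_fields(self):
        red = np.zeros((16, 16, 3), dtype=np.uint8)
        red[..., 0] = 200
        assert hist.picrosirius_coverage(red) == pytest.approx(100.0)
        half = np.full((16, 16, 3), 255, dtype=np.uint8)
        half[:8] = (200, 40, 40)
        assert hist.picrosirius_coverage(half) == pytest.approx(50.0, abs=0.5)


class TestDabDeconvolution:
    def test_unmix_mix_roundtrip_identity(self, rng):
        conc = rng.uniform(0, 1, size=(8, 8, 3))
        rgb = hist.mix_stains(conc, hist.DEFAULT_HDAB_VECTORS)
        back = hist.unmix_stains(rgb, hist.DEFAULT_HDAB_VECTORS)
        np.testing.assert_allclose(back, conc, atol=1e-9)

    def test_pure_white_zero_coverage(self):
        white = np.full((8, 8, 3), 255.0)
        assert hist.dab_coverage(white) == 0.0

    def test_synthetic_dab_field_full_coverage(self):
        conc = np.zeros((8, 8, 3))
        conc[..., 1] = 0.8  # strong DAB everywhere
        rgb = hist.mix_stains(conc, hist.DEFAULT_HDAB_VECTORS)
        assert hist.dab_coverage(rgb) == pytest.approx(100.0)

    def test_singular_stain_matrix_rejected(self):
        bad = np.ones((3, 3))
        with pytest.raises(InvalidInputError):
            hist.unmix_stains(np.full((4, 4, 3), 128.0), bad)


class TestScoreRois:
    def test_counts_match_point_in_rectangle_enumeration(self, rng):
        n = 300
        cells = pd.DataFrame({
            "x": rng.uniform(0, 2500, n),
            "y": rng.uniform(0, 1000, n),
            "positive": rng.random(n) < 0.4,
        })
        scores = hist.score_rois(cells, roi_size_um=500, n_rois=10)
        n_cols = int(np.floor(cells["x"].max() / 500)) + 1
        for s in scores:
            row, col = divmod(s.roi_id, n_cols)
            inside = (
                (cells["x"] >= col * 500) & (cells["x"] < (col + 1) * 500)
                & (cells["y"] >= row * 500) & (cells["y"] < (row + 1) * 500)
                & cells["positive"]
            )
            assert s.positive_count == int(inside.sum())

    def test_no_positives_all_zero(self):
        cells = pd.DataFrame({"x": [10.0, 600.0], "y": [10.0, 20.0],
                              "positive": [False, False]})
        assert all(s.positive_count == 0 for s in hist.score_rois(cells))

    def test_edge_cell_counted_once(self):
        # a cell exactly on the shared edge belongs to the right-hand ROI
        cells = pd.DataFrame({"x": [500.0], "y": [0.0], "positive": [True]})
        scores = hist.score_rois(cells, n_rois=2)
        assert [s.positive_count for s in scores] == [0, 1]

    def test_pixel_coordinates_need_calibration(self):
        cells = pd.DataFrame({"x": [5.0], "y": [5.0], "positive": [True]})
        cells.attrs["coordinate_unit"] = "px"
        with pytest.raises(InvalidInputError):
            hist.score_rois(cells)
        scores = hist.score_rois(cells, um_per_px=2.0)
        assert scores[0].positive_count == 1
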