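"""Structure-tensor orientation mapping and alignment-band statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from orgmatrix import orientation as ori, simulate as sim
from orgmatrix.errors import InvalidInputError


def grating(theta_deg, shape=(128, 128), period=8.0):
    """Sinusoidal grating whose stripes run along theta (display convention)."""
    t = np.radians(theta_deg)
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return np.sin(2 * np.pi * (cols * np.sin(t) + rows * np.cos(t)) / period)


def circ_dist_deg(a, b):
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def delta_histogram(angle_deg):
    freq = np.zeros(180)
    freq[int(angle_deg)] = 1.0
    return ori.AlignmentHistogram(np.arange(181.0), freq)


class TestStructureTensor:
    def test_constant_image_zero_components(self):
        jxx, jxy, jyy = ori.structure_tensor(np.full((16, 16), 0.7))
        assert np.allclose(jxx, 0) and np.allclose(jxy, 0) and np.allclose(jyy, 0)

    def test_horizontal_stripes_energy_in_jyy(self):
        jxx, jxy, jyy = ori.structure_tensor(grating(0))
        inner = (slice(10, -10),) * 2
        assert jyy[inner].mean() > 100 * jxx[inner].mean()
        assert abs(jxy[inner].mean()) < 0.01 * jyy[inner].mean()

    def test_positive_semidefinite_everywhere(self):
        img = sim.generate_fibre_image(sim.FibreFieldSpec(64, 64, 30, seed=0)).image
        jxx, jxy, jyy = ori.structure_tensor(img)
        assert np.all(jxx >= -1e-12) and np.all(jyy >= -1e-12)
        assert np.all(jxy**2 <= jxx * jyy + 1e-9)

    def test_tiny_image_rejected(self):
        with pytest.raises(InvalidInputError):
            ori.structure_tensor(np.zeros((3, 3)))


class TestOrientationMap:
    def test_horizontal_grating_maps_to_zero_degrees(self):
        omap = ori.orientation_map(*ori.structure_tensor(grating(0)))
        inner = omap.orientation_deg[10:-10, 10:-10]
        folded = np.minimum(inner, 180.0 - inner)  # distance to 0 on half-circle
        assert np.percentile(folded, 95) < 2.0

    @pytest.mark.parametrize("theta", [30, 45, 120])
    def test_oblique_grating_recovered(self, theta):
        omap = ori.orientation_map(*ori.structure_tensor(grating(theta)))
        inner = omap.orientation_deg[10:-10, 10:-10]
        dist = np.abs((inner - theta + 90) % 180 - 90)
        assert np.median(dist) < 2.5

    def test_flat_pixels_have_zero_weight(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 0.0  # fully flat image
        omap = ori.orientation_map(*ori.structure_tensor(img))
        assert np.all(omap.weight == 0)


class TestAlignmentHistogram:
    def test_all_mass_at_single_angle(self):
        omap = ori.OrientationMap(np.full((8, 8), 30.2), np.ones((8, 8)))
        hist = ori.alignment_histogram(omap)
        assert hist.frequency.sum() == pytest.approx(1.0)
        assert hist.frequency[30] == pytest.approx(1.0)
        assert ori.peak_alignment(hist) == pytest.approx(30.5)

    def test_normalisation_and_bin_count(self):
        img = sim.generate_fibre_image(sim.FibreFieldSpec(64, 64, 20, seed=2)).image
        hist = ori.alignment_histogram(
            ori.orientation_map(*ori.structure_tensor(img))
        )
        assert hist.frequency.size == 180
        assert hist.frequency.sum() == pytest.approx(1.0, abs=1e-9)

    def test_fully_masked_map_rejected(self):
        omap = ori.OrientationMap(np.zeros((4, 4)), np.zeros((4, 4)))
        with pytest.raises(InvalidInputError):
            ori.alignment_histogram(omap)


class TestPeakAndBands:
    def test_peak_recovery_on_concentrated_fixture(self):
        img = sim.generate_fibre_image(
            sim.FibreFieldSpec(512, 512, 600, orientation_mean_deg=120,
                               orientation_kappa=50, seed=0)
        ).image
        peak = ori.summarize_alignment(img).peak_alignment_deg
        assert circ_dist_deg(peak, 120) <= 3.0

    def test_tie_breaks_to_smallest_angle(self):
        freq = np.zeros(180)
        freq[10] = freq[100] = 0.5
        hist = ori.AlignmentHistogram(np.arange(181.0), freq)
        assert ori.peak_alignment(hist) == pytest.approx(10.5)

    def test_uniform_histogram_half_band(self):
        hist = ori.AlignmentHistogram(np.arange(181.0), np.full(180, 1 / 180))
        assert ori.band_frequency(hist, 90.5, 45) == pytest.approx(0.5)

    def test_delta_histogram_fills_every_band(self):
        hist = delta_histogram(72)
        for hw in (5, 15, 30, 45):
            assert ori.band_frequency(hist, 72.5, hw) == pytest.approx(1.0)

    def test_wraparound_matches_shifted_bruteforce(self):
        rng = np.random.default_rng(0)
        freq = rng.random(180)
        freq /= freq.sum()
        hist = ori.AlignmentHistogram(np.arange(181.0), freq)
        peak = 2.5
        got = ori.band_frequency(hist, peak, 5)
        # brute force: circular membership bin by bin
        acc = 0.0
        for i, c in enumerate(hist.bin_centers_deg):
            rel = (c - peak + 90) % 180 - 90
            if -5 <= rel < 5:
                acc += freq[i]
        assert got == pytest.approx(acc, abs=1e-12)
        assert got > 0  # band genuinely wraps through 179 deg

    def test_invalid_half_width(self):
        hist = delta_histogram(10)
        with pytest.raises(InvalidInputError):
            ori.band_frequency(hist, 10.5, 90)

    @settings(max_examples=50)
    @given(
        raw=st.lists(st.floats(0, 1), min_size=180, max_size=180),
        peak=st.floats(0, 179.9),
    )
    def test_band_monotone_in_half_width(self, raw, peak):
        freq = np.asarray(raw)
        if freq.sum() == 0:
            freq[0] = 1.0
        freq = freq / freq.sum()
        hist = ori.AlignmentHistogram(np.arange(181.0), freq)
        vals = [ori.band_frequency(hist, peak, hw) for hw in (5, 15, 30, 45)]
        assert vals == sorted(vals)


class TestPipelineProperties:
    def test_rotation_equivariance(self):
        img = sim.generate_fibre_image(
            sim.FibreFieldSpec(384, 384, 250, fibre_width_px=5,
                               orientation_mean_deg=15,
                               orientation_kappa=10000, seed=0)
        ).image
        rot = ndimage.rotate(img, 30, reshape=False, order=3)
        crop = slice(60, -60)
        p0 = ori.summarize_alignment(img[crop, crop]).peak_alignment_deg
        p1 = ori.summarize_alignment(rot[crop, crop]).peak_alignment_deg
        assert circ_dist_deg(p0, p1) == pytest.approx(30.0, abs=2.0)

    def test_band_frequencies_increase_with_concentration(self):
        medians = []
        for kappa in (2, 10, 50):
            vals = []
            for seed in range(5):
                img = sim.generate_fibre_image(
                    sim.FibreFieldSpec(256, 256, 400, fibre_length_px=64,
                                       orientation_mean_deg=60,
                                       orientation_kappa=kappa, seed=seed)
                ).image
                vals.append(ori.summarize_alignment(img).band_frequency[15])
            medians.append(float(np.median(vals)))
        assert medians[0] < medians[1] < medians[2]
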