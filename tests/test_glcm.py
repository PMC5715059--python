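"""GLCM correlation profiles, the mean correlation distance and coverage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from orgmatrix import glcm, simulate as sim
from orgmatrix.errors import InvalidInputError, UndefinedStatisticError

# offset vectors (drow, dcol) per orientation for the brute-force oracle
_OFFSETS = {0: (0, 1), 90: (1, 0), 180: (0, -1), 270: (-1, 0)}


def glcm_correlation_oracle(image, offset, orientation):
    """Direct pair enumeration + textbook correlation formula."""
    dr, dc = _OFFSETS[orientation]
    dr, dc = dr * offset, dc * offset
    h, w = image.shape
    pairs = []
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                pairs.append((image[r, c], image[r2, c2]))
                pairs.append((image[r2, c2], image[r, c]))  # symmetric
    pairs = np.array(pairs, dtype=float)
    p_i, p_j = pairs[:, 0], pairs[:, 1]
    mu, var = p_i.mean(), p_i.var()
    if var == 0:
        return None
    return float(((p_i - mu) * (p_j - mu)).mean() / var)


class TestComputeGlcm:
    def test_hand_enumerated_two_level_image(self):
        img = np.array([[0, 0], [1, 1]])
        p = glcm.compute_glcm(img, 1, 0, levels=2)
        np.testing.assert_allclose(p, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_image_single_entry(self):
        p = glcm.compute_glcm(np.zeros((4, 4), dtype=int), 1, 0, levels=2)
        assert p[0, 0] == 1.0 and p.sum() == 1.0

    def test_symmetrized_0_equals_180(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 4, (8, 8))
        np.testing.assert_allclose(
            glcm.compute_glcm(img, 2, 0, levels=4),
            glcm.compute_glcm(img, 2, 180, levels=4),
        )

    def test_bad_orientation_and_offset(self):
        img = np.zeros((4, 4), dtype=int)
        with pytest.raises(InvalidInputError):
            glcm.compute_glcm(img, 1, 45)
        with pytest.raises(InvalidInputError):
            glcm.compute_glcm(img, 4, 0)


class TestGlcmCorrelation:
    def test_hand_computed_perfect_correlation(self):
        img = np.array([[0, 0], [1, 1]])
        assert glcm.glcm_correlation(glcm.compute_glcm(img, 1, 0, levels=2)) == pytest.approx(1.0)
        assert glcm.glcm_correlation(glcm.compute_glcm(img, 1, 90, levels=2)) == pytest.approx(-1.0)

    def test_constant_image_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            glcm.glcm_correlation(glcm.compute_glcm(np.zeros((4, 4), int), 1, 0))

    def test_iid_noise_near_zero(self, rng):
        img = rng.random((512, 512))
        p = glcm.compute_glcm(img, 1, 0)
        assert abs(glcm.glcm_correlation(p)) < 0.05

    @settings(max_examples=60)
    @given(
        img=hnp.arrays(np.int64, hnp.array_shapes(min_dims=2, max_dims=2,
                                                  min_side=2, max_side=6),
                       elements=st.integers(0, 3)),
        offset=st.integers(1, 3),
        orientation=st.sampled_from([0, 90, 180, 270]),
    )
    def test_matches_brute_force_oracle(self, img, offset, orientation):
        if offset >= min(img.shape):
            return
        expected = glcm_correlation_oracle(img, offset, orientation)
        table = glcm.compute_glcm(img, offset, orientation, levels=4)
        if expected is None:
            with pytest.raises(UndefinedStatisticError):
                glcm.glcm_correlation(table)
        else:
            assert glcm.glcm_correlation(table) == pytest.approx(expected, abs=1e-12)


class TestCorrelationProfile:
    def test_default_offset_range_is_100(self):
        img = np.random.default_rng(1).random((128, 128))
        profile = glcm.correlation_profile(img)
        assert profile.offsets_px[0] == 1 and profile.offsets_px[-1] == 100
        assert profile.orientations_deg == (0, 90, 180, 270)

    def test_two_orientation_average_equals_four(self):
        # symmetric tables make 0==180 and 90==270
        img = np.random.default_rng(2).random((64, 64))
        four = glcm.correlation_profile(img, d_max=10)
        two = glcm.correlation_profile(img, d_max=10, orientations_deg=(0, 90))
        np.testing.assert_allclose(four.correlation, two.correlation, atol=1e-12)

    def test_long_correlation_decays_slower(self):
        short = sim.generate_correlated_texture(sim.TextureFieldSpec(256, 256, 2, seed=0))
        long_ = sim.generate_correlated_texture(sim.TextureFieldSpec(256, 256, 20, seed=0))
        c_short = glcm.correlation_profile(short, d_max=10).correlation[-1]
        c_long = glcm.correlation_profile(long_, d_max=10).correlation[-1]
        assert c_long > c_short

    def test_isotropic_field_orientation_agreement(self):
        img = sim.generate_correlated_texture(sim.TextureFieldSpec(256, 256, 5, seed=3))
        h = glcm.correlation_profile(img, d_max=5, orientations_deg=(0,))
        v = glcm.correlation_profile(img, d_max=5, orientations_deg=(90,))
        np.testing.assert_allclose(h.correlation, v.correlation, atol=0.05)


class TestMeanCorrelationDistance:
    def test_constant_profile_gives_midpoint(self):
        profile = glcm.CorrelationProfile(np.arange(1, 101), np.ones(100), (0,))
        assert glcm.mean_correlation_distance(profile) == pytest.approx(50.5)

    def test_point_mass_at_first_offset(self):
        c = np.zeros(10)
        c[0] = 1.0
        profile = glcm.CorrelationProfile(np.arange(1, 11), c, (0,))
        assert glcm.mean_correlation_distance(profile) == pytest.approx(1.0)

    def test_exponential_profile_matches_direct_summation(self):
        d = np.arange(1, 101)
        c = np.exp(-d / 15.0)
        profile = glcm.CorrelationProfile(d, c, (0,))
        expected = float((d * c).sum() / c.sum())
        assert glcm.mean_correlation_distance(profile) == pytest.approx(expected, abs=1e-12)

    def test_all_nonpositive_undefined(self):
        profile = glcm.CorrelationProfile(np.arange(1, 5), -np.ones(4), (0,))
        with pytest.raises(UndefinedStatisticError):
            glcm.mean_correlation_distance(profile)

    def test_iid_noise_small_when_defined(self):
        # noise carries no long-range structure: D collapses to the first
        # offsets (or is undefined when even c(1) <= 0)
        values = []
        for seed in range(5):
            img = np.random.default_rng(seed).random((512, 512))
            try:
                values.append(glcm.mean_correlation_distance(
                    glcm.correlation_profile(img, d_max=100)))
            except UndefinedStatisticError:
                continue
        assert all(v < 10 for v in values)


class TestShgCoverage:
    def test_half_above_fixed_threshold(self):
        block = np.zeros((10, 10))
        block[:5] = 1.0
        cov = glcm.shg_coverage([block], threshold=0.5)
        assert cov.coverage_pct[0] == pytest.approx(50.0)

    def test_all_zero_slice_and_peak_index(self):
        stack = [np.zeros((8, 8)), np.full((8, 8), 0.2), np.full((8, 8), 0.9)]
        stack[1][:4] = 0.9
        cov = glcm.shg_coverage(stack, threshold=0.5)
        assert cov.coverage_pct[0] == 0.0
        assert cov.peak_slice_index == int(np.argmax(cov.coverage_pct)) == 2
        assert cov.peak_coverage_pct == cov.coverage_pct.max()

    def test_empty_stack_rejected(self):
        with pytest.raises(InvalidInputError):
            glcm.shg_coverage(np.empty((0, 4, 4)))
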