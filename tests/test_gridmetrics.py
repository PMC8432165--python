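import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bvcsr
from bvcsr.gridmetrics import _fit_centered_ellipse

from conftest import hex_pattern


class TestSac:
    def test_zero_lag_is_one(self):
        m = hex_pattern()
        a = bvcsr.sac(m)
        assert a.values[a.center] == pytest.approx(1.0)

    def test_affine_invariance(self):
        m = hex_pattern()
        m2 = bvcsr.RateMap(values=2 * m.values + 3, mask=m.mask,
                           bin_size=m.bin_size, origin=m.origin)
        a1, a2 = bvcsr.sac(m), bvcsr.sac(m2)
        ok = np.isfinite(a1.values)
        np.testing.assert_allclose(a1.values[ok], a2.values[ok], atol=1e-8)

    def test_symmetric_under_lag_negation(self, small_fmap, small_learned):
        _, sm = small_learned
        m = bvcsr.grid_map(bvcsr.sr_eigenmodes(sm, small_fmap)[5], small_fmap)
        a = bvcsr.sac(m)
        flipped = a.values[::-1, ::-1]
        ok = np.isfinite(a.values) & np.isfinite(flipped)
        np.testing.assert_allclose(a.values[ok], flipped[ok], atol=1e-8)

    def test_cosine_map_has_cosine_sac(self):
        """SAC of cos(kx) along the x axis is a cosine of the same period."""
        n, bs = 80, 0.02
        xs = (np.arange(n) + 0.5) * bs
        gx, _ = np.meshgrid(xs, xs)
        period = 0.4
        vals = np.cos(2 * np.pi * gx / period)
        m = bvcsr.RateMap(values=vals - vals.min(), mask=np.ones_like(vals, bool),
                          bin_size=bs, origin=bvcsr.Point(0, 0))
        a = bvcsr.sac(m)
        cy, cx = a.center
        lags = np.arange(-30, 31)
        got = a.values[cy, cx - 30 : cx + 31]
        expected = np.cos(2 * np.pi * lags * bs / period)
        # windowed means/variances perturb the masked Pearson slightly
        np.testing.assert_allclose(got, expected, atol=0.1)
        assert got[30 + 20] > 0.95 and got[30 - 20] > 0.95  # one full period

    def test_sparse_overlap_is_missing(self):
        m = hex_pattern(n=20)
        a = bvcsr.sac(m)
        # extreme lags have < 20 overlapping bins -> NaN
        assert np.isnan(a.values[0, 0])


class TestGridness:
    def test_hexagonal_pattern_scores_high(self):
        assert bvcsr.gridness(bvcsr.sac(hex_pattern())) > 0.8

    def test_square_lattice_scores_negative(self):
        assert bvcsr.gridness(bvcsr.sac(hex_pattern(kind="sq"))) < 0.0

    def test_rotation_invariance(self):
        g0 = bvcsr.gridness(bvcsr.sac(hex_pattern()))
        g1 = bvcsr.gridness(bvcsr.sac(hex_pattern(rot=np.deg2rad(17))))
        assert abs(g0 - g1) < 0.1

    def test_hex_beats_square_for_any_annulus(self):
        hex_sac = bvcsr.sac(hex_pattern())
        sq_sac = bvcsr.sac(hex_pattern(kind="sq"))
        for inner in (3, 5, 8):
            gh = bvcsr.gridness(hex_sac, inner_radius=inner)
            gs = bvcsr.gridness(sq_sac, inner_radius=inner)
            assert gh > gs


class TestOrientationAndEllipse:
    def test_hex_orientation_by_construction(self):
        # wave vectors at 0/60/120 deg put SAC peaks at 30 deg mod 60
        ori = bvcsr.grid_orientation(bvcsr.sac(hex_pattern()))
        assert np.rad2deg(ori) == pytest.approx(30.0, abs=1.0)

    def test_orientation_equivariance(self):
        o0 = bvcsr.grid_orientation(bvcsr.sac(hex_pattern()))
        o15 = bvcsr.grid_orientation(bvcsr.sac(hex_pattern(rot=np.deg2rad(15))))
        shift = np.rad2deg((o15 - o0) % (np.pi / 3))
        assert shift == pytest.approx(15.0, abs=2.0)

    def test_orientation_stable_under_noise(self):
        o0 = bvcsr.grid_orientation(bvcsr.sac(hex_pattern()))
        o1 = bvcsr.grid_orientation(bvcsr.sac(hex_pattern(noise=0.05, seed=3)))
        assert abs(np.rad2deg(o1 - o0)) < 2.0

    def test_circular_peaks_give_zero_ellipticity(self):
        assert bvcsr.ellipticity(bvcsr.sac(hex_pattern())) < 0.05

    def test_axis_ratio_closed_form(self):
        """Peaks on an ellipse with b/a = 0.8 give eccentricity 0.6."""
        ang = np.linspace(0, 2 * np.pi, 6, endpoint=False) + 0.3
        pts = np.column_stack([10 * np.cos(ang), 8 * np.sin(ang)])
        a, b = _fit_centered_ellipse(pts)
        ecc = math.sqrt(1 - (b / a) ** 2)
        assert ecc == pytest.approx(0.6, abs=1e-6)

    def test_fit_matches_independent_oracle_on_noisy_peaks(self):
        from skimage.measure import EllipseModel

        rng = np.random.default_rng(0)
        ang = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pts = np.column_stack([12 * np.cos(ang), 9 * np.sin(ang)])
        pts += rng.normal(0, 0.05, pts.shape)
        a, b = _fit_centered_ellipse(pts)
        em = EllipseModel.from_estimate(pts)
        assert em
        ea, eb = sorted(em.axis_lengths, reverse=True)
        assert a == pytest.approx(ea, rel=0.01)
        assert b == pytest.approx(eb, rel=0.01)

    def test_ellipticity_monotone_in_stretch(self):
        from scipy import ndimage

        base = hex_pattern()
        eccs = []
        for k in (1.0, 1.15, 1.3):
            v = ndimage.zoom(base.values, (1, k), order=1)[:, :60]
            m = bvcsr.RateMap(values=v, mask=np.ones_like(v, bool),
                              bin_size=0.02, origin=bvcsr.Point(0, 0))
            eccs.append(bvcsr.ellipticity(bvcsr.sac(m)))
        assert eccs[0] < eccs[1] < eccs[2]


class TestPeakCv:
    def _two_bump(self, peaks):
        vals = np.zeros((40, 40))
        for k, p in enumerate(peaks):
            r, c = 10 + 20 * (k % 2), 10 + 20 * (k // 2)
            vals[r - 2 : r + 3, c - 2 : c + 3] = p * 0.6
            vals[r, c] = p
        return bvcsr.RateMap(values=vals / max(peaks), mask=np.ones((40, 40), bool),
                             bin_size=0.02, origin=bvcsr.Point(0, 0))

    def test_equal_peaks_give_zero(self):
        assert bvcsr.peak_cv(self._two_bump([1.0, 1.0])) == pytest.approx(0.0)

    def test_hand_computed_sample_sd_convention(self):
        # peaks {1, 3}: sample SD = sqrt(2), mean = 2 -> CV = sqrt(2)/2
        # (a low field threshold keeps the weaker field in the count)
        cv = bvcsr.peak_cv(self._two_bump([1.0, 3.0]), field_threshold=0.3)
        assert cv == pytest.approx(math.sqrt(2) / 2)

    def test_matches_direct_formula_on_random_sets(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            peaks = rng.uniform(0.6, 1.0, 4)
            peaks[rng.integers(4)] = 1.0  # ensure max is a field peak
            got = bvcsr.peak_cv(self._two_bump(list(peaks)))
            # direct formula on peaks above 50% of max
            kept = peaks[peaks > 0.5 * peaks.max()] / peaks.max()
            expected = kept.std(ddof=1) / kept.mean()
            assert got == pytest.approx(expected, rel=1e-6)

    def test_single_field_undefined(self):
        assert np.isnan(bvcsr.peak_cv(self._two_bump([1.0, 0.2])))


class TestShuffledThreshold:
    def test_reproducible_across_seeds_within_mc_error(self, small_fmap, small_learned):
        _, sm = small_learned
        modes = bvcsr.sr_eigenmodes(sm, small_fmap)
        t1 = bvcsr.shuffled_gridness_threshold(modes, small_fmap, n_shuffles=120, seed=1)
        t2 = bvcsr.shuffled_gridness_threshold(modes, small_fmap, n_shuffles=120, seed=2)
        assert abs(t1 - t2) < 0.2

    def test_ideal_hexagon_exceeds_its_shuffle_threshold(self, small_fmap):
        """A map with genuine hexagonal structure beats the null built by
        permuting its own generating weights."""
        rng = np.random.default_rng(0)
        # build a weight vector whose feature projection is quasi-periodic
        F = small_fmap.matrix()
        target = hex_pattern(n=50, scale=0.35).values[small_fmap.mask]
        v, *_ = np.linalg.lstsq(F, target, rcond=None)
        mode = bvcsr.EigenMode(vector=v / np.linalg.norm(v), eigenvalue=1.0, index=0)
        gm = bvcsr.grid_map(mode, small_fmap)
        g = bvcsr.gridness(bvcsr.sac(gm))
        thr = bvcsr.shuffled_gridness_threshold([mode], small_fmap,
                                                n_shuffles=100, seed=4)
        assert g > thr

    def test_requires_enough_shuffles(self, small_fmap, small_learned):
        _, sm = small_learned
        modes = bvcsr.sr_eigenmodes(sm, small_fmap)
        with pytest.raises(ValueError):
            bvcsr.shuffled_gridness_threshold(modes, small_fmap, n_shuffles=10)


class TestKlUniform:
    def test_uniform_counts_give_zero(self):
        ori = np.tile(np.linspace(0, np.pi / 3, 20, endpoint=False) + 0.01, 5)
        assert bvcsr.kl_uniform(ori) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_distribution_gives_log_nbins(self):
        assert bvcsr.kl_uniform([0.02] * 50) == pytest.approx(math.log(20))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_nonnegative_and_matches_direct_sum(self, seed):
        rng = np.random.default_rng(seed)
        ori = rng.uniform(0, np.pi / 3, rng.integers(5, 200))
        got = bvcsr.kl_uniform(ori, n_bins=12)
        counts, _ = np.histogram(ori, bins=12, range=(0, np.pi / 3))
        p = counts / counts.sum()
        expected = sum(pi * math.log(pi / (1 / 12)) for pi in p if pi > 0)
        assert got == pytest.approx(expected)
        assert got >= 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bvcsr.kl_uniform([])
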