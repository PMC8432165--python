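import numpy as np
import pytest

import bvcsr


def bump_map(centers, shape=(50, 50), radius=3, peaks=None, bin_size=0.02):
    vals = np.zeros(shape)
    peaks = peaks or [1.0] * len(centers)
    for (r, c), p in zip(centers, peaks):
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        d2 = (rr - r) ** 2 + (cc - c) ** 2
        vals = np.maximum(vals, p * np.exp(-d2 / (2 * radius**2)) * (d2 < (3 * radius) ** 2))
    return bvcsr.RateMap(values=vals, mask=np.ones(shape, bool), bin_size=bin_size,
                         origin=bvcsr.Point(0.0, 0.0))


def flood_fill_count(values, min_bins):
    """Independent labelling oracle: BFS flood fill, 4-connected."""
    active = values > 0
    seen = np.zeros_like(active)
    count = 0
    for r0 in range(active.shape[0]):
        for c0 in range(active.shape[1]):
            if active[r0, c0] and not seen[r0, c0]:
                stack, size = [(r0, c0)], 0
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    size += 1
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < active.shape[0] and 0 <= cc < active.shape[1]
                                and active[rr, cc] and not seen[rr, cc]):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
                if size >= min_bins:
                    count += 1
    return count


class TestDetectFields:
    def test_all_zero_map_gives_no_fields(self):
        m = bump_map([])
        assert bvcsr.detect_fields(m) == []

    def test_two_bumps_found_with_centroids(self):
        m = bump_map([(10, 10), (35, 40)])
        fields = bvcsr.detect_fields(m)
        assert len(fields) == 2
        cents = sorted((f.centroid.x, f.centroid.y) for f in fields)
        assert cents[0][0] == pytest.approx((10 + 0.5) * 0.02, abs=0.01)
        assert cents[1][0] == pytest.approx((40 + 0.5) * 0.02, abs=0.01)

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = (rng.random((30, 30)) > 0.7) * rng.random((30, 30))
            m = bvcsr.RateMap(values=vals, mask=np.ones((30, 30), bool),
                              bin_size=0.02, origin=bvcsr.Point(0, 0))
            got = len(bvcsr.detect_fields(m, min_area=2 * 0.02**2))
            assert got == flood_fill_count(vals, 2)

    def test_invariant_to_positive_rescale(self):
        m = bump_map([(10, 10), (35, 40)])
        m2 = bvcsr.RateMap(values=7.3 * m.values, mask=m.mask,
                           bin_size=m.bin_size, origin=m.origin)
        a = [(f.n_bins, f.area) for f in bvcsr.detect_fields(m)]
        b = [(f.n_bins, f.area) for f in bvcsr.detect_fields(m2)]
        assert a == b

    def test_min_area_filters_speckle(self):
        vals = np.zeros((50, 50))
        vals[5, 5] = 1.0  # single-bin speckle
        vals[20:26, 20:26] = 0.8
        m = bvcsr.RateMap(values=vals, mask=np.ones((50, 50), bool),
                          bin_size=0.02, origin=bvcsr.Point(0, 0))
        assert len(bvcsr.detect_fields(m)) == 1


class TestBarrierDuplication:
    BARRIER = bvcsr.Segment(bvcsr.Point(0.5, 0.0), bvcsr.Point(0.5, 0.5))

    def test_identical_maps_not_duplicated(self):
        m = bump_map([(10, 10)])
        rec = bvcsr.barrier_duplication(m, m, self.BARRIER)
        assert not rec.duplicated

    def test_straddling_bumps_duplicated(self):
        before = bump_map([(10, 10)])
        after = bump_map([(10, 10), (10, 40)])  # one on each side of x=0.5
        rec = bvcsr.barrier_duplication(before, after, self.BARRIER)
        assert rec.duplicated
        assert rec.fields_before == 1 and rec.fields_after_insertion == 2

    def test_extra_field_on_same_side_not_duplication(self):
        before = bump_map([(10, 10)])
        after = bump_map([(10, 10), (40, 15)])  # both west of the barrier
        assert not bvcsr.barrier_duplication(before, after, self.BARRIER).duplicated

    def test_fields_outside_barrier_strip_unassigned(self):
        # barrier spans y in [0, 0.5]; bumps at y = 0.8 are outside its strip
        before = bump_map([(40, 18)])
        after = bump_map([(40, 18), (40, 32)])
        assert not bvcsr.barrier_duplication(before, after, self.BARRIER).duplicated

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bvcsr.barrier_duplication(bump_map([], shape=(50, 50)),
                                      bump_map([], shape=(40, 40)), self.BARRIER)


class TestFieldSizeComparison:
    def test_identical_environments_correlate_perfectly(self):
        maps = [bump_map([(10, 10)], radius=2 + k) for k in range(5)]
        areas, corr = bvcsr.field_size_comparison({"a": maps, "b": maps})
        np.testing.assert_array_equal(areas["a"], areas["b"])
        assert corr[("a", "b")] == pytest.approx(1.0)

    def test_scaled_areas_keep_correlation(self):
        small = [bump_map([(20, 20)], radius=2 + k) for k in range(4)]
        big = [bump_map([(20, 20)], radius=2 + k, bin_size=0.04) for k in range(4)]
        areas, corr = bvcsr.field_size_comparison({"s": small, "b": big})
        assert corr[("s", "b")] == pytest.approx(1.0, abs=0.01)
        ratio = areas["b"] / areas["s"]
        np.testing.assert_allclose(ratio, 4.0, rtol=0.01)


class TestArmCorrelation:
    def _hairpin(self):
        return bvcsr.build_environment("hairpin", bin_size=0.05)

    def test_masks_partition_channels(self):
        env = self._hairpin()
        masks = bvcsr.hairpin_arm_masks(env)
        assert len(masks) == 8
        combined = np.zeros_like(masks[0], dtype=int)
        for m in masks:
            combined += m
        assert combined.max() == 1  # disjoint

    def test_identical_pattern_gives_all_ones(self):
        env = self._hairpin()
        masks = bvcsr.hairpin_arm_masks(env)
        ny, nx = env.grid_shape
        gy = np.tile(np.sin(np.linspace(0, 6 * np.pi, ny))[:, None] ** 2, (1, nx))
        # make the pattern symmetric under the alternate-arm vertical flip
        gy = np.minimum(gy, gy[::-1, :])
        m = bvcsr.RateMap(values=gy, mask=env.bin_mask(), bin_size=0.05,
                          origin=env.origin)
        C = bvcsr.arm_correlation_matrix(m, masks)
        ok = np.isfinite(C)
        assert np.all(C[ok] > 0.99)

    def test_alternating_pattern_gives_checkerboard(self):
        env = self._hairpin()
        masks = bvcsr.hairpin_arm_masks(env)
        ny, nx = env.grid_shape
        vals = np.zeros((ny, nx))
        ys = np.linspace(0, 1, ny)
        pat_a = np.sin(4 * np.pi * ys) ** 2
        pat_b = np.exp(-((ys - 0.3) ** 2) / 0.02)  # structurally different
        for k, mask in enumerate(masks):
            cols = np.unique(np.nonzero(mask)[1])
            pattern = pat_a if k % 2 == 0 else pat_b
            vals[:, cols] = pattern[:, None]
        m = bvcsr.RateMap(values=vals, mask=env.bin_mask(), bin_size=0.05,
                          origin=env.origin)
        C = bvcsr.arm_correlation_matrix(m, masks, align_alternating=False)
        same = [C[i, j] for i in range(8) for j in range(i + 1, 8) if (i - j) % 2 == 0]
        diff = [C[i, j] for i in range(8) for j in range(i + 1, 8) if (i - j) % 2 == 1]
        assert np.nanmean(same) > np.nanmean(diff)

    def test_symmetric_unit_diagonal(self, small_fmap, small_learned):
        env = self._hairpin()
        masks = bvcsr.hairpin_arm_masks(env)
        rng = np.random.default_rng(2)
        vals = rng.random(env.grid_shape)
        m = bvcsr.RateMap(values=vals, mask=env.bin_mask(), bin_size=0.05,
                          origin=env.origin)
        C = bvcsr.arm_correlation_matrix(m, masks)
        np.testing.assert_allclose(np.diag(C), 1.0)
        ok = np.isfinite(C)
        np.testing.assert_allclose(C[ok], C.T[ok], atol=1e-12)
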