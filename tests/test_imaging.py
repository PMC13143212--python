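"""Colocalization, cluster, particle and NFAT quantification rules."""

import numpy as np
import pytest

import spinemetrics as sm
from spinemetrics.imaging import boundary_chain_perimeter, circularity
from spinemetrics.images import BinaryMask, GrayscaleImage

PX = 0.1


class TestThresholdMeanPlusKsd:
    def test_constant_image_empty_mask(self):
        mask, thr = sm.threshold_mean_plus_ksd(
            GrayscaleImage(np.full((8, 8), 5.0), PX))
        assert mask.area_px == 0
        assert thr == pytest.approx(5.0)

    def test_single_outlier_survives(self):
        v = np.zeros(100)
        v[37] = 100.0
        mask, thr = sm.threshold_mean_plus_ksd(
            GrayscaleImage(v.reshape(10, 10), PX), k=2)
        assert thr == pytest.approx(1 + 2 * np.sqrt(99**2 / 100 + 99 * 1 / 100))
        assert mask.area_px == 1 and mask.values.flat[37]

    def test_k_zero_is_above_mean(self):
        v = np.arange(16.0).reshape(4, 4)
        mask, thr = sm.threshold_mean_plus_ksd(GrayscaleImage(v, PX), k=0)
        assert thr == pytest.approx(v.mean())
        assert np.array_equal(mask.values, v > v.mean())


class TestManders:
    def _pair(self, a, b):
        ia = GrayscaleImage(np.asarray(a, float), PX)
        ib = GrayscaleImage(np.asarray(b, float), PX)
        return ia, ib, BinaryMask(ia.values > 0, PX), BinaryMask(ib.values > 0, PX)

    def test_identical_channels_give_one(self):
        ia, ib, ma, mb = self._pair([[1, 2], [3, 0]], [[1, 2], [3, 0]])
        assert sm.manders(ia, ib, ma, mb) == (1.0, 1.0)

    def test_disjoint_masks_give_zero(self):
        ia, ib, ma, mb = self._pair([[5, 0], [0, 0]], [[0, 0], [0, 5]])
        assert sm.manders(ia, ib, ma, mb) == (0.0, 0.0)

    def test_matches_brute_force_on_4x4_fixture(self):
        rng = np.random.default_rng(0)
        a = rng.random((4, 4)) * 10
        b = rng.random((4, 4)) * 10
        ma, mb = a > 5, b > 5
        m1, m2 = sm.manders(GrayscaleImage(a, PX), GrayscaleImage(b, PX),
                            BinaryMask(ma, PX), BinaryMask(mb, PX))
        # per-pixel summation oracle
        s1 = sum(a[i, j] for i in range(4) for j in range(4)
                 if ma[i, j] and mb[i, j])
        s2 = sum(b[i, j] for i in range(4) for j in range(4)
                 if ma[i, j] and mb[i, j])
        assert m1 == pytest.approx(s1 / a[ma].sum())
        assert m2 == pytest.approx(s2 / b[mb].sum())

    def test_bounds_and_swap_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b = rng.random((2, 8, 8))
            ma, mb = a > 0.4, b > 0.4
            m1, m2 = sm.manders(GrayscaleImage(a, PX), GrayscaleImage(b, PX),
                                BinaryMask(ma, PX), BinaryMask(mb, PX))
            assert 0 <= m1 <= 1 and 0 <= m2 <= 1
            swapped = sm.manders(GrayscaleImage(b, PX), GrayscaleImage(a, PX),
                                 BinaryMask(mb, PX), BinaryMask(ma, PX))
            assert swapped == (m2, m1)

    def test_empty_mask_raises(self):
        ia, ib, ma, _ = self._pair([[1, 1], [1, 1]], [[0, 0], [0, 0]])
        with pytest.raises(ValueError):
            sm.manders(ia, ib, ma, BinaryMask(np.zeros((2, 2), bool), PX))


class TestRollingBall:
    def test_constant_image_goes_to_zero(self):
        out = sm.rolling_ball_subtract(GrayscaleImage(np.full((32, 32), 7.0), PX),
                                       radius_px=5)
        assert np.allclose(out.values, 0.0)

    def test_small_bright_dot_preserved(self):
        v = np.full((64, 64), 10.0)
        v[30:33, 30:33] += 50.0
        out = sm.rolling_ball_subtract(GrayscaleImage(v, PX), radius_px=15)
        assert out.values[31, 31] == pytest.approx(50.0, rel=0.05)

    def test_output_never_negative(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            v = rng.random((24, 24)) * 100
            out = sm.rolling_ball_subtract(GrayscaleImage(v, PX), radius_px=4)
            assert (out.values >= 0).all()

    def test_radius_exceeding_image_raises(self):
        with pytest.raises(ValueError):
            sm.rolling_ball_subtract(GrayscaleImage(np.ones((8, 8)), PX), 100)


class TestClusterStats:
    def test_two_squares_arithmetic(self):
        v = np.zeros((20, 20))
        v[2:4, 2:4] = 10.0       # 4 px
        v[10:13, 10:13] = 10.0   # 9 px
        mask = BinaryMask(v > 0, PX)
        st = sm.cluster_stats(GrayscaleImage(v, PX), mask)
        assert st.n_clusters == 2
        assert st.mean_cluster_area_um2 == pytest.approx(0.065)
        assert st.integrated_density == pytest.approx(130.0)
        assert st.hist_counts.sum() == 2

    def test_empty_mask_zeros(self):
        st = sm.cluster_stats(GrayscaleImage(np.ones((8, 8)), PX),
                              BinaryMask(np.zeros((8, 8), bool), PX))
        assert st.n_clusters == 0
        assert st.mean_cluster_area_um2 == 0.0
        assert st.hist_counts.sum() == 0

    def test_integrated_density_equals_masked_sum(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            v = rng.random((16, 16)) * 50
            mask = BinaryMask(v > 25, PX)
            st = sm.cluster_stats(GrayscaleImage(v, PX), mask)
            assert st.integrated_density == pytest.approx(v[mask.values].sum())


class TestParticleFilter:
    def _labeled_disk(self, r=5):
        yy, xx = np.mgrid[0:24, 0:24]
        disk = ((yy - 12) ** 2 + (xx - 12) ** 2 <= r**2).astype(np.int64)
        from spinemetrics.images import LabelMap
        return LabelMap(disk, pixel_size=PX)

    def test_digital_disk_is_circular_and_retained(self):
        lm = self._labeled_disk()
        assert 0.8 <= circularity(lm.labels == 1) <= 1.0
        spec = sm.ParticleFilterSpec(0.1, 5.0, 0.1, 1.0)
        assert 1 in sm.particle_filter(lm, spec)

    def test_single_pixel_boundary_area_inclusive(self):
        from spinemetrics.images import LabelMap
        labels = np.zeros((5, 5), dtype=np.int64)
        labels[2, 2] = 1
        spec = sm.ParticleFilterSpec(min_area_um2=0.01, max_area_um2=5.0,
                                     min_circularity=0.1, max_circularity=1.0)
        surviving = sm.particle_filter(LabelMap(labels, pixel_size=PX), spec)
        assert surviving == {1: pytest.approx(0.01)}

    def test_long_line_rejected_by_circularity(self):
        from spinemetrics.images import LabelMap
        labels = np.zeros((4, 40), dtype=np.int64)
        labels[2, 2:38] = 1
        # chain-length oracle: 36-px line, perimeter ~70, circularity << 0.1
        assert circularity(labels == 1) < 0.1
        spec = sm.ParticleFilterSpec(0.0, 10.0, 0.1, 1.0)
        assert sm.particle_filter(LabelMap(labels, pixel_size=PX), spec) == {}

    def test_unbounded_spec_is_identity(self):
        rng = np.random.default_rng(3)
        from spinemetrics.segmentation import label_clusters
        m = rng.random((20, 20)) < 0.3
        lm = label_clusters(BinaryMask(m, PX), 8)
        spec = sm.ParticleFilterSpec(0.0, np.inf, 0.0, 1.0)
        assert set(sm.particle_filter(lm, spec)) == set(lm.island_sizes)

    def test_crofton_perimeter_close_to_chain(self):
        lm = self._labeled_disk(r=7)
        chain = circularity(lm.labels == 1, method="chain")
        crofton = circularity(lm.labels == 1, method="crofton")
        assert chain == pytest.approx(crofton, abs=0.25)


class TestNfatRatio:
    def _compartments(self):
        nuc = np.zeros((10, 10), dtype=bool)
        cyt = np.zeros((10, 10), dtype=bool)
        nuc[2:5, 2:5] = True
        cyt[6:9, 6:9] = True
        return BinaryMask(nuc, PX), BinaryMask(cyt, PX)

    def test_twofold_nuclear_enrichment(self):
        nuc, cyt = self._compartments()
        v = np.ones((10, 10))
        v[nuc.values] = 2.0
        assert sm.nfat_ratio(GrayscaleImage(v, PX), nuc, cyt) == pytest.approx(2.0)

    def test_uniform_image_unity(self):
        nuc, cyt = self._compartments()
        img = GrayscaleImage(np.full((10, 10), 3.3), PX)
        assert sm.nfat_ratio(img, nuc, cyt) == pytest.approx(1.0)

    def test_matches_masked_mean_oracle(self):
        rng = np.random.default_rng(4)
        nuc, cyt = self._compartments()
        v = rng.random((10, 10)) * 100
        got = sm.nfat_ratio(GrayscaleImage(v, PX), nuc, cyt)
        assert got == pytest.approx(v[nuc.values].mean() / v[cyt.values].mean())

    def test_overlap_or_empty_raises(self):
        nuc, cyt = self._compartments()
        img = GrayscaleImage(np.ones((10, 10)), PX)
        with pytest.raises(ValueError):
            sm.nfat_ratio(img, nuc, nuc)
        with pytest.raises(ValueError):
            sm.nfat_ratio(img, BinaryMask(np.zeros((10, 10), bool), PX), cyt)
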