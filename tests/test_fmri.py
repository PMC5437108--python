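import numpy as np
import pytest

from netbeh import fmri as fm
from netbeh.errors import DegenerateInputError, InsufficientDataError

AFFINE3 = np.diag([3.0, 3.0, 3.0, 1.0])


def _bold(data, tr=2.0, affine=AFFINE3):
    return fm.BoldSeries(data=np.asarray(data, dtype=float), tr_s=tr, affine=affine)


def _noise_bold(rng, shape=(4, 4, 3, 200), tr=2.0):
    return _bold(rng.standard_normal(shape), tr=tr)


class TestDiscard:
    def test_paper_count(self, rng):
        out = fm.discard_initial_volumes(_noise_bold(rng), k=10)
        assert out.n_volumes == 190

    def test_identity(self, rng):
        b = _noise_bold(rng, (2, 2, 2, 20))
        out = fm.discard_initial_volumes(b, k=0)
        np.testing.assert_array_equal(out.data, b.data)

    def test_boundary_raises(self, rng):
        b = _noise_bold(rng, (2, 2, 2, 10))
        with pytest.raises(InsufficientDataError):
            fm.discard_initial_volumes(b, k=10)


class TestMotionExclude:
    def test_zero_kept(self):
        assert fm.motion_exclude([0, 0, 0, 0, 0, 0])

    def test_over_limit_excluded(self):
        assert not fm.motion_exclude([2.6, 0, 0, 0, 0, 0])
        assert not fm.motion_exclude([0, 0, 0, 0, 2.6, 0])

    def test_boundary_kept(self):
        assert fm.motion_exclude([2.5, 2.5, 2.5, 2.5, 2.5, 2.5])


class TestSmooth:
    def test_constant_unchanged(self):
        vol = np.full((8, 8, 8), 3.5)
        out = fm.gaussian_smooth(vol, 6.0, [3, 3, 3])
        np.testing.assert_allclose(out, vol, atol=1e-10)

    def test_zero_fwhm_identity(self, rng):
        vol = rng.standard_normal((6, 6, 6))
        np.testing.assert_array_equal(fm.gaussian_smooth(vol, 0.0, [3, 3, 3]), vol)

    def test_impulse_fwhm(self):
        vol = np.zeros((31, 31, 31))
        vol[15, 15, 15] = 1.0
        out = fm.gaussian_smooth(vol, 6.0, [3, 3, 3])
        profile = out[:, 15, 15]
        half = profile.max() / 2
        # interpolate the half-max crossings along x (in mm)
        x = np.arange(31) * 3.0
        above = profile >= half
        lo, hi = np.nonzero(above)[0][[0, -1]]
        def cross(i, j):
            return x[i] + (half - profile[i]) * (x[j] - x[i]) / (profile[j] - profile[i])
        width = cross(hi, hi + 1) - cross(lo, lo - 1)
        assert width == pytest.approx(6.0, rel=0.05)


class TestDetrendBandpass:
    def test_linear_ramp_removed(self):
        t = np.arange(200, dtype=float)
        data = np.tile(5 + 0.3 * t, (2, 2, 2, 1))
        out = fm.detrend_bandpass(_bold(data))
        assert np.abs(out.data).max() < 1e-8 * (0.3 * 200)

    @pytest.mark.parametrize("freq,retained", [(0.05, True), (0.20, False)])
    def test_band_selectivity(self, freq, retained):
        t = np.arange(200) * 2.0
        sig = np.sin(2 * np.pi * freq * t)
        data = np.tile(sig, (2, 2, 2, 1))
        out = fm.detrend_bandpass(_bold(data))
        ratio = np.sum(out.data[0, 0, 0] ** 2) / np.sum(sig**2)
        if retained:
            assert ratio > 0.95
        else:
            assert ratio < 0.05

    def test_invalid_band(self, rng):
        with pytest.raises(ValueError):
            fm.detrend_bandpass(_noise_bold(rng), 0.01, 0.30)


class TestNuisance:
    def test_own_series_zero(self, rng):
        b = _noise_bold(rng, (2, 2, 1, 50))
        conf = b.data[0, 0, 0][:, None]
        out = fm.nuisance_regress(b, conf)
        assert np.abs(out.data[0, 0, 0]).max() < 1e-10

    def test_empty_confounds_center(self, rng):
        b = _noise_bold(rng, (2, 2, 1, 50))
        out = fm.nuisance_regress(b, None)
        np.testing.assert_allclose(
            out.data, b.data - b.data.mean(axis=-1, keepdims=True), atol=1e-12
        )

    def test_orthogonality(self, rng):
        b = _noise_bold(rng, (3, 3, 2, 80))
        conf = rng.standard_normal((80, 4))
        out = fm.nuisance_regress(b, conf)
        dots = np.einsum("xyzt,tq->xyzq", out.data, conf)
        assert np.abs(dots).max() < 1e-8


class TestMfalff:
    def test_mask_mean_is_one(self, rng):
        b = _noise_bold(rng, (4, 4, 3, 100))
        mask = np.zeros((4, 4, 3), dtype=bool)
        mask[1:3, 1:3, :] = True
        out = fm.mfalff_map(b, mask)
        assert out[mask].mean() == pytest.approx(1.0, abs=1e-12)

    def test_monotonicity(self):
        t = np.arange(200) * 2.0
        inband = np.sin(2 * np.pi * 0.05 * t)
        outband = np.sin(2 * np.pi * 0.05 * t) + np.sin(2 * np.pi * 0.2 * t)
        data = np.zeros((2, 1, 1, 200))
        data[0, 0, 0] = inband
        data[1, 0, 0] = outband
        mask = np.ones((2, 1, 1), dtype=bool)
        out = fm.mfalff_map(_bold(data), mask)
        assert out[0, 0, 0] > out[1, 0, 0]

    def test_against_direct_fft(self, rng):
        # independent oracle: per-voxel in-band amplitude fraction via FFT
        t = np.arange(128) * 2.0
        sig_a = np.sin(2 * np.pi * 0.05 * t) + 0.05 * rng.standard_normal(128)
        sig_b = np.sin(2 * np.pi * 0.20 * t) + 0.05 * rng.standard_normal(128)
        data = np.zeros((2, 1, 1, 128))
        data[0, 0, 0] = sig_a
        data[1, 0, 0] = sig_b
        mask = np.ones((2, 1, 1), dtype=bool)
        out = fm.mfalff_map(_bold(data), mask)

        freqs = np.fft.rfftfreq(128, d=2.0)
        inband = (freqs >= 0.01) & (freqs <= 0.10)

        def frac(sig):
            amp = np.abs(np.fft.rfft(sig))
            return amp[inband].sum() / amp[freqs > 0].sum()

        fa, fb = frac(sig_a), frac(sig_b)
        norm = np.mean([fa, fb])
        assert out[0, 0, 0] == pytest.approx(fa / norm, abs=1e-10)
        assert out[1, 0, 0] == pytest.approx(fb / norm, abs=1e-10)


class TestFcDegree:
    def test_duplicate_series(self, rng):
        data = np.zeros((2, 1, 1, 30))
        s = rng.standard_normal(30)
        data[0, 0, 0] = s
        data[1, 0, 0] = s
        r, valid = fm.fc_matrix(_bold(data), np.ones((2, 1, 1), bool))
        assert r[0, 1] == pytest.approx(1.0)
        assert valid.all()

    def test_hand_value(self):
        data = np.zeros((2, 1, 1, 3))
        data[0, 0, 0] = [1, 2, 3]
        data[1, 0, 0] = [1, 3, 2]
        r, _ = fm.fc_matrix(_bold(data), np.ones((2, 1, 1), bool))
        assert r[0, 1] == pytest.approx(0.5)

    def test_symmetry(self, rng):
        b = _noise_bold(rng, (3, 3, 2, 40))
        r, _ = fm.fc_matrix(b, np.ones((3, 3, 2), bool))
        assert np.nanmax(np.abs(r - r.T)) < 1e-12

    def test_constant_voxel_flagged(self, rng):
        data = rng.standard_normal((2, 1, 1, 30))
        data[1, 0, 0] = 4.2
        r, valid = fm.fc_matrix(_bold(data), np.ones((2, 1, 1), bool))
        assert not valid[1]
        assert np.isnan(r[0, 1])
        deg = fm.degree_map(r, 0.1)
        assert deg[0] == 0  # NaN edge never counted

    def test_identical_series_full_degree(self, rng):
        s = rng.standard_normal(30)
        data = np.broadcast_to(s, (3, 2, 2, 30)).copy()
        r, _ = fm.fc_matrix(_bold(data), np.ones((3, 2, 2), bool))
        deg = fm.degree_map(r, 0.1)
        assert (deg == 11).all()

    def test_threshold_one_gives_zero(self, rng):
        b = _noise_bold(rng, (3, 3, 1, 50))
        r, _ = fm.fc_matrix(b, np.ones((3, 3, 1), bool))
        assert (fm.degree_map(r, 1.0) == 0).all()

    def test_toy_counts(self):
        r = np.array(
            [
                [1.0, 0.5, 0.05, 0.2],
                [0.5, 1.0, 0.2, 0.2],
                [0.05, 0.2, 1.0, 0.2],
                [0.2, 0.2, 0.2, 1.0],
            ]
        )
        deg = fm.degree_map(r, 0.10)
        np.testing.assert_array_equal(deg, [2, 3, 2, 3])

    def test_brute_force_equivalence(self, rng):
        shape = (4, 4, 4)
        b = _noise_bold(rng, (*shape, 25))
        mask = rng.random(shape) > 0.3
        r, valid = fm.fc_matrix(b, mask)
        deg = fm.degree_map(r, 0.10)
        series = b.data[mask]
        n = series.shape[0]
        expected = np.zeros(n)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                rij = np.corrcoef(series[i], series[j])[0, 1]
                if rij > 0.10:
                    expected[i] += 1
        np.testing.assert_array_equal(deg, expected)

    def test_degree_affine_invariance(self, rng):
        shape = (3, 3, 2)
        data = rng.standard_normal((*shape, 40))
        mask = np.ones(shape, bool)
        r1, _ = fm.fc_matrix(_bold(data), mask)
        scales = rng.uniform(0.5, 2.0, shape)[..., None]
        offsets = rng.normal(0, 3, shape)[..., None]
        r2, _ = fm.fc_matrix(_bold(data * scales + offsets), mask)
        np.testing.assert_array_equal(
            fm.degree_map(r1, 0.1), fm.degree_map(r2, 0.1)
        )


class TestZStandardize:
    def test_moments(self, rng):
        data = rng.standard_normal((5, 5, 3))
        mask = rng.random((5, 5, 3)) > 0.4
        out = fm.z_standardize(data, mask)
        assert out[mask].mean() == pytest.approx(0.0, abs=1e-10)
        assert out[mask].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_affine_invariance(self, rng):
        data = rng.standard_normal((4, 4, 2))
        mask = np.ones((4, 4, 2), bool)
        out1 = fm.z_standardize(data, mask)
        out2 = fm.z_standardize(3.0 * data - 7.0, mask)
        np.testing.assert_allclose(out1, out2, atol=1e-10)

    def test_hand_values(self):
        data = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
        out = fm.z_standardize(data, np.ones((4, 1, 1), bool))
        np.testing.assert_allclose(
            out.ravel(), [-1.162, -0.387, 0.387, 1.162], atol=1e-3
        )

    def test_constant_raises(self):
        with pytest.raises(DegenerateInputError):
            fm.z_standardize(np.ones((3, 1, 1)), np.ones((3, 1, 1), bool))


class TestSeedFromPeak:
    def test_interior_seven_voxels(self):
        stat = np.zeros((9, 9, 9))
        stat[4, 4, 4] = 5.0
        seed = fm.seed_from_peak(stat, np.ones((9, 9, 9), bool), AFFINE3, 3.0)
        assert len(seed.voxels) == 7  # center + 6 face neighbors at 3 mm

    def test_corner_four_voxels(self):
        stat = np.zeros((9, 9, 9))
        stat[0, 0, 0] = 5.0
        seed = fm.seed_from_peak(stat, np.ones((9, 9, 9), bool), AFFINE3, 3.0)
        assert len(seed.voxels) == 4

    def test_mask_restricts_to_peak(self):
        stat = np.zeros((9, 9, 9))
        stat[4, 4, 4] = 5.0
        mask = np.zeros((9, 9, 9), bool)
        mask[4, 4, 4] = True
        seed = fm.seed_from_peak(stat, mask, AFFINE3, 3.0)
        assert seed.voxels == ((4, 4, 4),)


class TestSeedFcZmap:
    def test_saturated_voxel_excluded(self, rng):
        data = np.zeros((3, 1, 1, 40))
        s = rng.standard_normal(40)
        data[0, 0, 0] = s
        data[1, 0, 0] = s  # equals the seed mean -> |r| = 1
        data[2, 0, 0] = rng.standard_normal(40)
        seed = fm.Seed(center_mm=(0, 0, 0), radius_mm=3.0, voxels=((0, 0, 0),))
        z = fm.seed_fc_zmap(_bold(data), seed, np.ones((3, 1, 1), bool))
        assert np.isnan(z[0, 0, 0])  # seed voxel excluded
        assert np.isnan(z[1, 0, 0])  # saturated flagged
        assert np.isfinite(z[2, 0, 0])

    def test_null_z_scale(self, rng):
        shape = (8, 8, 4)
        t = 120
        b = _noise_bold(rng, (*shape, t))
        seed = fm.Seed(center_mm=(0, 0, 0), radius_mm=3.0, voxels=((0, 0, 0),))
        z = fm.seed_fc_zmap(b, seed, np.ones(shape, bool))
        vals = z[np.isfinite(z)]
        frac = np.mean(np.abs(vals) < 3.0 / np.sqrt(t - 3))
        assert frac > 0.95


class TestMapBehaviorCorrelation:
    def test_perfect_voxel(self, rng):
        n = 10
        maps = rng.standard_normal((n, 3, 3, 1))
        scores = maps[:, 1, 1, 0].copy()
        rmap, df = fm.map_behavior_correlation(maps, scores, np.ones((3, 3, 1), bool))
        assert rmap[1, 1, 0] == pytest.approx(1.0)
        assert df == n - 2

    def test_null_calibration(self, rng):
        n = 20
        maps = rng.standard_normal((n, 12, 12, 6))
        scores = rng.standard_normal(n)
        mask = np.ones((12, 12, 6), bool)
        rmap, df = fm.map_behavior_correlation(maps, scores, mask)
        rcrit = fm.r_threshold_for_p(0.05, df)
        frac = np.mean(np.abs(rmap[mask]) > rcrit)
        assert 0.03 < frac < 0.07

    def test_partial_matches_stats(self, rng):
        from netbeh import stats as st

        n = 15
        maps = rng.standard_normal((n, 2, 2, 1))
        scores = rng.standard_normal(n)
        cov = rng.standard_normal((n, 2))
        rmap, df = fm.map_behavior_correlation(
            maps, scores, np.ones((2, 2, 1), bool), covariates=cov
        )
        expected = st.partial_r(maps[:, 0, 0, 0], scores, cov)
        assert rmap[0, 0, 0] == pytest.approx(expected.r, abs=1e-10)
        assert df == expected.df
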