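"""Xe histograms, Gaussian fits, normalization factors and error
propagation against independent oracles (Poisson statistics, bootstrap)."""

import math

import numpy as np
import pytest

from imcquant import (QuantRecord, fit_gaussian, normalization_factor,
                      normalize_quant, xe_histogram)
from imcquant.errors import DataError
from imcquant.normalization import Histogram, XeFit, factors_for_batch


def poisson_fit(lam, shape, seed, image_id=None):
    rng = np.random.default_rng(seed)
    arr = rng.poisson(lam, shape).astype(float)
    return fit_gaussian(xe_histogram(arr), image_id=image_id)


class TestHistogram:
    def test_constant_image_single_occupied_bin(self):
        h = xe_histogram(np.full(100, 50.0))
        assert h.n_pixels == 100
        assert np.count_nonzero(h.frequencies) == 1
        assert h.centers[h.frequencies > 0][0] == pytest.approx(50.0)

    def test_frequencies_conserve_pixel_count(self, rng):
        vals = rng.poisson(30, (64, 64)).astype(float)
        assert xe_histogram(vals).n_pixels == vals.size

    def test_poisson_sample_mean_near_lambda(self):
        rng = np.random.default_rng(11)
        arr = rng.poisson(100, (256, 256)).astype(float)
        mean, _ = xe_histogram(arr).sample_mean_sd()
        assert abs(mean - 100) < 3 * (math.sqrt(100) / 256)

    def test_too_few_pixels_rejected(self):
        with pytest.raises(DataError):
            xe_histogram(np.full(50, 5.0))

    def test_nan_pixels_excluded(self):
        arr = np.full(200, 40.0)
        arr[:50] = np.nan
        assert xe_histogram(arr).n_pixels == 150


class TestGaussianFit:
    def test_recovers_noiseless_gaussian(self):
        x = np.arange(20, 81)
        y = 100.0 * np.exp(-((x - 50.0) ** 2) / (2 * 5.0 ** 2))
        h = Histogram(np.concatenate([x - 0.5, [x[-1] + 0.5]]),
                      np.round(y).astype(np.int64))
        fit = fit_gaussian(h)
        assert not fit.fallback_used
        assert fit.mean == pytest.approx(50.0, abs=0.1)
        assert fit.sigma == pytest.approx(5.0, abs=0.1)

    def test_poisson_400_mean_within_one_percent(self):
        fit = poisson_fit(400, (256, 256), seed=21)
        assert not fit.fallback_used
        assert abs(fit.mean - 400) / 400 < 0.01
        assert abs(fit.sigma - 20.0) / 20.0 < 0.15

    def test_single_bin_falls_back_to_sample_stats(self):
        h = xe_histogram(np.full(100, 50.0))
        fit = fit_gaussian(h)
        assert fit.fallback_used
        assert fit.mean == pytest.approx(50.0)

    def test_stderr_scales_as_sigma_over_sqrt_n(self):
        fit = poisson_fit(400, (256, 256), seed=22)
        assert fit.mean_stderr == pytest.approx(fit.sigma / 256.0)


class TestNormalizationFactor:
    def test_reference_against_itself_is_exactly_one(self):
        fit = poisson_fit(400, (128, 128), seed=1, image_id="ref")
        assert normalization_factor(fit, fit).factor == 1.0

    def test_ratio_definition(self):
        h = xe_histogram(np.full(100, 1.0))
        a = XeFit(h, 100.0, 5.0, 1.0, True, False, 0.5, 100, "a")
        b = XeFit(h, 50.0, 5.0, 1.0, True, False, 0.5, 100, "b")
        assert normalization_factor(a, b).factor == pytest.approx(2.0)

    def test_factors_are_multiplicative(self):
        fits = [poisson_fit(lam, (128, 128), seed=s, image_id=i)
                for lam, s, i in ((300, 1, "A"), (400, 2, "B"), (500, 3, "C"))]
        f_ab = normalization_factor(fits[0], fits[1]).factor
        f_bc = normalization_factor(fits[1], fits[2]).factor
        f_ac = normalization_factor(fits[0], fits[2]).factor
        assert f_ac == pytest.approx(f_ab * f_bc)

    def test_reference_invariance_of_ratios(self):
        fits = [poisson_fit(lam, (128, 128), seed=s, image_id=i)
                for lam, s, i in ((300, 4, "A"), (400, 5, "B"), (500, 6, "C"))]
        fA = factors_for_batch(fits, reference_id="A")
        fC = factors_for_batch(fits, reference_id="C")
        # changing reference rescales all factors by a common constant
        r = np.array([x.factor for x in fA]) / np.array([x.factor for x in fC])
        np.testing.assert_allclose(r, r[0])


class TestNormalizeQuant:
    def _record(self, mean, sd, n=1000):
        return QuantRecord("img", "m", "g", "epithelium", "195Pt",
                           mean, sd, n)

    def _fit(self, mean, stderr, image_id):
        h = xe_histogram(np.full(100, 1.0))
        return XeFit(h, mean, stderr * 10, 1.0, True, False, stderr, 100,
                     image_id)

    def test_identity_factor_with_no_xe_error(self):
        ref = self._fit(400.0, 0.0, "ref")
        nf = normalization_factor(ref, ref)
        rec = self._record(200.0, 10.0)
        out = normalize_quant(rec, nf, ref)
        assert out.mean == pytest.approx(200.0)
        assert out.sd == pytest.approx(10.0)
        assert out.normalized

    def test_mean_divided_by_factor(self):
        ref = self._fit(200.0, 0.0, "ref")
        img = self._fit(400.0, 0.0, "img")
        out = normalize_quant(self._record(200.0, 1.0),
                              normalization_factor(img, ref), ref)
        assert out.mean == pytest.approx(100.0)

    def test_double_normalization_rejected(self):
        ref = self._fit(400.0, 0.0, "ref")
        nf = normalization_factor(ref, ref)
        out = normalize_quant(self._record(5.0, 1.0), nf, ref)
        with pytest.raises(DataError):
            normalize_quant(out, nf, ref)

    def test_propagated_se_matches_bootstrap(self):
        """First-order ratio propagation vs a 1000-draw pixel bootstrap."""
        rng = np.random.default_rng(33)
        region = rng.poisson(80, 4000).astype(float)
        xe_img = rng.poisson(380, 20000).astype(float)
        xe_ref = rng.poisson(420, 20000).astype(float)

        fit_i = fit_gaussian(xe_histogram(xe_img), image_id="img")
        fit_r = fit_gaussian(xe_histogram(xe_ref), image_id="ref")
        nf = normalization_factor(fit_i, fit_r)
        rec = QuantRecord("img", "m", "g", "epithelium", "195Pt",
                          float(region.mean()), float(region.std(ddof=1)),
                          region.size)
        out = normalize_quant(rec, nf, fit_r)

        boots = np.empty(1000)
        for b in range(1000):
            m = rng.choice(region, region.size).mean()
            xi = rng.choice(xe_img, xe_img.size).mean()
            xr = rng.choice(xe_ref, xe_ref.size).mean()
            boots[b] = m / (xi / xr)
        assert out.mean_se == pytest.approx(boots.std(ddof=1), rel=0.10)


class TestDriftCancellation:
    def test_drift_cancels_in_normalized_means(self, small_config, panel):
        """Two images differing only in drift agree after normalization."""
        from imcquant import (RegionMask, make_tissue_labels,
                              simulate_channels, region_channel_means)
        from imcquant.normalization import fit_xe

        truth0 = make_tissue_labels(small_config, seed=77)
        mask = RegionMask(truth0.label_map)     # same regions for both images
        results = []
        for i, (drift, iid) in enumerate(((1.0, "ref"), (1.8, "bright"))):
            t = type(truth0)(truth0.label_map.copy(), truth0.hypoxia_map.copy(),
                             truth0.nucleus_map.copy(),
                             truth0.nucleus_labels.copy(), group="cisplatin")
            img = simulate_channels(t, small_config, panel, seed=78 + i,
                                    drift_factor=drift)
            fit = fit_xe(img, image_id=iid)
            recs = [r for r in region_channel_means(img, mask, image_id=iid,
                                                    group="cisplatin")
                    if r.channel == "195Pt" and r.region == "stroma_collagen"]
            results.append((recs[0], fit))
        (rec_a, fit_a), (rec_b, fit_b) = results
        # un-normalized means differ by the drift ratio
        assert rec_b.mean / rec_a.mean == pytest.approx(1.8, rel=0.05)
        nf_a = normalization_factor(fit_a, fit_a)
        nf_b = normalization_factor(fit_b, fit_a)
        na = normalize_quant(rec_a, nf_a, fit_a)
        nb = normalize_quant(rec_b, nf_b, fit_a)
        tol = 3 * math.hypot(na.mean_se, nb.mean_se)
        assert abs(na.mean - nb.mean) < tol
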