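import numpy as np
import pytest

from persipet import (
    BinaryMask,
    DegenerateHistogramError,
    FitConfig,
    IntensityHistogram,
    ValidationError,
    Volume3D,
    bimodal_model,
    binarize_segmentation,
    build_histogram,
    derive_persi_reference,
    fit_bimodal,
    fwhm_from_sigma,
    gaussian_smooth,
    generate_subject,
    normalize_volume,
    select_reference_voxels,
)
from persipet.persi import FWHM_PER_SIGMA, BimodalFit


def _vol(data, voxel=2.0):
    return Volume3D(np.asarray(data, dtype=float), np.diag([voxel] * 3 + [1.0]))


def _hist_from_samples(samples, n_bins=128):
    """Histogram a 1D sample through the volume API."""
    n = len(samples)
    side = int(np.ceil(n ** (1 / 3)))
    data = np.zeros(side**3)
    data[:n] = samples
    mask = np.zeros(side**3, dtype=bool)
    mask[:n] = True
    return build_histogram(
        _vol(data.reshape(side, side, side)), BinaryMask(mask.reshape(side, side, side)), n_bins
    )


def mixture_samples(rng, n, mu_lo, sd_lo, mu_hi, sd_hi, w_hi):
    n_hi = int(round(w_hi * n))
    return np.concatenate(
        [rng.normal(mu_lo, sd_lo, n - n_hi), rng.normal(mu_hi, sd_hi, n_hi)]
    )


class TestBuildHistogram:
    def test_uniform_partition_example(self):
        hist = _hist_from_samples([1, 1, 2, 2, 3, 3, 4, 4], n_bins=4)
        assert list(hist.counts) == [2, 2, 2, 2]

    def test_counts_conserve_voxel_count(self, ad_subject):
        pet, _, wm, _, _ = ad_subject
        mask = binarize_segmentation(wm)
        hist = build_histogram(pet, mask)
        assert hist.counts.sum() == hist.n_voxels == mask.n_voxels

    def test_matches_bruteforce_binning(self):
        rng = np.random.default_rng(5)
        samples = mixture_samples(rng, 50_000, 1.0, 0.1, 1.5, 0.15, 0.3)
        hist = _hist_from_samples(samples, n_bins=64)
        # independent brute-force binning over explicit half-open intervals
        lo, hi = samples.min(), samples.max()
        edges = np.linspace(lo, hi, 65)
        brute = np.zeros(64, dtype=int)
        for v in samples:
            i = min(int((v - lo) / (hi - lo) * 64), 63)
            brute[i] += 1
        np.testing.assert_array_equal(hist.counts, brute)
        np.testing.assert_allclose(hist.bin_edges, edges)

    def test_constant_region_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            _hist_from_samples(np.full(100, 2.0))

    def test_nonuniform_edges_rejected(self):
        with pytest.raises(ValidationError):
            IntensityHistogram(np.array([0.0, 1.0, 3.0]), np.array([1, 1]), 2)


class TestBimodalModel:
    def test_peak_value_and_one_sigma_point(self):
        p = (2.0, 1.0, 0.1, 0.0, 2.0, 0.2)
        assert bimodal_model(1.0, p) == pytest.approx(2.0)
        assert bimodal_model(1.1, p) == pytest.approx(2.0 * np.exp(-0.5))

    def test_equals_sum_of_terms(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 3, 50)
        a1, m1, s1, a2, m2, s2 = 1.3, 0.9, 0.12, 0.5, 1.6, 0.2
        term = lambda a, m, s: a * np.exp(-((x - m) ** 2) / (2 * s * s))  # noqa: E731
        np.testing.assert_allclose(
            bimodal_model(x, (a1, m1, s1, a2, m2, s2)), term(a1, m1, s1) + term(a2, m2, s2)
        )

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValidationError):
            bimodal_model(1.0, (1, 1, 0, 1, 2, 0.1))


class TestFwhm:
    def test_closed_form(self):
        assert fwhm_from_sigma(1.0) == pytest.approx(2.3548200450309493, abs=1e-12)
        assert fwhm_from_sigma(0.1) == pytest.approx(0.23548200450309493, abs=1e-12)

    def test_homogeneity(self):
        for s in (0.05, 0.7, 3.0):
            assert fwhm_from_sigma(2 * s) == pytest.approx(2 * fwhm_from_sigma(s), rel=1e-15)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            fwhm_from_sigma(0.0)


class TestFitBimodal:
    def test_recovers_known_mixture(self):
        rng = np.random.default_rng(17)
        samples = mixture_samples(rng, 50_000, 1.0, 0.10, 1.5, 0.15, 0.3)
        fit = fit_bimodal(_hist_from_samples(samples))
        assert fit.converged and not fit.unimodal_fallback
        assert fit.mu_low == pytest.approx(1.0, abs=0.01)
        assert fit.sigma_low == pytest.approx(0.10, abs=0.01)
        assert fit.mu_high == pytest.approx(1.5, abs=0.02)

    def test_unimodal_input_trips_fallback(self):
        rng = np.random.default_rng(23)
        fit = fit_bimodal(_hist_from_samples(rng.normal(1.0, 0.1, 50_000)))
        assert fit.unimodal_fallback
        assert fit.mu_low == pytest.approx(1.0, abs=0.01)
        assert fit.mu_low == fit.mu_high  # dominant parameters fill both slots

    def test_init_order_irrelevant_after_relabeling(self):
        rng = np.random.default_rng(31)
        hist = _hist_from_samples(mixture_samples(rng, 50_000, 1.0, 0.10, 1.5, 0.15, 0.3))
        fit_fwd = fit_bimodal(hist, FitConfig(init_centers=(1.0, 1.5)))
        fit_swp = fit_bimodal(hist, FitConfig(init_centers=(1.5, 1.0)))
        for attr in ("mu_low", "sigma_low", "mu_high", "sigma_high", "amp_low", "amp_high"):
            assert getattr(fit_fwd, attr) == pytest.approx(getattr(fit_swp, attr), rel=1e-4)
        assert fit_fwd.mu_low <= fit_fwd.mu_high

    def test_too_few_bins_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValidationError, match="10 bins"):
            fit_bimodal(_hist_from_samples(rng.normal(1, 0.1, 1000), n_bins=8))

    def test_ordering_invariant_enforced_on_type(self):
        with pytest.raises(ValidationError):
            BimodalFit(1, 2.0, 0.1, 1, 1.0, 0.1, rss=0.0, converged=True)


class TestSelectReference:
    def test_interval_membership_closed_form(self):
        fit = BimodalFit(1, 1.0, 0.10, 1, 1.5, 0.15, rss=0.0, converged=True)
        data = np.full((5, 5, 5), 1.4)
        data[0, 0, 0] = 1.0  # inside [0.88226, 1.11774]
        pet = _vol(data)
        mask = BinaryMask(np.ones((5, 5, 5), dtype=bool))
        ref = select_reference_voxels(pet, mask, fit, min_voxels=1)
        assert ref.n_voxels == 1
        assert ref.mean_intensity == pytest.approx(1.0)
        half = 0.5 * fwhm_from_sigma(0.10)
        assert 1.0 - half == pytest.approx(0.8822589977, abs=1e-6)

    def test_membership_exhaustive_on_phantom(self, ad_subject):
        pet, _, wm, _, _ = ad_subject
        mask = binarize_segmentation(wm)
        fit = fit_bimodal(build_histogram(pet, mask))
        ref = select_reference_voxels(pet, mask, fit)
        half = 0.5 * fwhm_from_sigma(fit.sigma_low)
        lo, hi = fit.mu_low - half, fit.mu_low + half
        inside = ref.mask.data
        assert np.all((pet.data[inside] >= lo) & (pet.data[inside] <= hi))
        excluded = mask.data & ~inside
        assert np.all((pet.data[excluded] < lo) | (pet.data[excluded] > hi))

    def test_control_reference_matches_true_wm_mean(self, hc_subject):
        pet, _, wm, _, truth = hc_subject
        mask = binarize_segmentation(wm)
        ref, fit = derive_persi_reference(pet, mask)
        assert ref.mean_intensity == pytest.approx(truth.clean_wm_mean_true, rel=0.02)

    def test_sparse_reference_raises(self):
        from persipet import SparseReferenceError

        fit = BimodalFit(1, 10.0, 0.01, 1, 20.0, 0.01, rss=0.0, converged=True)
        pet = _vol(np.ones((5, 5, 5)))
        with pytest.raises(SparseReferenceError):
            select_reference_voxels(pet, BinaryMask(np.ones((5, 5, 5), bool)), fit)


class TestNormalizeAndSmooth:
    def test_self_normalization(self):
        pet = _vol(np.full((6, 6, 6), 5.0))
        from persipet.persi import ReferenceRegion

        ref = ReferenceRegion(BinaryMask(np.ones((6, 6, 6), bool)), 5.0, 216, "PERSI_WM")
        out = normalize_volume(pet, ref)
        np.testing.assert_allclose(out.data, 1.0)
        assert out.data[ref.mask.data].mean() == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance_of_ratio(self, ad_subject):
        pet, _, wm, _, _ = ad_subject
        mask = binarize_segmentation(wm)
        ref1, _ = derive_persi_reference(pet, mask)
        out1 = normalize_volume(pet, ref1)
        pet_c = pet.with_data(pet.data * 3.0)
        ref2, _ = derive_persi_reference(pet_c, mask)
        out2 = normalize_volume(pet_c, ref2)
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-6)

    def test_uniform_volume_unchanged_by_smoothing(self):
        pet = _vol(np.full((16, 16, 16), 2.5))
        np.testing.assert_allclose(gaussian_smooth(pet, 8.0).data, 2.5, atol=1e-9)

    def test_impulse_response_matches_analytic_kernel(self):
        n = 41
        data = np.zeros((n, n, n))
        data[n // 2, n // 2, n // 2] = 1.0
        vol = _vol(data, voxel=2.0)
        out = gaussian_smooth(vol, 8.0)
        sigma = 8.0 / (FWHM_PER_SIGMA * 2.0)  # voxels
        ax = np.arange(n) - n // 2
        k1 = np.exp(-(ax**2) / (2 * sigma**2))
        k1 /= k1.sum()
        expected = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        np.testing.assert_allclose(out.data, expected, atol=1e-6)

    def test_sigma_in_voxels(self):
        assert 8.0 / (FWHM_PER_SIGMA * 2.0) == pytest.approx(1.69864, abs=1e-5)

    def test_tiny_fwhm_returns_identity_with_warning(self):
        rng = np.random.default_rng(0)
        vol = _vol(rng.uniform(size=(8, 8, 8)))
        with pytest.warns(UserWarning, match="half a voxel"):
            out = gaussian_smooth(vol, 0.5)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_smoothing_preserves_global_mean(self, ad_subject):
        pet, _, _, _, _ = ad_subject
        out = gaussian_smooth(pet, 8.0)
        assert out.data.mean() == pytest.approx(pet.data.mean(), rel=1e-3)


class TestParameterRecoveryProperties:
    def test_median_mu_low_error_under_one_percent(self, spec, geometry):
        errs = []
        for seed in range(20):
            pet, _, wm, _, truth = generate_subject(spec, "AD", 900 + seed, geometry=geometry)
            mask = binarize_segmentation(wm)
            fit = fit_bimodal(build_histogram(pet, mask))
            errs.append(abs(fit.mu_low / truth.clean_wm_mean_true - 1))
        assert np.median(errs) < 0.01

    def test_recovery_degrades_as_separation_shrinks(self):
        rng = np.random.default_rng(99)
        med_errs = []
        for sep_sigma in (5.0, 3.0, 1.0):
            errs = []
            for rep in range(5):
                samples = mixture_samples(
                    rng, 50_000, 1.0, 0.10, 1.0 + sep_sigma * 0.10, 0.10, 0.3
                )
                fit = fit_bimodal(_hist_from_samples(samples))
                errs.append(abs(fit.mu_low - 1.0))
            med_errs.append(np.median(errs))
        assert med_errs[0] <= med_errs[1] <= med_errs[2]
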