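"""Rate conversion, global fitting, model selection and error estimation."""

import numpy as np
import pytest

from methylex.dispersion import (
    DispersionDataset,
    FitConfig,
    datasets_from_frame,
    datasets_to_frame,
    ftest_dwh,
    global_fit,
    covariance_errors,
    r2eff_from_intensities,
    validate_exchange_endpoint,
)
from methylex.csp import Peak, PeakList
from methylex.synthetic import gen_dispersion_dataset

from conftest import make_scenario


class TestR2effFromIntensities:
    def test_reference_intensity_gives_zero_rate(self):
        r2eff, _, valid = r2eff_from_intensities([1000.0], 1000.0, 0.030)
        assert valid.all() and r2eff[0] == pytest.approx(0.0)

    def test_closed_form_value(self):
        r2eff, _, _ = r2eff_from_intensities([1000.0 * np.exp(-0.9)], 1000.0, 0.030)
        assert r2eff[0] == pytest.approx(30.0)

    def test_negative_intensity_flagged_not_clamped(self):
        r2eff, sigma, valid = r2eff_from_intensities([500.0, -5.0], 1000.0, 0.030)
        assert valid.tolist() == [True, False]
        assert np.isnan(r2eff[1]) and np.isnan(sigma[1])

    def test_sigma_propagation(self):
        # sigma_R = sigma_I / (I * Trelax)
        r2eff, sigma, _ = r2eff_from_intensities([500.0], 1000.0, 0.030, sigma_i=20.0)
        assert sigma[0] == pytest.approx(20.0 / (500.0 * 0.030))

    def test_replicate_based_noise_estimate(self):
        nu = [66.7, 66.7, 133.3, 133.3]
        i_nu = [900.0, 910.0, 800.0, 790.0]
        _, sigma, _ = r2eff_from_intensities(i_nu, 1000.0, 0.030, nu=nu, noise_floor=1e-6)
        pooled = np.sqrt((2 * 5.0**2 + 2 * 5.0**2) / 2)
        assert sigma[0] == pytest.approx(pooled / (900.0 * 0.030))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            r2eff_from_intensities([1.0], -1.0, 0.030)
        with pytest.raises(ValueError):
            r2eff_from_intensities([1.0], 1.0, 0.0)


class TestGlobalFit:
    def test_noise_free_round_trip_recovers_truth(self):
        scn = make_scenario(1950.0, seed=11, n_sites=3, noise=0.0)
        datasets, _ = gen_dispersion_dataset(scn)
        fit = global_fit(datasets)
        assert fit.kex == pytest.approx(1950.0, rel=1e-3)
        assert fit.pm == pytest.approx(0.03, rel=1e-3)
        for site, sp in scn.truth.sites.items():
            assert fit.dwc[site] == pytest.approx(sp.dw_c_ppm, rel=1e-3)
        assert fit.identifiable

    def test_noisy_recovery_within_covariance_errors(self, noisy_datasets):
        scn, datasets, _ = noisy_datasets
        fit = global_fit(datasets)
        assert abs(fit.kex - 1950.0) < 3 * fit.kex_sigma
        assert abs(fit.pm - 0.03) < 3 * fit.pm_sigma

    def test_flat_data_raises_identifiability_flag(self):
        rng = np.random.default_rng(0)
        nu = np.array([66.7, 133.3, 333.3, 1000.0])
        datasets = [
            DispersionDataset(
                "I1", 800.0, 0.030, nu, 20.0 + 0.1 * rng.standard_normal(4),
                np.full(4, 0.5),
            )
        ]
        fit = global_fit(datasets)
        assert not fit.identifiable

    def test_excluded_sites_are_dropped(self, noisy_datasets):
        _, datasets, _ = noisy_datasets
        fit = global_fit(datasets, FitConfig(exclude_sites=frozenset({"I1"})))
        assert "I1" not in fit.dwc

    def test_fitted_parameters_reproduce_chi2(self, noisy_datasets):
        _, datasets, _ = noisy_datasets
        fit = global_fit(datasets)
        from methylex.exchange import mq_r2eff_curve

        params = fit.exchange_params()
        chi2 = 0.0
        for ds in datasets:
            calc = mq_r2eff_curve(params, ds.site, ds.schedule)
            chi2 += float(np.sum(((calc - ds.r2eff) / ds.sigma) ** 2))
        assert chi2 == pytest.approx(fit.chi2, rel=1e-6)

    def test_pm_constrained_below_half(self, noisy_datasets):
        # two-state label-swap symmetry makes pm and 1-pm equivalent;
        # the fitter must resolve it by constraining pm < 0.5
        _, datasets, _ = noisy_datasets
        fit = global_fit(datasets)
        assert 0.0 < fit.pm < 0.5

    def test_phi_better_determined_than_parts(self):
        """In the fast regime the product pm(1-pm)dw^2 stays identifiable
        while pm and dw individually wander along the degenerate direction.

        The shift difference enters phi squared, so the commensurate
        per-parameter comparison is against dw^2 (and against pm, which is
        linear in phi).
        """
        err_phi, err_pm, err_dw2 = [], [], []
        for seed in range(20, 28):
            scn = make_scenario(3000.0, seed=seed, n_sites=3, dwc_range=(0.3, 0.8))
            datasets, _ = gen_dispersion_dataset(scn)
            fit = global_fit(datasets)
            q_true = 0.03 * 0.97
            for site, sp in scn.truth.sites.items():
                phi_t = q_true * sp.dw_c_ppm**2
                err_phi.append(abs(fit.phi[site] - phi_t) / phi_t)
                err_dw2.append(
                    abs(fit.dwc[site] ** 2 - sp.dw_c_ppm**2) / sp.dw_c_ppm**2
                )
            err_pm.append(abs(fit.pm - 0.03) / 0.03)
        assert np.median(err_phi) < np.median(err_pm)
        assert np.median(err_phi) < np.median(err_dw2)

    def test_frame_round_trip(self, noisy_datasets):
        _, datasets, _ = noisy_datasets
        back = datasets_from_frame(datasets_to_frame(datasets))
        assert len(back) == len(datasets)
        key = lambda d: (d.site, d.field_mhz)
        for a, b in zip(sorted(datasets, key=key), sorted(back, key=key)):
            assert a.site == b.site
            np.testing.assert_allclose(a.r2eff, b.r2eff)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_fit([])


class TestCovarianceErrors:
    def test_doubling_sigma_doubles_parameter_errors(self):
        scn = make_scenario(1100.0, seed=31, n_sites=2)
        datasets, _ = gen_dispersion_dataset(scn)
        fit1 = global_fit(datasets)
        for ds in datasets:
            ds.sigma = ds.sigma * 2.0
        fit2 = global_fit(datasets)
        e1, e2 = covariance_errors(fit1), covariance_errors(fit2)
        for name in ("kex", "pm"):
            assert e2[name] == pytest.approx(2.0 * e1[name], rel=0.05)

    def test_flat_site_dwc_unidentifiable(self):
        nu = np.array([66.7, 133.3, 333.3, 533.3, 1000.0])
        datasets = [
            DispersionDataset("I9", 800.0, 0.030, nu, np.full(5, 20.0), np.full(5, 0.5))
        ]
        fit = global_fit(datasets)
        # a perfectly flat series carries no information on dwC
        assert fit.dwc["I9"] == pytest.approx(0.0, abs=0.05) or np.isinf(
            fit.dwc_sigma["I9"]
        ) or fit.dwc_sigma["I9"] > 10.0


class TestFTest:
    def test_identical_chi2_rejects_dwh(self, noisy_datasets):
        _, datasets, _ = noisy_datasets
        f0 = global_fit(datasets)
        f1 = global_fit(datasets, FitConfig(fit_dwh=frozenset({"I1"})))
        # build a fake "full" fit with the same chi2: F = 0 -> p = 1
        f1.chi2 = f0.chi2
        res = ftest_dwh(f0, f1, "I1")
        assert not res.include_dwh and res.p_value == pytest.approx(1.0)

    def test_non_nested_fits_rejected(self, noisy_datasets):
        _, datasets, _ = noisy_datasets
        f0 = global_fit(datasets)
        with pytest.raises(ValueError):
            ftest_dwh(f0, f0, "I1")

    def test_true_dwh_detected_and_recovered(self):
        # one site with a genuine proton shift difference amid companions
        # that pin the global parameters (as in a full global analysis)
        scn = make_scenario(
            1100.0, seed=402, n_sites=3, dwh={"I1": 0.10}, dwc_range=(0.5, 1.2)
        )
        datasets, _ = gen_dispersion_dataset(scn)
        f0 = global_fit(datasets)
        f1 = global_fit(datasets, FitConfig(fit_dwh=frozenset({"I1"})))
        res = ftest_dwh(f0, f1, "I1")
        assert res.include_dwh
        assert abs(f1.dwh["I1"]) == pytest.approx(0.10, abs=0.05)


class TestEndpointValidation:
    def _fit_and_lists(self, dc_offsets=None):
        scn = make_scenario(1100.0, seed=51, n_sites=4, noise=0.0)
        datasets, _ = gen_dispersion_dataset(scn)
        fit = global_fit(datasets)
        free = PeakList(
            Peak(s, "Ile-d1", 0.6, 10.0 + i, 1.0)
            for i, s in enumerate(sorted(scn.truth.sites))
        )
        offsets = dc_offsets or {
            s: scn.truth.sites[s].dw_c_ppm for s in scn.truth.sites
        }
        bound = PeakList(
            Peak(p.site, p.methyl_class, p.dh, p.dc + offsets[p.site], 1.0) for p in free
        )
        return fit, free, bound

    def test_perfect_agreement_gives_r_one(self):
        fit, free, bound = self._fit_and_lists()
        val = validate_exchange_endpoint(fit, free, bound)
        assert val.pearson_r == pytest.approx(1.0, abs=1e-3)
        assert val.pearson_r_sqrtphi == pytest.approx(1.0, abs=1e-3)

    def test_permuted_labels_destroy_correlation(self):
        fit, free, bound = self._fit_and_lists()
        sites = sorted(fit.dwc)
        perm = {a: fit.dwc[b] for a, b in zip(sites, sites[1:] + sites[:1])}
        fit.dwc = perm
        val = validate_exchange_endpoint(fit, free, bound)
        assert abs(val.pearson_r) < 0.95

    def test_too_few_shared_sites_leaves_r_undefined(self):
        fit, free, bound = self._fit_and_lists()
        small = PeakList([free[sorted(free.sites())[0]]])
        val = validate_exchange_endpoint(fit, small, bound)
        assert np.isnan(val.pearson_r)
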