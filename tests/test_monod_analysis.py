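"""Monod parameter extraction, rate laws, and the Gaussian amendment."""

import numpy as np
import pytest

from methanomod.monod import (ExtractionError, GrowthCurve, MonodFit,
                              alt_monod, amended_monod, approx_control,
                              composite_params, extract_alpha, extract_k_m,
                              extract_mu_max, first_order,
                              fit_gaussian_amendment, liebig, monod,
                              rate_law_comparison)

GRID = np.logspace(-6, 0, 121)


def _exact_monod_curve(mu_max=1.0, k_m=4e-4):
    return GrowthCurve(GRID, monod(GRID, mu_max, k_m))


class TestExtraction:
    def test_exact_monod_recovery(self):
        curve = _exact_monod_curve()
        mu_max = extract_mu_max(curve)
        k_m = extract_k_m(curve, mu_max)
        assert mu_max == pytest.approx(1.0, rel=1e-3)
        assert k_m == pytest.approx(4e-4, rel=1e-2)
        # on an exact Monod curve alpha approaches mu_max/K_M = 2500
        assert extract_alpha(curve) == pytest.approx(2500.0, rel=0.03)

    def test_recovery_within_one_percent(self):
        for mu_max, k_m in [(0.7, 1e-4), (1.3, 2e-3)]:
            curve = _exact_monod_curve(mu_max, k_m)
            m = extract_mu_max(curve)
            assert m == pytest.approx(mu_max, rel=0.01)
            assert extract_k_m(curve, m) == pytest.approx(k_m, rel=0.01)

    def test_flat_curve_has_no_half_saturation(self):
        flat = GrowthCurve(GRID, np.full_like(GRID, 0.5))
        with pytest.raises(ExtractionError):
            extract_k_m(flat, 0.5)

    def test_short_curve_rejects_mu_max(self):
        short = GrowthCurve(GRID[:50], monod(GRID[:50], 1.0, 4e-4))
        with pytest.raises(ExtractionError):
            extract_mu_max(short)


class TestRateLaws:
    def test_monod_half_saturation_identities(self):
        assert monod(4e-4, 1.0, 4e-4) == pytest.approx(0.5)
        assert alt_monod(1.0 / 2500.0, 1.0, 2500.0) == pytest.approx(0.5)
        assert monod(0.1, 1.0, 4e-4) == pytest.approx(0.99602, rel=1e-4)

    def test_alt_monod_equals_monod_at_derived_km(self):
        mu_max, alpha = 1.1, 1800.0
        vals1 = monod(GRID, mu_max, mu_max / alpha)
        vals8 = alt_monod(GRID, mu_max, alpha)
        assert np.allclose(vals1, vals8, rtol=1e-14)

    def test_first_order_and_liebig(self):
        assert first_order(2e-4, 1600.0) == pytest.approx(0.32)
        lb = liebig(GRID, 1.0, 1600.0)
        assert lb[-1] == 1.0
        assert lb[0] == pytest.approx(1600.0 * GRID[0])

    def test_approx_control_sums_to_one(self):
        e_mcr, e_mta = approx_control(GRID, 1.0, 1600.0)
        assert np.allclose(e_mcr + e_mta, 1.0, rtol=1e-14)
        e_mcr_mid, e_mta_mid = approx_control(1.0 / 1600.0, 1.0, 1600.0)
        assert e_mcr_mid == pytest.approx(0.5)
        assert float(approx_control(1e-7, 1.0, 1600.0)[1]) > 0.99


class TestAmendment:
    FIT = MonodFit(1.0, 4e-4, 1600.0, mu_o=0.1, beta_low=2.1,
                   beta_high=3.1)

    def test_peak_value(self):
        c_peak = self.FIT.mu_max / self.FIT.alpha
        assert amended_monod(c_peak, self.FIT) \
            == pytest.approx(0.5 + 0.1, rel=1e-12)

    def test_tails_recover_alt_monod(self):
        for c in (1e-8, 10.0):
            assert amended_monod(c, self.FIT) == pytest.approx(
                float(alt_monod(c, 1.0, 1600.0)), rel=1e-6)

    def test_amended_dominates_alt_monod(self):
        assert np.all(amended_monod(GRID, self.FIT)
                      >= alt_monod(GRID, 1.0, 1600.0))

    def test_parameter_recovery_on_constructed_curve(self):
        mu_max, alpha = 1.0, 1600.0
        x = np.log(mu_max / (alpha * GRID))
        truth = alt_monod(GRID, mu_max, alpha) \
            + 0.1 * np.exp(-np.pi * (x / 2.5) ** 2)
        curve = GrowthCurve(GRID, truth)
        mu_o, b_lo, b_hi = fit_gaussian_amendment(curve, mu_max, alpha)
        assert mu_o == pytest.approx(0.1, rel=0.01)
        assert b_lo == pytest.approx(2.5, rel=0.01)
        assert b_hi == pytest.approx(2.5, rel=0.01)

    def test_degenerate_fit_on_pure_alt_monod(self):
        curve = GrowthCurve(GRID, alt_monod(GRID, 1.0, 1600.0))
        mu_o, b_lo, b_hi = fit_gaussian_amendment(curve, 1.0, 1600.0)
        assert mu_o == 0.0
        assert np.isnan(b_lo) and np.isnan(b_hi)


class TestComparisonTable:
    def test_identical_curves_have_zero_difference(self):
        fit = MonodFit(1.0, 4e-4, 2500.0)
        curve = _exact_monod_curve()
        cmp = rate_law_comparison(curve, fit)
        assert np.abs(cmp["monod"]).max() < 1e-12


class TestComposite:
    def test_cob_saturation_factor(self, model, ss100):
        # CoB pool at 1.7 mM vs a 59 uM Michaelis constant: 1.7/1.759
        cp = composite_params(model, ss100, ss100)
        assert cp.cob_saturation == pytest.approx(0.96646, rel=1e-4)
        assert cp.k_mta_app <= model.reaction("MTA").kcat
        assert cp.k_mcr_app <= model.reaction("MCR").kcat

    def test_saturation_limit_of_mcr_apparent_constant(self, model, ss100):
        big = model.copy()
        big.moieties["CoM"].total = 1.0  # T_CoM >> Km
        cp = composite_params(big, ss100, ss100)
        mcr = model.reaction("MCR")
        assert cp.k_mcr_app == pytest.approx(
            mcr.kcat * cp.cob_saturation, rel=1e-3)
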