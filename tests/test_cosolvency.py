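"""Excess solubility and CNIBS/Redlich-Kister fitting, selection, maxima."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cosolv import (
    DomainError,
    cnibs_predict,
    excess_solubility,
    fit_cnibs,
    ideal_ln_solubility,
    locate_maximum,
    redlich_kister_term,
    select_order,
)
from cosolv.core import BinarySolubilityProfile, ETHANOL, ETHYL_ACETATE
from cosolv.cosolvency import excess_profile
from cosolv.synthetic import (
    ProfileSimSpec,
    simulate_binary_profile,
)

endpoint_st = st.floats(1e-6, 0.2)
coeff_st = st.floats(-10, 10)


class TestIdealAndExcess:
    def test_endpoint_identities(self):
        assert ideal_ln_solubility(0.0, 0.02, 0.005) == pytest.approx(np.log(0.02))
        assert ideal_ln_solubility(1.0, 0.02, 0.005) == pytest.approx(np.log(0.005))

    def test_midpoint_log_average(self):
        assert ideal_ln_solubility(0.5, np.exp(-2), np.exp(-4)) == pytest.approx(-3.0)

    def test_excess_zero_at_matching_endpoint(self):
        assert excess_solubility((0.0, 0.02), 0.02, 0.005) == pytest.approx(0.0)

    def test_ideal_profile_has_zero_excess_everywhere(self):
        x2 = np.linspace(0, 1, 11)
        x = np.exp(ideal_ln_solubility(x2, 0.02, 0.005))
        for c, v in zip(x2, x):
            assert excess_solubility((c, v), 0.02, 0.005) == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(
        x1p=endpoint_st,
        x2p=endpoint_st,
        s=st.lists(coeff_st, min_size=1, max_size=4),
        x2=st.floats(0.0, 1.0),
    )
    def test_cnibs_excess_equals_closed_form(self, x1p, x2p, s, x2):
        """For model-generated data, ln xE is exactly the Redlich-Kister term."""
        x = cnibs_predict(x2, s, x1p, x2p)
        assert excess_solubility((x2, x), x1p, x2p) == pytest.approx(
            redlich_kister_term(x2, s), abs=1e-10
        )


class TestPrediction:
    @settings(derandomize=True, max_examples=1000)
    @given(
        x1p=endpoint_st,
        x2p=endpoint_st,
        s=st.lists(coeff_st, min_size=1, max_size=4),
    )
    def test_endpoint_exactness_for_any_coefficients(self, x1p, x2p, s):
        assert cnibs_predict(0.0, s, x1p, x2p) == pytest.approx(x1p, rel=1e-12)
        assert cnibs_predict(1.0, s, x1p, x2p) == pytest.approx(x2p, rel=1e-12)

    def test_zero_coefficients_give_geometric_mean_at_midpoint(self):
        assert cnibs_predict(0.5, [0.0], 0.04, 0.01) == pytest.approx(
            np.sqrt(0.04 * 0.01)
        )

    def test_fitted_curve_shows_interior_maximum(self, noisefree_profile):
        """A strong synergistic system peaks at an intermediate composition."""
        fit = fit_cnibs(noisefree_profile, 1)
        loc = locate_maximum(fit)
        assert 0.2 < loc.x2_at_max < 0.5
        assert loc.x_max > max(fit.x1_pure, fit.x2_pure)


class TestFitting:
    def test_roundtrip_recovery_to_1e8(self):
        spec = ProfileSimSpec(
            x1_pure=271.5e-5, x2_pure=6.732e-5, s_coeffs=(8.7259, -1.2030),
            noise_sigma=0.0,
        )
        fit = fit_cnibs(simulate_binary_profile(spec), 1)
        assert fit.s_coeffs == pytest.approx([8.7259, -1.2030], abs=1e-8)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_ideal_profile_fits_to_zero_constant(self):
        x2 = np.linspace(0, 1, 11)
        x = np.exp(ideal_ln_solubility(x2, 0.02, 0.02))
        prof = BinarySolubilityProfile.from_arrays("s", ETHANOL, ETHYL_ACETATE, x2, x)
        fit = fit_cnibs(prof, 0)
        assert fit.s_coeffs[0] == pytest.approx(0.0, abs=1e-10)

    def test_idempotent_refit(self, noisefree_profile):
        fit = fit_cnibs(noisefree_profile, 1)
        x2 = noisefree_profile.x2_grid
        refit_prof = BinarySolubilityProfile.from_arrays(
            "s", ETHANOL, ETHYL_ACETATE, x2, fit.predict(x2)
        )
        refit = fit_cnibs(refit_prof, 1)
        assert refit.s_coeffs == pytest.approx(fit.s_coeffs, abs=1e-10)

    def test_nested_orders_never_increase_rss(self):
        prof = simulate_binary_profile(
            ProfileSimSpec(
                x1_pure=0.02, x2_pure=0.004, s_coeffs=(5.0, -1.0, 0.5),
                noise_sigma=0.05, seed=11,
            )
        )
        rss = [fit_cnibs(prof, n).rss_interior for n in (0, 1, 2, 3)]
        assert all(b <= a + 1e-12 for a, b in zip(rss, rss[1:]))

    def test_insufficient_points_rejected(self):
        x2 = np.array([0.0, 0.5, 1.0])
        x = np.array([0.02, 0.03, 0.01])
        prof = BinarySolubilityProfile.from_arrays("s", ETHANOL, ETHYL_ACETATE, x2, x)
        with pytest.raises(DomainError):
            fit_cnibs(prof, 2)

    def test_ci_halfwidths_cover_truth(self):
        """k = 2 intervals cover the generating constants in >=90 % of sims."""
        truth = (4.3347, -1.0773)
        hits = np.zeros(2)
        n_sim = 500
        for rep in range(n_sim):
            prof = simulate_binary_profile(
                ProfileSimSpec(
                    x1_pure=2583e-5, x2_pure=895.0e-5, s_coeffs=truth,
                    noise_sigma=0.03, seed=30_000 + rep,
                )
            )
            fit = fit_cnibs(prof, 1)
            hits += np.abs(fit.s_coeffs - truth) <= fit.ci_halfwidths
        assert (hits / n_sim >= 0.90).all()


class TestOrderSelection:
    def test_two_constant_truth_selected(self):
        hits = 0
        for rep in range(100):
            prof = simulate_binary_profile(
                ProfileSimSpec(
                    x1_pure=2583e-5, x2_pure=895.0e-5, s_coeffs=(4.3347, -1.0773),
                    noise_sigma=0.03, seed=20_000 + rep,
                )
            )
            if select_order(prof).best.order == 1:
                hits += 1
        assert hits >= 90

    def test_noisefree_higher_orders_add_nothing(self, noisefree_profile):
        sel = select_order(noisefree_profile)
        rss = sel.table["rss_interior"]
        assert rss.loc[2] < 1e-10 and rss.loc[3] < 1e-10

    def test_pure_ideal_prefers_order_zero(self):
        x2 = np.linspace(0, 1, 11)
        rng = np.random.default_rng(5)
        x = np.exp(ideal_ln_solubility(x2, 0.02, 0.004))
        x[1:-1] *= np.exp(rng.normal(0, 0.01, 9))
        prof = BinarySolubilityProfile.from_arrays("s", ETHANOL, ETHYL_ACETATE, x2, x)
        sel = select_order(prof)
        assert sel.best.order == 0
        assert abs(sel.best.s_coeffs[0]) < 0.1


class TestMaximumLocation:
    def test_monotone_profile_peaks_at_pure_alcohol(self):
        x2 = np.linspace(0, 1, 11)
        x = np.exp(ideal_ln_solubility(x2, 0.03, 0.001))
        prof = BinarySolubilityProfile.from_arrays("s", ETHANOL, ETHYL_ACETATE, x2, x)
        loc = locate_maximum(prof)
        assert loc.x2_at_max == 0.0
        assert loc.enhancement_vs_alcohol == pytest.approx(0.0)

    def test_symmetric_model_peaks_at_half(self):
        """Equal endpoints and a constant-only correction peak at x2 = 0.5."""
        prof = simulate_binary_profile(
            ProfileSimSpec(x1_pure=0.01, x2_pure=0.01, s_coeffs=(3.0,), noise_sigma=0.0)
        )
        loc = locate_maximum(fit_cnibs(prof, 0))
        assert loc.x2_at_max == pytest.approx(0.5, abs=1e-6)

    def test_excess_profile_frame_shape(self, noisefree_profile):
        df = excess_profile(noisefree_profile)
        assert list(df.columns) == ["solute", "x2_ethyl_acetate", "x", "ln_xE"]
        assert df.ln_xE.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert df.ln_xE.iloc[-1] == pytest.approx(0.0, abs=1e-12)
        assert (df.ln_xE.iloc[1:-1] > 0).all()
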