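"""KAT solvatochromic regression and the term-elimination procedure."""

import numpy as np
import pytest

from cosolv import (
    CollinearityError,
    DomainError,
    KATModelSpec,
    KATParameters,
    classical_kat_predict,
    eliminate_terms,
    fit_kat,
    kat_design_matrix,
)
from cosolv.kat import FULL_QUADRATIC_SPEC, REDUCED_QUADRATIC_SPEC
from cosolv.synthetic import simulate_kat_parameters

from conftest import make_kat_profile


@pytest.fixture(scope="module")
def params():
    return simulate_kat_parameters()


class TestClassicalModel:
    def test_intercept_only(self):
        p = KATParameters(0.3, 0.5, 0.6, 0.55, 500.0)
        assert classical_kat_predict(p, (2.5, 0, 0, 0, 0)) == pytest.approx(2.5)

    def test_unit_case(self):
        p = KATParameters(0.3, 1.0, 1.0, 1.0, 1000.0)
        assert classical_kat_predict(p, (0, 1, 1, 1, 1)) == pytest.approx(4.0)

    def test_finite_difference_slope_in_alpha(self):
        c = (0.1, -2.0, 1.5, 0.3, -0.7)
        p0 = KATParameters(0.3, 0.5, 0.6, 0.55, 500.0)
        p1 = KATParameters(0.3, 0.5 + 1e-7, 0.6, 0.55, 500.0)
        slope = (classical_kat_predict(p1, c) - classical_kat_predict(p0, c)) / 1e-7
        assert slope == pytest.approx(c[1], rel=1e-5)

    def test_incomplete_coefficients_rejected(self):
        p = KATParameters(0.3, 0.5, 0.6, 0.55, 500.0)
        with pytest.raises(DomainError):
            classical_kat_predict(p, (1.0, 2.0))


class TestDesignMatrix:
    def test_intercept_only_column_of_ones(self, params):
        X = kat_design_matrix(params, KATModelSpec(("intercept",)))
        assert (X.to_numpy() == 1.0).all()

    def test_beta_quadratic_row(self):
        p = KATParameters(0.0, 0.9, 0.5, 0.6, 700.0)
        X = kat_design_matrix([p], KATModelSpec(("intercept", "beta", "beta^2")))
        assert X.iloc[0].tolist() == pytest.approx([1.0, 0.5, 0.25])

    def test_full_family_matches_hand_built_oracle(self, params):
        X = kat_design_matrix(params, FULL_QUADRATIC_SPEC).to_numpy()
        assert X.shape == (11, 9)
        for i, p in enumerate(params):
            h = p.deltaH2 / 1000.0
            row = [1.0, p.pi_star, p.pi_star**2, p.beta, p.beta**2,
                   p.alpha, p.alpha**2, h, h**2]
            assert X[i] == pytest.approx(row, abs=1e-14)

    def test_unknown_term_rejected(self):
        with pytest.raises(DomainError):
            KATModelSpec(("intercept", "gamma"))


class TestFit:
    TRUTH = {"intercept": -0.02, "beta^2": 0.20, "dh2^2": -0.18}

    def test_exact_recovery_of_generating_coefficients(self, params):
        prof = make_kat_profile(params, self.TRUTH)
        fit = fit_kat(
            prof, params, KATModelSpec(("intercept", "beta^2", "dh2^2"))
        )
        for term, c in self.TRUTH.items():
            assert fit.coefficients[term] == pytest.approx(c, abs=1e-8)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_constant_response_gives_pure_intercept(self, params):
        prof = make_kat_profile(params, {"intercept": 0.005})
        fit = fit_kat(prof, params, KATModelSpec(("intercept", "beta", "dh2")))
        assert fit.coefficients["intercept"] == pytest.approx(0.005, abs=1e-10)
        assert fit.coefficients["beta"] == pytest.approx(0.0, abs=1e-8)
        assert fit.coefficients["dh2"] == pytest.approx(0.0, abs=1e-8)

    def test_constant_parameter_squared_is_collinear(self, params):
        prof = make_kat_profile(params, self.TRUTH)
        with pytest.raises(CollinearityError) as exc:
            fit_kat(prof, params, KATModelSpec(("intercept", "pi_star", "pi_star^2")))
        assert any("pi_star" in t for t in exc.value.terms)

    def test_residuals_orthogonal_to_design(self, params):
        prof = make_kat_profile(params, self.TRUTH, noise_sigma=0.05, seed=3)
        spec = KATModelSpec(("intercept", "beta", "beta^2", "dh2"))
        fit = fit_kat(prof, params, spec)
        X = kat_design_matrix(params, spec).to_numpy()
        resid = prof.x_values - fit.predict(params)
        assert np.abs(X.T @ resid).max() < 1e-10

    def test_nested_specs_never_increase_rss(self, params):
        prof = make_kat_profile(params, self.TRUTH, noise_sigma=0.05, seed=9)
        small = KATModelSpec(("intercept", "beta^2"))
        big = KATModelSpec(("intercept", "beta^2", "dh2^2"))
        assert fit_kat(prof, params, big).rss <= fit_kat(prof, params, small).rss + 1e-15


class TestElimination:
    TRUTH = {"intercept": -0.02, "beta^2": 0.20, "dh2^2": -0.18}

    def test_pi_star_terms_eliminated_first(self, params):
        """pi* is constant in these mixtures, so it must fall out before any
        data-driven pruning happens."""
        prof = make_kat_profile(params, self.TRUTH, noise_sigma=0.01, seed=1)
        elim = eliminate_terms(prof, params, FULL_QUADRATIC_SPEC)
        first_two = elim.dropped_terms[:2]
        assert set(first_two) == {"pi_star", "pi_star^2"}
        reasons = [s.reason for s in elim.trace[:2]]
        assert all("constant" in r or "collinear" in r for r in reasons)

    def test_all_constant_parameters_leave_only_intercept(self):
        const = [
            KATParameters(x2, 0.5, 0.6, 0.55, 500.0)
            for x2 in np.linspace(0, 1, 11)
        ]
        prof = make_kat_profile(const, {"intercept": 0.01})
        elim = eliminate_terms(prof, const, REDUCED_QUADRATIC_SPEC)
        assert elim.final.spec.included_terms == ("intercept",)

    def test_rmsd_nondecreasing_along_backward_trace(self, params):
        prof = make_kat_profile(params, self.TRUTH, noise_sigma=0.03, seed=21)
        elim = eliminate_terms(prof, params, REDUCED_QUADRATIC_SPEC, threshold=0.5)
        rmsds = [s.fit.rmsd for s in elim.trace if s.fit is not None]
        assert all(b >= a - 1e-12 for a, b in zip(rmsds, rmsds[1:]))

    def test_exhaustive_recovers_planted_model(self, params):
        """AICc subset enumeration identifies the generating 3-term form."""
        prof = make_kat_profile(params, self.TRUTH, noise_sigma=0.01, seed=77)
        elim = eliminate_terms(prof, params, REDUCED_QUADRATIC_SPEC, mode="exhaustive")
        assert set(elim.final.spec.non_intercept_terms) == {"beta^2", "dh2^2"}

    def test_selection_consistency_rate(self, params):
        """The planted beta^2 + (dH2/1000)^2 family is recovered in >=90 %
        of 200 seeded replicates at 1 % multiplicative noise."""
        hits = 0
        for rep in range(200):
            prof = make_kat_profile(
                params, self.TRUTH, noise_sigma=0.01, seed=10_000 + rep
            )
            elim = eliminate_terms(
                prof, params, REDUCED_QUADRATIC_SPEC, mode="exhaustive"
            )
            if set(elim.final.spec.non_intercept_terms) == {"beta^2", "dh2^2"}:
                hits += 1
        assert hits >= 180

    def test_backward_mode_runs_and_traces(self, params):
        prof = make_kat_profile(params, self.TRUTH, noise_sigma=0.01, seed=4)
        elim = eliminate_terms(prof, params, REDUCED_QUADRATIC_SPEC)
        assert elim.mode == "backward"
        assert elim.trace[-1].fit is not None
        # every remaining term is significant at the threshold
        pvals = elim.final.diagnostics["p"].drop("intercept")
        assert (pvals <= 0.05).all() or len(pvals) == 1
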