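"""Abraham LFER: prediction, evaluation, contributions, descriptor inversion."""

import numpy as np
import pytest

from cosolv import (
    DomainError,
    PartitionObservation,
    SoluteDescriptors,
    SolventLFERCoefficients,
    evaluate_predictions,
    experimental_log_partition,
    fit_solute_descriptors,
    predict_log_partition,
    term_contributions,
)
from cosolv.core import ETHANOL, METHANOL, SolventSpec, WATER
from cosolv.synthetic import simulate_partition_dataset

UNIT_D = SoluteDescriptors(1, 1, 1, 1, 1)
UNIT_K = SolventLFERCoefficients(1, 1, 1, 1, 1, 1)


class TestForwardPrediction:
    def test_zero_descriptors_give_intercept(self):
        d = SoluteDescriptors(0, 0, 0, 0, 1e-12)
        k = SolventLFERCoefficients(0.75, 1, 1, 1, 1, 0)
        assert predict_log_partition(d, k) == pytest.approx(0.75)

    def test_unit_sums(self):
        assert predict_log_partition(UNIT_D, UNIT_K) == pytest.approx(6.0)

    def test_linearity_finite_difference_slope_equals_e(self):
        k = SolventLFERCoefficients(0.2, 0.47, -1.0, 0.33, -3.6, 3.86)
        d0 = SoluteDescriptors(1.0, 1.5, 0.8, 0.9, 1.4)
        d1 = SoluteDescriptors(1.0 + 1e-6, 1.5, 0.8, 0.9, 1.4)
        slope = (predict_log_partition(d1, k) - predict_log_partition(d0, k)) / 1e-6
        assert slope == pytest.approx(k.e, rel=1e-6)


class TestExperimentalPartition:
    def test_symmetric_solvents_give_zero(self):
        twin = SolventSpec("twin", WATER.molar_mass, WATER.density_298K)
        assert experimental_log_partition(1e-4, twin, 1e-4) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "x, solvent, x_water, expected",
        [
            (2583e-5, ETHANOL, 4.701e-6, 3.2282),   # stilbene polyphenol
            (2754e-5, METHANOL, 2.376e-6, 3.7111),  # hydroxycinnamic acid
        ],
    )
    def test_measured_partitions(self, x, solvent, x_water, expected):
        assert experimental_log_partition(x, solvent, x_water) == pytest.approx(
            expected, abs=5e-4
        )

    def test_nonpositive_solubility_rejected(self):
        with pytest.raises(DomainError):
            experimental_log_partition(0.0, ETHANOL, 1e-6)


class TestEvaluation:
    def _pairs(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        obs = [
            PartitionObservation(f"solute{i % 3}", f"solvent{i % 2}", rng.normal(3, 1))
            for i in range(n)
        ]
        return obs

    def test_identical_predictions_all_zero(self):
        obs = self._pairs()
        ev = evaluate_predictions(obs, [o.log10_partition for o in obs])
        assert (ev.pairs["ard"] == 0).all()
        assert ev.grand_mean == 0.0

    def test_constructed_ten_percent_offset(self):
        obs = self._pairs()
        preds = [o.log10_partition * 1.1 for o in obs]
        ev = evaluate_predictions(obs, preds)
        assert ev.pairs["ard"].to_numpy() == pytest.approx(np.full(len(obs), 10.0))

    def test_linear_scale_offset(self):
        obs = self._pairs()
        preds = [o.log10_partition + np.log10(1.1) for o in obs]
        ev = evaluate_predictions(obs, preds, scale="linear")
        assert ev.pairs["ard"].to_numpy() == pytest.approx(np.full(len(obs), 10.0))

    def test_grand_mean_invariant_under_reordering(self):
        obs = self._pairs(8, seed=3)
        preds = [o.log10_partition * 1.05 for o in obs]
        ev1 = evaluate_predictions(obs, preds)
        order = np.random.default_rng(1).permutation(len(obs))
        ev2 = evaluate_predictions([obs[i] for i in order], [preds[i] for i in order])
        assert ev1.grand_mean == pytest.approx(ev2.grand_mean, abs=1e-12)

    def test_grand_mean_equals_mean_of_pairs(self):
        obs = self._pairs(7, seed=5)
        preds = [o.log10_partition + 0.2 for o in obs]
        ev = evaluate_predictions(obs, preds)
        assert ev.grand_mean == pytest.approx(ev.pairs["ard"].mean())


class TestTermContributions:
    def test_single_term_dominates(self):
        d = SoluteDescriptors(0, 0, 0, 0, 1.5)
        k = SolventLFERCoefficients(0.3, 1, 1, 1, 1, 4.0)
        contrib = term_contributions(d, k)
        assert contrib["V"] == pytest.approx(100.0)

    def test_equal_magnitudes_split_evenly(self):
        contrib = term_contributions(UNIT_D, UNIT_K)
        assert all(v == pytest.approx(20.0) for v in contrib.values())

    def test_percentages_sum_to_100(self, synthetic_descriptors, lfer_coefficients):
        for d in synthetic_descriptors.values():
            for k in lfer_coefficients.values():
                assert sum(term_contributions(d, k).values()) == pytest.approx(100.0)

    def test_include_intercept_variant(self):
        contrib = term_contributions(UNIT_D, UNIT_K, include_intercept=True)
        assert set(contrib) == {"E", "S", "A", "B", "V", "c"}
        assert sum(contrib.values()) == pytest.approx(100.0)

    def test_all_zero_terms_rejected(self):
        d = SoluteDescriptors(0, 0, 0, 0, 1.0)
        k = SolventLFERCoefficients(1.0, 1, 1, 1, 1, 0)
        with pytest.raises(DomainError):
            term_contributions(d, k)


class TestDescriptorInversion:
    def test_exact_recovery_of_free_subset(self, lfer_coefficients):
        ks = list(lfer_coefficients.values())
        truth = SoluteDescriptors(1.5, 1.8, 0.9, 0.8, 1.4, solute="truth")
        obs = simulate_partition_dataset(truth, ks, noise_sigma=0.0)
        res = fit_solute_descriptors(
            obs, ks, ("A", "B"), fixed={"E": 1.5, "S": 1.8, "V": 1.4}
        )
        assert res.converged
        assert res.fitted_values["A"] == pytest.approx(0.9, abs=1e-8)
        assert res.fitted_values["B"] == pytest.approx(0.8, abs=1e-8)
        assert res.max_abs_residual < 1e-10

    def test_underdetermined_failure_report(self, lfer_coefficients):
        ks = list(lfer_coefficients.values())  # 3 solvents
        truth = SoluteDescriptors(1.5, 1.8, 0.9, 0.8, 1.4)
        obs = simulate_partition_dataset(truth, ks, noise_sigma=0.1, seed=7)
        res = fit_solute_descriptors(obs, ks, ("E", "S", "A", "B", "V"))
        assert not res.converged
        assert res.status == "under_determined"
        assert res.descriptors is None

    def test_unphysical_solution_reported_not_clamped(self, lfer_coefficients):
        ks = list(lfer_coefficients.values())
        # generate from a deliberately unphysical acidity
        base = np.array([1.5, 1.8, -0.5, 0.8, 1.4])
        obs = [
            PartitionObservation("x", k.solvent, k.c + float(k.as_array() @ base))
            for k in ks
        ]
        res = fit_solute_descriptors(
            obs, ks, ("A", "B"), fixed={"E": 1.5, "S": 1.8, "V": 1.4}
        )
        assert res.status == "invariant_violation"
        assert "A" in res.message

    def test_bad_free_set_rejected(self, lfer_coefficients):
        ks = list(lfer_coefficients.values())
        obs = simulate_partition_dataset(SoluteDescriptors(1, 1, 1, 1, 1), ks)
        with pytest.raises(DomainError):
            fit_solute_descriptors(obs, ks, ("Q",))
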