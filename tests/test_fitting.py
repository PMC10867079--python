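"""Chi-square construction and the multistart simplex fit."""

import numpy as np
import pandas as pd
import pytest

from rdmc.fitting import (
    FitConfig,
    ObservedBins,
    bin_observed,
    chi_square,
    fit,
    predicted_proportions,
)
from rdmc.model_core import RDMCParameters
from rdmc.simulator import TrialTable, simulate_dataset


def trials(rts, accuracy=None):
    n = len(rts)
    return pd.DataFrame({
        "congruency": "congruent",
        "rt_ms": np.asarray(rts, float),
        "accuracy": np.ones(n, int) if accuracy is None else np.asarray(accuracy),
        "censored": False,
    })


def two_bin_obs(counts, edges=(400.0,)):
    # helper for toy chi-square cases: 2 correct bins + error bin
    return ObservedBins(edges=edges, correct_counts=tuple(counts),
                        error_count=0, n=int(sum(counts)))


class TestBinObserved:
    def test_quantiles_split_by_construction(self):
        obs = bin_observed(trials(np.linspace(300, 800, 100)))
        assert list(obs.correct_counts) == [10, 20, 20, 20, 20, 10]
        assert obs.error_count == 0
        assert obs.n == 100

    def test_conservation_with_errors(self):
        accuracy = np.ones(100, int)
        accuracy[:5] = 0
        obs = bin_observed(trials(np.linspace(300, 800, 100), accuracy))
        assert sum(obs.correct_counts) == 95
        assert obs.error_count == 5
        assert obs.n == 100

    def test_tie_heavy_sample_matches_brute_force(self):
        rts = np.array([300.0] * 7 + [400.0] * 9 + [500.0] * 4)
        obs = bin_observed(trials(rts))
        edges = np.asarray(obs.edges)
        # brute-force half-open interval count (-inf,e1], (e1,e2], ...
        brute = []
        lo = -np.inf
        for e in list(edges) + [np.inf]:
            brute.append(int(np.sum((rts > lo) & (rts <= e))))
            lo = e
        assert list(obs.correct_counts) == brute
        assert sum(obs.correct_counts) == rts.size

    def test_insufficient_correct_trials(self):
        with pytest.raises(ValueError):
            bin_observed(trials(np.linspace(300, 400, 5)))

    def test_inconsistent_bins_rejected(self):
        with pytest.raises(ValueError):
            ObservedBins(edges=(400.0,), correct_counts=(5, 4),
                         error_count=0, n=10)  # 5+4 != 10


class TestChiSquare:
    def test_zero_when_observed_equals_expected(self):
        obs = {"congruent": two_bin_obs([4, 6])}
        props = {"congruent": np.array([0.4, 0.6, 0.0])}
        assert chi_square(obs, props) == pytest.approx(0.0)

    def test_toy_two_bin_hand_value(self):
        # O={2,8}, E={4,6}: (2-4)^2/4 + (8-6)^2/6 = 1 + 2/3
        obs = {"congruent": two_bin_obs([2, 8])}
        props = {"congruent": np.array([0.4, 0.6, 0.0])}
        assert chi_square(obs, props) == pytest.approx(1.6667, abs=1e-4)

    def test_doubling_counts_doubles_statistic(self):
        props = {"congruent": np.array([0.4, 0.6, 0.0])}
        v1 = chi_square({"congruent": two_bin_obs([2, 8])}, props)
        v2 = chi_square({"congruent": two_bin_obs([4, 16])}, props)
        assert v2 == pytest.approx(2 * v1)

    def test_expected_floor_keeps_statistic_finite(self):
        obs = {"congruent": two_bin_obs([2, 8])}
        props = {"congruent": np.array([0.0, 1.0, 0.0])}
        assert np.isfinite(chi_square(obs, props))

    def test_all_zero_expected_rejected(self):
        obs = {"congruent": two_bin_obs([2, 8])}
        with pytest.raises(ValueError):
            chi_square(obs, {"congruent": np.zeros(3)})

    def test_sums_over_conditions(self):
        props = {"congruent": np.array([0.4, 0.6, 0.0]),
                 "incongruent": np.array([0.4, 0.6, 0.0])}
        obs = {"congruent": two_bin_obs([2, 8]),
               "incongruent": two_bin_obs([2, 8])}
        single = chi_square({"congruent": obs["congruent"]},
                            {"congruent": props["congruent"]})
        assert chi_square(obs, props) == pytest.approx(2 * single)


class TestPredictedProportions:
    def test_same_seed_identical(self, table3_row1):
        edges = (320.0, 360.0, 400.0, 450.0, 520.0)
        a = predicted_proportions(table3_row1, edges, "congruent", 2000, seed=5)
        b = predicted_proportions(table3_row1, edges, "congruent", 2000, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_mass_sums_to_one_up_to_censoring(self, table3_row1):
        edges = (320.0, 360.0, 400.0, 450.0, 520.0)
        p = predicted_proportions(table3_row1, edges, "congruent", 4000, seed=5)
        assert p.shape == (7,)
        assert p.sum() == pytest.approx(1.0, abs=1e-3)

    def test_self_consistency_across_sizes(self, table3_row1):
        """Proportions at n and 2n agree within 3 binomial SEs."""
        edges = (320.0, 360.0, 400.0, 450.0, 520.0)
        p1 = predicted_proportions(table3_row1, edges, "incongruent",
                                   4000, seed=5)
        p2 = predicted_proportions(table3_row1, edges, "incongruent",
                                   8000, seed=17)
        se = np.sqrt(p2 * (1 - p2) * (1 / 4000 + 1 / 8000)) + 1e-9
        assert np.all(np.abs(p1 - p2) <= 3 * se + 0.005)

    def test_near_deterministic_mass_in_one_bin(self):
        p = RDMCParameters(A0=0.8, k_c=2.0, k_i=30.0, d_a=0.6, d_c=0.6,
                           a=0.094, Ter=300.0, st=0.0, sigma=1e-4)
        # constant drift 0.6 crosses at ~78 ms -> RT ~378 ms, inside bin 3
        edges = (300.0, 350.0, 400.0, 450.0, 500.0)
        props = predicted_proportions(p, edges, "congruent", 1500, seed=1)
        assert props[2] > 0.999


@pytest.fixture(scope="module")
def fit_setup(table3_row1):
    data = simulate_dataset(table3_row1, 500, seed=77)
    config = FitConfig(n_sim=1000, dt=0.001, restarts=2, seed=13,
                       max_evals=60)
    return data, config, fit(data, config, start=table3_row1)


class TestFit:
    def test_descent_from_truth(self, fit_setup, table3_row1):
        data, config, result = fit_setup
        # the returned optimum is no worse than any restart's start value
        assert result.chi2 == pytest.approx(result.restarts["chi2"].min())
        assert np.isfinite(result.chi2)

    def test_objective_deterministic_with_common_random_numbers(
            self, fit_setup, table3_row1):
        from rdmc.fitting import PARAM_ORDER, _objective, bin_observed
        data, config, _ = fit_setup
        observed = {c: bin_observed(data.condition(c))
                    for c in ("congruent", "incongruent")}
        theta = np.array([getattr(table3_row1, k) for k in PARAM_ORDER])
        v1 = _objective(theta, observed, config)
        v2 = _objective(theta, observed, config)
        assert v1 == v2

    def test_bounds_respected(self, fit_setup):
        _, config, result = fit_setup
        for key, (lo, hi) in config.bounds.items():
            val = getattr(result.params, key)
            assert lo - 1e-9 <= val <= hi + 1e-9

    def test_restart_table_complete(self, fit_setup):
        _, config, result = fit_setup
        assert len(result.restarts) == config.restarts
        assert {"chi2", "n_evals", "start_A0", "end_A0"} <= set(
            result.restarts.columns)

    def test_objective_prefers_truth_over_perturbed(self, table3_row1):
        """Median objective at truth beats truth with d_c inflated 30%."""
        from rdmc.fitting import bin_observed, chi_square
        wrong = table3_row1.replace(d_c=table3_row1.d_c * 1.3)
        at_truth, at_wrong = [], []
        for s in range(10):
            data = simulate_dataset(table3_row1, 400, seed=1000 + s)
            observed = {c: bin_observed(data.condition(c))
                        for c in ("congruent", "incongruent")}
            for params, store in ((table3_row1, at_truth), (wrong, at_wrong)):
                props = {c: predicted_proportions(
                    params, observed[c].edges, c, 2000, seed=2000 + s)
                    for c in observed}
                store.append(chi_square(observed, props))
        assert np.median(at_truth) < np.median(at_wrong)

    def test_empty_data_rejected(self, table3_row1):
        config = FitConfig(n_sim=1000, restarts=1)
        empty = TrialTable(pd.DataFrame(
            columns=["congruency", "rt_ms", "accuracy", "censored"]))
        with pytest.raises(ValueError):
            fit(empty, config, start=table3_row1)

    def test_n_sim_floor_enforced(self):
        with pytest.raises(ValueError):
            FitConfig(n_sim=500)
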