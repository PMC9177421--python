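import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neofit.clonal_fitness import (
    Clone,
    CloneTree,
    FitConfig,
    FitnessParams,
    clone_covariates,
    clone_fitness,
    driver_fitness,
    evaluate_frequency_changes,
    fit_params,
    fit_params_pooled,
    immune_fitness_cost,
    predict_recurrent,
    predict_recurrent_frequencies,
)
from neofit.data_model import MutationRecord


def mut(clone_id, gene, effect):
    return MutationRecord("P1", "T1", clone_id, gene, effect)


@pytest.fixture
def chain_tree():
    return CloneTree(
        [
            Clone("c0", None, frozenset({"m0"}), {"prim": 0.6, "rec": 0.3}),
            Clone("c1", "c0", frozenset({"m1"}), {"prim": 0.3, "rec": 0.3}),
            Clone("c2", "c1", frozenset({"m2"}), {"prim": 0.1, "rec": 0.4}),
        ],
        sample_roles={"prim": "primary", "rec": "recurrent"},
    )


class TestFitnessComponents:
    def test_driver_count_is_missense_only(self, chain_tree):
        muts = [mut("c0", "KRAS", "missense"), mut("c0", "TP53", "missense"),
                mut("c0", "SMAD4", "nonsense")]
        assert driver_fitness(chain_tree, "c0", muts) == 2

    def test_child_inherits_and_adds_driver(self, chain_tree):
        muts = [mut("c0", "KRAS", "missense"), mut("c0", "TP53", "missense"),
                mut("c0", "SMAD4", "nonsense"), mut("c1", "CDKN2A", "missense")]
        assert driver_fitness(chain_tree, "c1", muts) == 3

    def test_empty_genotype_is_zero(self, chain_tree):
        assert driver_fitness(chain_tree, "c0", []) == 0
        assert driver_fitness(chain_tree, "c0", [mut("c0", "GENE1", "missense")]) == 0

    def test_immune_cost_is_max_quality(self, chain_tree):
        qualities = {"c0": [0.2, 1.7, 0.9]}
        assert immune_fitness_cost(chain_tree, "c0", qualities) == 1.7

    def test_neoantigen_free_clone_costs_zero(self, chain_tree):
        assert immune_fitness_cost(chain_tree, "c0", {}) == 0.0

    def test_child_max_is_monotone_along_lineage(self, chain_tree):
        qualities = {"c0": [1.7], "c1": [0.5], "c2": [2.4]}
        assert immune_fitness_cost(chain_tree, "c1", qualities) == 1.7
        assert immune_fitness_cost(chain_tree, "c2", qualities) == 2.4

    def test_clone_fitness_arithmetic(self):
        assert clone_fitness(2.0, 2.0, FitnessParams(1.0, 0.5)) == pytest.approx(-1.0)
        assert clone_fitness(3.0, 7.0, FitnessParams(0.0, 0.0)) == 0.0

    def test_negative_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            FitnessParams(-0.1, 0.0)


class TestPredictRecurrent:
    def test_neutral_returns_primary_exactly(self):
        x = np.array([0.5, 0.3, 0.2])
        assert np.array_equal(predict_recurrent(x, np.zeros(3)), x)

    def test_two_clone_analytic(self):
        out = predict_recurrent(np.array([0.5, 0.5]), np.array([0.0, math.log(2.0)]))
        assert np.allclose(out, [1 / 3, 2 / 3], atol=1e-15)

    def test_single_clone_always_one(self):
        assert predict_recurrent(np.array([0.4]), np.array([-37.0]))[0] == 1.0

    def test_all_zero_primary_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            predict_recurrent(np.zeros(3), np.zeros(3))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=12),
        st.floats(-30.0, 30.0),
        st.integers(0, 10_000),
    )
    def test_conservation_and_zero_padding(self, x, fscale, seed):
        """Predicted fractions sum to 1 to 1e-12; zero-frequency clones are inert."""
        rng = np.random.default_rng(seed)
        x = np.array(x)
        f = rng.uniform(-1.0, 1.0, len(x)) * fscale
        out = predict_recurrent(x, f)
        assert abs(out.sum() - 1.0) < 1e-12
        padded = predict_recurrent(np.append(x, 0.0), np.append(f, rng.uniform(-5, 5)))
        assert np.allclose(padded[:-1], out, atol=1e-12)
        assert padded[-1] == 0.0

    def test_invariant_to_clone_relabeling(self, chain_tree):
        params = FitnessParams(1.0, 0.5)
        qualities = {"c0": [0.5], "c2": [1.5]}
        muts = [mut("c0", "KRAS", "missense"), mut("c1", "SMAD4", "missense")]
        pred = predict_recurrent_frequencies(chain_tree, params, qualities, muts, "prim")
        assert sum(pred.values()) == pytest.approx(1.0, abs=1e-12)
        # permuting clone order leaves per-clone predictions unchanged
        shuffled = CloneTree(list(reversed(chain_tree.clones)), chain_tree.sample_roles)
        pred2 = predict_recurrent_frequencies(shuffled, params, qualities, muts, "prim")
        assert pred2 == pytest.approx(pred)


class TestFitParams:
    @staticmethod
    def noiseless_data(seed=5, n=10, sigma=(1.0, 0.5)):
        rng = np.random.default_rng(seed)
        x_prim = rng.dirichlet(np.ones(n))
        f_i = rng.uniform(0.0, 2.0, n)
        f_p = rng.integers(2, 5, n).astype(float)
        x_rec = predict_recurrent(x_prim, -sigma[0] * f_i + sigma[1] * f_p)
        return x_prim, x_rec, f_i, f_p

    def test_noiseless_exact_recovery(self):
        x_prim, x_rec, f_i, f_p = self.noiseless_data()
        res = fit_params(x_prim, x_rec, f_i, f_p, FitConfig(n_eff=200))
        assert res.params.sigma_i == pytest.approx(1.0, abs=1e-6)
        assert res.params.sigma_p == pytest.approx(0.5, abs=1e-6)
        assert res.preferred_model == "full"

    def test_likelihood_at_truth_beats_neutral(self):
        x_prim, x_rec, f_i, f_p = self.noiseless_data()
        res = fit_params(x_prim, x_rec, f_i, f_p)
        assert res.log_likelihood >= -0.5 * res.bic_neutral  # lnL_neutral = -bic_neutral/2

    def test_single_clone_falls_back_to_neutral(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = fit_params(np.array([1.0]), np.array([1.0]), np.zeros(1), np.zeros(1))
        assert res.preferred_model == "neutral"

    def test_bic_ordering_matches_preferred(self):
        x_prim, x_rec, f_i, f_p = self.noiseless_data(seed=9)
        res = fit_params(x_prim, x_rec, f_i, f_p)
        assert res.preferred_model == min(res.bics, key=res.bics.get)

    def test_pooled_fit_tightens_estimates(self):
        datasets = [self.noiseless_data(seed=s) for s in range(4)]
        res = fit_params_pooled(datasets, FitConfig(n_eff=200))
        assert res.params.sigma_i == pytest.approx(1.0, abs=1e-6)
        assert res.params.sigma_p == pytest.approx(0.5, abs=1e-6)
        assert res.n_clones_used == sum(len(d[0]) for d in datasets)


class TestEvaluateFrequencyChanges:
    def test_perfect_prediction(self):
        x_prim = np.array([0.5, 0.3, 0.2])
        x_rec = np.array([0.3, 0.5, 0.2])
        table, summary = evaluate_frequency_changes(x_prim, x_rec, x_rec.copy())
        assert summary["direction_agreement"] == 1.0
        assert summary["spearman_rho"] == pytest.approx(1.0)

    def test_unchanged_frequencies_are_ties(self):
        x = np.array([0.5, 0.3, 0.2])
        table, summary = evaluate_frequency_changes(x, x.copy(), x.copy())
        assert summary["n_directional"] == 0
        assert math.isnan(summary["direction_agreement"])

    def test_pseudocount_substitution_below_threshold(self):
        x_prim = np.array([0.5, 0.5])
        x_rec = np.array([0.99, 0.01])  # 0.01 < 3% threshold -> pseudocount 0.015
        table, _ = evaluate_frequency_changes(x_prim, x_rec, x_rec.copy())
        assert table["log_ratio_obs"].iloc[1] == pytest.approx(math.log(0.015 / 0.5))

    def test_threshold_filters_clones(self):
        x_prim = np.array([0.97, 0.02, 0.01])
        table, summary = evaluate_frequency_changes(x_prim, x_prim.copy(), x_prim.copy())
        assert summary["n_clones"] == 1
        with pytest.raises(ValueError, match="threshold"):
            evaluate_frequency_changes(np.array([0.01]), np.array([1.0]), np.array([1.0]))

    def test_spearman_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        x_prim = rng.dirichlet(np.ones(8)) * 0.5 + 0.05
        x_rec = rng.dirichlet(np.ones(8))
        x_hat = rng.dirichlet(np.ones(8))
        table, summary = evaluate_frequency_changes(x_prim, x_rec, x_hat, threshold=0.03)
        lo, lf = table["log_ratio_obs"].to_numpy(), table["log_ratio_fit"].to_numpy()

        def ranks(v):
            order = np.argsort(v)
            r = np.empty(len(v))
            r[order] = np.arange(1, len(v) + 1)
            return r

        ro, rf = ranks(lo), ranks(lf)
        rho = np.sum((ro - ro.mean()) * (rf - rf.mean())) / math.sqrt(
            np.sum((ro - ro.mean()) ** 2) * np.sum((rf - rf.mean()) ** 2)
        )
        assert summary["spearman_rho"] == pytest.approx(rho, abs=1e-12)


class TestTreeValidation:
    def test_two_roots_rejected(self):
        with pytest.raises(ValueError, match="root"):
            CloneTree([Clone("a", None), Clone("b", None)])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CloneTree([Clone("a", None), Clone("a", "a")])

    def test_covariates_in_clone_order(self, chain_tree):
        cov = clone_covariates(chain_tree, {"c1": [0.8]}, [mut("c2", "KRAS", "missense")])
        assert list(cov["clone_id"]) == ["c0", "c1", "c2"]
        assert list(cov["F_I"]) == [0.0, 0.8, 0.8]
        assert list(cov["F_P"]) == [0, 0, 1]
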