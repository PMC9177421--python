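import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neofit.clonal_fitness import Clone, CloneTree
from neofit.cohort_metrics import (
    depletion_analysis,
    ecdf,
    group_comparison,
    paired_deltas,
    shannon_entropy,
    substitution_frequency_regression,
    summarize_tumor,
)
from neofit.data_model import MutationRecord, NeoantigenRecord


class TestShannonEntropy:
    def test_uniform_four_clones(self):
        assert shannon_entropy([0.25] * 4) == pytest.approx(math.log(4), abs=1e-12)

    def test_single_clone_zero(self):
        assert shannon_entropy([1.0]) == 0.0

    def test_closed_form_mixture(self):
        expected = 0.5 * math.log(2) + 0.5 * math.log(4)
        assert shannon_entropy([0.5, 0.25, 0.25]) == pytest.approx(expected, abs=1e-12)

    def test_base_two_display(self):
        assert shannon_entropy([0.25] * 4, base=2) == pytest.approx(2.0)

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError):
            shannon_entropy([0.0, 0.0])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=10))
    def test_bounded_by_uniform_and_padding_invariant(self, x):
        s = shannon_entropy(x)
        assert s <= math.log(len(x)) + 1e-12
        assert shannon_entropy(list(x) + [0.0, 0.0]) == pytest.approx(s, abs=1e-12)


def two_sample_tree():
    return CloneTree(
        [
            Clone("c0", None, frozenset(), {"prim": 0.7, "rec": 0.2}),
            Clone("c1", "c0", frozenset(), {"prim": 0.3, "rec": 0.5}),
            Clone("c2", "c0", frozenset(), {"prim": 0.0, "rec": 0.3}),
        ],
        sample_roles={"prim": "primary", "rec": "recurrent"},
    )


def neo(clone_id, kd_mt, p_mt="NLVPKVATV", gene="G1"):
    return NeoantigenRecord(
        "P1", "T1", clone_id, "NLVPMVATV", p_mt, "HLA-A*02:01", 500.0, kd_mt, gene=gene
    )


class TestSummarizeTumor:
    def test_tmb_counts_nonsynonymous_only(self):
        tree = two_sample_tree()
        muts = [MutationRecord("P1", "T1", "c0", f"G{i}", "missense") for i in range(5)]
        muts += [MutationRecord("P1", "T1", "c0", f"S{i}", "synonymous") for i in range(2)]
        s = summarize_tumor("prim", tree, muts, [], {})
        assert s.tmb == 5

    def test_binder_threshold_filters_neoantigens(self):
        tree = two_sample_tree()
        neos = [neo("c0", 50.0), neo("c0", 400.0, p_mt="NLVPRVATV", gene="G2"),
                neo("c0", 800.0, p_mt="NLVPDVATV", gene="G3")]
        s = summarize_tumor("prim", tree, [], neos, {})
        assert s.na_count == 2
        assert s.na_mut_count == 2

    def test_single_clone_cost_is_clone_cost(self):
        tree = CloneTree([Clone("c0", None, frozenset(), {"prim": 0.9})],
                         sample_roles={"prim": "primary"})
        s = summarize_tumor("prim", tree, [], [], {"c0": [0.3, 1.1]})
        assert s.mean_immune_cost == pytest.approx(1.1)

    def test_absent_sample_is_error(self):
        with pytest.raises(ValueError, match="not present"):
            summarize_tumor("ghost", two_sample_tree(), [], [], {})

    def test_frequency_weighted_cost(self):
        tree = two_sample_tree()
        q = {"c0": [1.0], "c1": [2.0]}
        s = summarize_tumor("prim", tree, [], [], q)
        assert s.mean_immune_cost == pytest.approx((0.7 * 1.0 + 0.3 * 2.0))
        s_unw = summarize_tumor("prim", tree, [], [], q, weighted_immune_cost=False)
        assert s_unw.mean_immune_cost == pytest.approx(1.5)


class TestPairedDeltas:
    def test_identical_samples_zero_deltas(self):
        tree = CloneTree(
            [Clone("c0", None, frozenset(), {"prim": 0.6, "rec": 0.6}),
             Clone("c1", "c0", frozenset(), {"prim": 0.4, "rec": 0.4})],
            sample_roles={"prim": "primary", "rec": "recurrent"},
        )
        sp = summarize_tumor("prim", tree, [], [], {})
        sr = summarize_tumor("rec", tree, [], [], {})
        d = paired_deltas("P1", tree, sp, sr, [], {})
        assert (d.delta_entropy, d.delta_tmb, d.delta_na) == (0.0, 0, 0)
        assert d.n_new_clones == 0

    def test_new_clone_neoantigen_percentage(self):
        tree = two_sample_tree()  # c2 is new in the recurrent sample
        neos = [neo("c0", 100.0, p_mt=f"NLVP{a}VATV", gene=f"G{i}")
                for i, a in enumerate("ACDEFGHI")]
        neos += [neo("c2", 100.0, p_mt="NLVPSVATV", gene="N1"),
                 neo("c2", 100.0, p_mt="NLVPTVATV", gene="N2")]
        sp = summarize_tumor("prim", tree, [], neos, {})
        sr = summarize_tumor("rec", tree, [], neos, {})
        d = paired_deltas("P1", tree, sp, sr, neos, {})
        assert d.n_new_clones == 1
        assert d.pct_new_neoantigens == pytest.approx(20.0)

    def test_no_recurrent_neoantigens_flagged(self):
        tree = two_sample_tree()
        sp = summarize_tumor("prim", tree, [], [], {})
        sr = summarize_tumor("rec", tree, [], [], {})
        d = paired_deltas("P1", tree, sp, sr, [], {})
        assert d.pct_new_neoantigens == 0.0
        assert not d.pct_new_defined

    def test_deltas_antisymmetric(self):
        tree = two_sample_tree()
        muts = [MutationRecord("P1", "T1", "c1", "G1", "missense")]
        sp = summarize_tumor("prim", tree, muts, [], {})
        sr = summarize_tumor("rec", tree, muts, [], {})
        fwd = paired_deltas("P1", tree, sp, sr, [], {})
        rev = paired_deltas("P1", tree, sr, sp, [], {})
        assert fwd.delta_entropy == pytest.approx(-rev.delta_entropy)
        assert fwd.delta_tmb == -rev.delta_tmb


class TestDepletionAnalysis:
    def test_identical_groups(self):
        df = pd.DataFrame({"logC": np.arange(10.0), "D": np.arange(10.0)})
        out = depletion_analysis(df, df.copy())
        for stat in ("logC", "D"):
            assert out[stat]["ks_statistic"] == 0.0
            assert out[stat]["p_value"] == 1.0

    def test_shift_detected(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame({"logC": rng.normal(0, 1, 200), "D": rng.normal(0, 1, 200)})
        b = pd.DataFrame({"logC": a["logC"] + 1.0, "D": a["D"] + 1.0})
        out = depletion_analysis(a, b)
        assert out["D"]["p_value"] < 0.01

    def test_ks_matches_brute_force_sup_difference(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 37)
        b = rng.normal(0.4, 1.3, 53)
        out = depletion_analysis(pd.DataFrame({"logC": a, "D": a}),
                                 pd.DataFrame({"logC": b, "D": b}))
        grid = np.concatenate([a, b])
        sup = max(
            abs(np.mean(a <= v) - np.mean(b <= v)) for v in grid
        )
        assert out["logC"]["ks_statistic"] == pytest.approx(sup, abs=1e-12)

    def test_insufficient_data_names_statistic(self):
        a = pd.DataFrame({"logC": [1.0], "D": [1.0]})
        with pytest.raises(ValueError, match="logC"):
            depletion_analysis(a, a.copy())

    def test_ecdf_shape(self):
        table = ecdf(np.array([3.0, 1.0, 2.0]))
        assert list(table["value"]) == [1.0, 2.0, 3.0]
        assert list(table["cdf"]) == pytest.approx([1 / 3, 2 / 3, 1.0])


class TestSubstitutionFrequencyRegression:
    @staticmethod
    def toy_matrix():
        from neofit.cross_reactivity import SubstitutionMatrix
        from conftest import AA_IDX

        m = np.zeros((20, 20))
        for i, (a, b) in enumerate([("A", "G"), ("L", "V"), ("K", "R"), ("D", "E")]):
            m[AA_IDX[a], AA_IDX[b]] = float(i + 1)
        return SubstitutionMatrix(entries=m, support=np.ones((20, 20), dtype=int))

    def test_exactly_linear_counts_give_perfect_fit(self):
        matrix = self.toy_matrix()
        counts = {("A", "G"): 40.0, ("L", "V"): 30.0, ("K", "R"): 20.0, ("D", "E"): 10.0}
        out = substitution_frequency_regression(counts, matrix)
        assert out["pearson_r"] == pytest.approx(-1.0)
        assert out["slope"] < 0

    def test_matches_closed_form_least_squares(self):
        matrix = self.toy_matrix()
        counts = {("A", "G"): 13.0, ("L", "V"): 29.0, ("K", "R"): 7.0, ("D", "E"): 31.0}
        out = substitution_frequency_regression(counts, matrix)
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([13, 29, 7, 31.0]) / 80.0
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        r = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert out["slope"] == pytest.approx(slope, abs=1e-12)
        assert out["pearson_r"] == pytest.approx(r, abs=1e-12)

    def test_permuted_frequencies_decorrelate(self):
        matrix = self.toy_matrix()
        base = np.array([40.0, 30.0, 20.0, 10.0])
        pairs = [("A", "G"), ("L", "V"), ("K", "R"), ("D", "E")]
        rng = np.random.default_rng(2)
        rs = []
        for _ in range(100):
            perm = rng.permutation(base)
            out = substitution_frequency_regression(dict(zip(pairs, perm)), matrix)
            rs.append(out["pearson_r"])
        assert abs(np.median(rs)) < 0.5

    def test_too_few_types_is_error(self):
        with pytest.raises(ValueError, match="3 distinct"):
            substitution_frequency_regression({("A", "G"): 1.0, ("L", "V"): 2.0},
                                              self.toy_matrix())


def test_group_comparison_two_tailed():
    out = group_comparison([1, 2, 3, 4], [10, 11, 12, 13])
    assert out["p_value"] < 0.05
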