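import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import brute_bh, brute_wilcoxon_two_sided
from mirabind.functional_stats import (
    StatsParams,
    bh_adjust,
    diff_abundance,
    filter_functions,
    log2_fold_change,
    relative_abundance,
    wilcoxon_rank_sum,
)
from mirabind.synthetic_fixtures import simulate_function_counts


class TestRelativeAbundance:
    def test_rows_normalize_to_one(self):
        counts = pd.DataFrame({"F1": [3, 0], "F2": [1, 0]}, index=["s1", "s2"]).astype(float)
        rel = relative_abundance(counts)
        assert list(rel.index) == ["s1"]  # empty sample dropped
        assert rel.loc["s1"].tolist() == [0.75, 0.25]

    def test_random_matrices_sum_to_one(self, rng):
        counts = pd.DataFrame(rng.integers(1, 50, size=(8, 6)).astype(float))
        rel = relative_abundance(counts)
        assert np.allclose(rel.sum(axis=1), 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            relative_abundance(pd.DataFrame({"F1": [-1.0]}))


class TestFilterFunctions:
    def _toy(self):
        rel = pd.DataFrame(
            {
                "common": [0.5] * 10,
                "rare_prevalence": [0.4] + [0.0] * 9,  # 10% prevalence
                "low_abundance": [0.001] * 10,
                "a_only": [0.2] * 5 + [0.0] * 5,
            },
            index=[f"s{i}" for i in range(10)],
        )
        groups = pd.Series(["A"] * 5 + ["B"] * 5, index=rel.index)
        return rel, groups

    def test_prevalence_abundance_and_shared_filters(self):
        rel, groups = self._toy()
        kept = filter_functions(rel, groups)
        assert list(kept.columns) == ["common"]

    def test_engineered_survivor_count(self, rng):
        # 6 functions, exactly 4 designed to survive the default filter
        rel = pd.DataFrame(
            rng.dirichlet(np.ones(4) * 20, size=8),
            columns=["f1", "f2", "f3", "f4"],
            index=[f"s{i}" for i in range(8)],
        )
        rel["low"] = 0.0001
        rel["b_only"] = [0.0] * 4 + [0.05] * 4
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=rel.index)
        kept = filter_functions(rel, groups)
        assert set(kept.columns) == {"f1", "f2", "f3", "f4"}


class TestWilcoxon:
    def test_textbook_extreme_split(self):
        p, branch = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert branch == "exact"
        assert p == pytest.approx(0.1)

    def test_matches_enumeration_oracle_on_small_samples(self, rng):
        for _ in range(25):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 13 - n1))
            vals = rng.choice(1000, size=n1 + n2, replace=False).astype(float)
            x, y = vals[:n1], vals[n1:]
            p, branch = wilcoxon_rank_sum(x, y)
            assert branch == "exact"
            assert p == pytest.approx(brute_wilcoxon_two_sided(x, y), abs=1e-12)

    def test_identical_groups_give_p_one(self):
        assert wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0]) == (1.0, "degenerate")

    def test_exact_and_normal_branches_agree(self, rng):
        diffs = []
        for _ in range(30):
            vals = rng.normal(size=12)
            x, y = vals[:6], vals[6:]
            p_exact, _ = wilcoxon_rank_sum(x, y)
            from scipy.stats import mannwhitneyu

            p_norm = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            diffs.append(abs(p_exact - p_norm))
        assert max(diffs) < 0.05  # continuity-corrected approximation is close


class TestBhAdjust:
    def test_hand_computed_stepup(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]).tolist() == [0.3]

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_textbook_definition_and_dominates_input(self, ps):
        got = bh_adjust(ps)
        assert np.allclose(got, brute_bh(ps))
        assert (got >= np.asarray(ps) - 1e-12).all()
        assert (got <= 1.0 + 1e-12).all()

    def test_permutation_equivariance(self, rng):
        ps = rng.uniform(size=12)
        perm = rng.permutation(12)
        assert np.allclose(bh_adjust(ps)[perm], bh_adjust(ps[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestLog2FoldChange:
    def test_equal_means_give_zero(self):
        assert log2_fold_change(0.3, 0.3) == 0.0

    def test_fourfold_shift(self):
        assert log2_fold_change(0.04, 0.01, pseudocount=1e-12) == pytest.approx(2.0)

    def test_antisymmetry(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0, 1, 2)
            assert log2_fold_change(a, b) == pytest.approx(-log2_fold_change(b, a))


class TestDiffAbundance:
    def test_planted_shift_detected_and_null_functions_not_flagged(self, rng):
        counts, groups = simulate_function_counts(
            n_per_group=10, n_functions=20, rng=rng, shifted=(0, 1, 2, 3, 4)
        )
        rel = relative_abundance(counts)
        out = diff_abundance(rel, groups)
        flagged = set(out.loc[out["significant"], "function_id"])
        planted = {f"F{j + 1:02d}" for j in range(5)}
        assert planted <= flagged
        assert len(flagged - planted) <= 1  # at most a stray false positive

    def test_requires_exactly_two_groups(self, rng):
        counts, groups = simulate_function_counts(3, 5, rng)
        rel = relative_abundance(counts)
        with pytest.raises(ValueError, match="2 groups"):
            diff_abundance(rel, pd.Series("A", index=rel.index))

    def test_group_order_flips_sign(self, rng):
        counts, groups = simulate_function_counts(6, 8, rng, shifted=(0,))
        rel = relative_abundance(counts)
        ab = diff_abundance(rel, groups, group_order=("A", "B"))
        ba = diff_abundance(rel, groups, group_order=("B", "A"))
        merged = ab.merge(ba, on="function_id", suffixes=("_ab", "_ba"))
        assert np.allclose(merged["log2fc_ab"], -merged["log2fc_ba"])


def test_stats_params_validation():
    with pytest.raises(ValueError):
        StatsParams(min_prevalence=1.5)
    with pytest.raises(ValueError):
        StatsParams(lfc_min=0.0)
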