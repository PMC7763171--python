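from itertools import combinations

import numpy as np
import pytest

import serapept as sp
from serapept.differential import SamConfig, sam_two_class

from conftest import make_table


def brute_force_sam(x, na, nb, s0):
    """Independent oracle: d statistic and exhaustive permutation p-values
    computed by direct enumeration of all label splits."""
    n = na + nb

    def d_for(idx_b):
        idx_b = set(idx_b)
        a = x[:, [i for i in range(n) if i not in idx_b]]
        b = x[:, sorted(idx_b)]
        r = b.mean(axis=1) - a.mean(axis=1)
        ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
             ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        s = np.sqrt((1 / na + 1 / nb) / (na + nb - 2) * ss)
        return r / (s + s0)

    d_obs = d_for(range(na, n))
    splits = list(combinations(range(n), nb))
    d_all = np.array([d_for(idx) for idx in splits])  # splits × signals
    p = np.mean(np.abs(d_all) >= np.abs(d_obs)[None, :] - 1e-12, axis=0)
    return d_obs, p


class TestSamTwoClass:
    def test_identical_groups_null_result(self):
        x = np.tile(np.arange(1, 6, dtype=float)[:, None], (1, 8))
        table = make_table(x, ["a"] * 4 + ["b"] * 4)
        res = sam_two_class(table, "a", "b", SamConfig(n_permutations=70, seed=0))
        np.testing.assert_allclose(res.stats["score"], 0.0)
        np.testing.assert_allclose(res.stats["fold_change"], 1.0)
        assert (res.stats["q_value"] > 0.9).all()

    def test_exhaustive_permutation_matches_brute_force(self, rng):
        """3-vs-3, 5 signals: p-values equal enumeration over all 20 splits."""
        x = rng.lognormal(1.0, 0.6, size=(5, 6))
        table = make_table(x, ["a"] * 3 + ["b"] * 3)
        cfg = SamConfig(n_permutations=1000, s0_method="fixed", s0_fixed=0.1, seed=0)
        res = sam_two_class(table, "a", "b", cfg)
        assert res.exhaustive and res.n_permutations == 20
        d_oracle, p_oracle = brute_force_sam(x, 3, 3, s0=0.1)
        np.testing.assert_allclose(res.stats["score"], d_oracle, rtol=1e-12)
        np.testing.assert_allclose(res.stats["p_value"], p_oracle, atol=1e-12)

    def test_monte_carlo_close_to_exhaustive(self, rng):
        x = rng.lognormal(1.0, 0.6, size=(4, 12))
        x[0, 6:] *= 4
        table = make_table(x, ["a"] * 6 + ["b"] * 6)
        exact = sam_two_class(table, "a", "b",
                              SamConfig(n_permutations=10 ** 6, s0_method="fixed",
                                        s0_fixed=0.05, seed=0))
        mc = sam_two_class(table, "a", "b",
                           SamConfig(n_permutations=400, s0_method="fixed",
                                     s0_fixed=0.05, seed=1))
        assert exact.exhaustive and not mc.exhaustive
        np.testing.assert_allclose(mc.stats["p_value"], exact.stats["p_value"],
                                   atol=0.08)

    def test_fold_change_is_ratio_of_means(self):
        """Group means 6.01 and 17.52 give fold change 2.915."""
        x = np.vstack([
            np.concatenate([np.full(10, 6.01) + np.linspace(-1, 1, 10),
                            np.full(10, 17.52) + np.linspace(-2, 2, 10)]),
        ])
        table = make_table(x, ["control"] * 10 + ["metastatic"] * 10)
        res = sam_two_class(table, "control", "metastatic",
                            SamConfig(n_permutations=50, seed=0))
        assert res.stats["fold_change"].iloc[0] == pytest.approx(2.915, abs=5e-4)

    def test_score_invariant_to_constant_shift(self, rng):
        x = rng.normal(10, 2, size=(6, 14))
        table1 = make_table(x, ["a"] * 7 + ["b"] * 7)
        table2 = make_table(x + 100.0, ["a"] * 7 + ["b"] * 7)
        cfg = SamConfig(n_permutations=10, s0_method="fixed", s0_fixed=0.0, seed=0)
        r1 = sam_two_class(table1, "a", "b", cfg)
        r2 = sam_two_class(table2, "a", "b", cfg)
        np.testing.assert_allclose(r1.stats["score"], r2.stats["score"], rtol=1e-9)

    def test_score_invariant_to_sample_order(self, rng):
        x = rng.normal(10, 2, size=(6, 10))
        labels = ["a"] * 5 + ["b"] * 5
        perm = rng.permutation(10)
        t1 = make_table(x, labels)
        t2 = make_table(x[:, perm], [labels[i] for i in perm])
        cfg = SamConfig(n_permutations=10, s0_method="fixed", s0_fixed=0.1, seed=0)
        r1 = sam_two_class(t1, "a", "b", cfg)
        r2 = sam_two_class(t2, "a", "b", cfg)
        np.testing.assert_allclose(r1.stats["score"], r2.stats["score"], rtol=1e-9)

    def test_zero_variance_signal_flagged(self):
        x = np.vstack([np.ones(8), np.arange(8.0)])
        table = make_table(x, ["a"] * 4 + ["b"] * 4)
        res = sam_two_class(table, "a", "b", SamConfig(n_permutations=30, seed=0))
        assert bool(res.stats["zero_scatter"].iloc[0])
        assert np.isfinite(res.stats["score"]).all()

    def test_q_values_monotone_in_score_rank(self, rng):
        x = rng.lognormal(0, 0.5, size=(40, 30))
        x[:3, 15:] *= 3
        table = make_table(x, ["a"] * 15 + ["b"] * 15)
        res = sam_two_class(table, "a", "b", SamConfig(n_permutations=200, seed=0))
        df = res.stats.reindex(res.stats["score"].abs().sort_values(ascending=False).index)
        assert (np.diff(df["q_value"]) >= -1e-12).all()

    def test_group_too_small_errors(self):
        table = make_table(np.ones((2, 3)), ["a", "a", "b"])
        with pytest.raises(ValueError, match="need >= 2"):
            sam_two_class(table, "a", "b")


class TestRunAllComparisons:
    def test_three_comparisons_and_case_over_control_convention(self, rng):
        x = rng.lognormal(0, 0.3, size=(10, 24))
        labels = ["control"] * 8 + ["non_metastatic"] * 8 + ["metastatic"] * 8
        x[0, 8:] *= 6  # elevated in both patient groups
        table = make_table(x, labels)
        results, signature = sp.run_all_comparisons(
            table, SamConfig(n_permutations=200, seed=0))
        assert set(results) == {"control_vs_non_metastatic", "control_vs_metastatic",
                                "non_metastatic_vs_metastatic"}
        fc = results["control_vs_metastatic"].stats["fold_change"].iloc[0]
        assert fc > 1  # elevated in patients reads as fold > 1

    def test_missing_group_named_in_error(self, rng):
        table = make_table(rng.random((3, 8)), ["control"] * 4 + ["metastatic"] * 4)
        with pytest.raises(ValueError, match="non_metastatic"):
            sp.run_all_comparisons(table)

    def test_tiny_q_threshold_empties_signature(self, rng):
        x = rng.lognormal(0, 0.4, size=(8, 30))
        labels = ["control"] * 10 + ["non_metastatic"] * 10 + ["metastatic"] * 10
        _, signature = sp.run_all_comparisons(
            table := make_table(x, labels),
            SamConfig(n_permutations=100, q_threshold=1e-9, seed=0))
        assert signature.empty
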