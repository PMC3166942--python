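import numpy as np
import pandas as pd
import pytest

from rowcollapse.collapse import (
    CollapseConfig,
    CollapseConfigError,
    STRATEGIES,
    collapse,
    module_eigengene,
    row_score,
    select_representative,
    strategy,
    trim_fewest_missing,
)

from .oracles import oracle_collapse_selection


def _mat(rows, ids, cols=None):
    rows = np.asarray(rows, dtype=float)
    cols = cols or [f"s{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=ids, columns=cols)


class TestConfig:
    def test_rejects_unknown_method_and_bad_power(self):
        with pytest.raises(CollapseConfigError):
            CollapseConfig(method="median")
        with pytest.raises(CollapseConfigError):
            CollapseConfig(connectivity_power=0)

    def test_function_method_requires_aggregator_and_vice_versa(self):
        with pytest.raises(CollapseConfigError):
            CollapseConfig(method="function")
        with pytest.raises(CollapseConfigError):
            CollapseConfig(method="MaxMean", custom_aggregator=lambda m: m.mean(axis=0))

    def test_strategy_presets_match_documented_settings(self):
        assert STRATEGIES["1.max"].method == "MaxMean"
        assert not STRATEGIES["1.max"].connectivity_based
        assert STRATEGIES["3.kMax"].method == "MaxMean"
        assert STRATEGIES["3.kMax"].connectivity_based
        assert STRATEGIES["4.kVar"].method == "maxRowVariance"
        assert STRATEGIES["4.kVar"].connectivity_based
        assert STRATEGIES["5.ME"].method == "ME"
        assert STRATEGIES["6.Avg"].method == "average"
        with pytest.raises(CollapseConfigError):
            strategy("7.median")


class TestTrim:
    def test_keeps_only_fewest_missing_rows_per_group(self):
        m = _mat(
            [[1, 2, 3], [1, np.nan, np.nan], [1, 2, np.nan], [5, 6, 7]],
            ids=["a", "b", "c", "d"],
        )
        g = pd.Series({"a": "G1", "b": "G1", "c": "G1", "d": "G2"})
        out = trim_fewest_missing(m, g)
        assert list(out.index) == ["a", "d"]

    def test_complete_matrix_is_identity(self, small_matrix, small_groups):
        pd.testing.assert_frame_equal(
            trim_fewest_missing(small_matrix, small_groups), small_matrix
        )

    def test_singleton_group_survives_even_if_mostly_missing(self):
        m = _mat([[1, np.nan, np.nan, np.nan, 2]], ids=["only"])
        g = pd.Series({"only": "G"})
        assert list(trim_fewest_missing(m, g).index) == ["only"]


class TestScoresAndSelection:
    def test_scores_agree_with_hand_values(self):
        m = _mat([[1, 2, 3], [-3, 1, np.nan], [1, 3, 5]], ids=["a", "b", "c"])
        assert row_score(m, "MaxMean")["a"] == pytest.approx(2.0)
        assert row_score(m, "absMaxMean")["b"] == pytest.approx(2.0)
        # sample variance with n-1 denominator
        assert row_score(m, "maxRowVariance")["c"] == pytest.approx(4.0)

    def test_selection_directions(self):
        m = _mat([[5, 5], [3, 3]], ids=["p1", "p2"])
        assert select_representative(m, "MaxMean") == "p1"
        assert select_representative(m, "MinMean") == "p2"
        v = _mat([[1, 2, 3], [0, 3, 6]], ids=["lo", "hi"])
        assert select_representative(v, "maxRowVariance") == "hi"

    def test_variance_tie_broken_by_highest_mean(self):
        m = _mat([[1, 2, 3], [11, 12, 13]], ids=["low", "high"])
        assert select_representative(m, "maxRowVariance") == "high"

    def test_row_with_single_observation_loses_variance_contest(self):
        m = _mat([[np.nan, np.nan, 9], [1, 2, 3]], ids=["undef", "ok"])
        assert select_representative(m, "maxRowVariance") == "ok"

    def test_identical_rows_tie_is_seeded_and_reproducible(self):
        m = _mat([[1, 2, 3]] * 4, ids=["a", "b", "c", "d"])
        picks = {select_representative(m, "MaxMean", rng=0) for _ in range(5)}
        assert len(picks) == 1  # same seed, same choice
        all_seeds = {select_representative(m, "MaxMean", rng=s) for s in range(40)}
        assert len(all_seeds) > 1  # the choice is genuinely random across seeds


class TestCollapse:
    def test_one_row_per_group_with_representative_fidelity(
        self, small_matrix, small_groups
    ):
        res = collapse(small_matrix, small_groups, "MaxMean")
        assert sorted(res.matrix.index) == ["gA", "gB", "gC"]
        for group, rid in res.group_to_row.items():
            np.testing.assert_array_equal(
                res.matrix.loc[group].to_numpy(), small_matrix.loc[rid].to_numpy()
            )

    def test_maxmean_matches_bruteforce_argmax(self, small_matrix, small_groups):
        res = collapse(small_matrix, small_groups, "MaxMean")
        for group in ["gA", "gB", "gC"]:
            members = small_groups[small_groups == group].index
            expected = small_matrix.loc[members].mean(axis=1).idxmax()
            assert res.group_to_row[group] == expected

    def test_average_is_columnwise_group_mean(self, small_matrix, small_groups):
        res = collapse(small_matrix, small_groups, "average")
        for group in ["gA", "gB", "gC"]:
            members = small_groups[small_groups == group].index
            np.testing.assert_allclose(
                res.matrix.loc[group].to_numpy(),
                small_matrix.loc[members].mean(axis=0).to_numpy(),
            )
        assert res.group_to_row["gA"] == "<composite:average>"

    def test_average_ignores_missing_entries_per_column(self):
        # disable the fewest-missing trim so both rows contribute
        m = _mat([[1, np.nan], [3, 4]], ids=["a", "b"])
        g = pd.Series({"a": "G", "b": "G"})
        cfg = CollapseConfig(method="average", select_fewest_missing=False)
        out = collapse(m, g, cfg).matrix
        np.testing.assert_allclose(out.loc["G"].to_numpy(), [2.0, 4.0])

    def test_fewest_missing_trim_precedes_composite_aggregation(self):
        m = _mat([[1, np.nan], [3, 4]], ids=["a", "b"])
        g = pd.Series({"a": "G", "b": "G"})
        out = collapse(m, g, "average").matrix  # trim keeps only the complete row
        np.testing.assert_allclose(out.loc["G"].to_numpy(), [3.0, 4.0])

    def test_single_row_group_passes_through_under_any_method(self):
        m = _mat([[1.0, 2.0, 3.0]], ids=["solo"])
        g = pd.Series({"solo": "G"})
        for method in ["MaxMean", "maxRowVariance", "average"]:
            out = collapse(m, g, method).matrix
            np.testing.assert_allclose(out.loc["G"].to_numpy(), [1.0, 2.0, 3.0])

    def test_connectivity_dispatch_uses_hub_only_from_three_rows(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=20)
        # h is a clean copy of the shared signal; the others are noisy
        m = _mat(
            [s + 0.05 * rng.normal(size=20),
             s + 0.8 * rng.normal(size=20) - 1.0,
             s + 0.8 * rng.normal(size=20) - 1.0,
             rng.normal(size=20),
             rng.normal(size=20) + 5.0],
            ids=["h", "n1", "n2", "two_a", "two_b"],
        )
        g = pd.Series({"h": "G3", "n1": "G3", "n2": "G3", "two_a": "G2", "two_b": "G2"})
        res = collapse(m, g, strategy("3.kMax"))
        assert res.group_to_row["G3"] == "h"  # hub of the 3-row group
        assert res.group_to_row["G2"] == "two_b"  # 2-row group falls back to MaxMean

    def test_custom_aggregator_and_contract_error(self, small_matrix, small_groups):
        cfg = CollapseConfig(
            method="function",
            custom_aggregator=lambda rows: rows.median(axis=0).to_numpy(),
        )
        res = collapse(small_matrix, small_groups, cfg)
        members = small_groups[small_groups == "gC"].index
        np.testing.assert_allclose(
            res.matrix.loc["gC"].to_numpy(),
            small_matrix.loc[members].median(axis=0).to_numpy(),
        )
        bad = CollapseConfig(method="function", custom_aggregator=lambda rows: [1.0])
        with pytest.raises(CollapseConfigError, match="gA"):
            collapse(small_matrix, small_groups, bad)

    def test_permutation_invariance_without_ties(self, small_matrix, small_groups):
        res = collapse(small_matrix, small_groups, "MaxMean")
        shuffled = small_matrix.iloc[[4, 2, 0, 5, 1, 3]]
        res2 = collapse(shuffled, small_groups, "MaxMean")
        assert res.group_to_row == res2.group_to_row
        pd.testing.assert_frame_equal(res.matrix, res2.matrix)

    @pytest.mark.parametrize(
        "method", ["MaxMean", "MinMean", "absMaxMean", "absMinMean", "maxRowVariance"]
    )
    def test_oracle_equivalence_on_random_matrices(self, method):
        from .conftest import random_grouped_matrix

        for seed in range(12):
            matrix, groups = random_grouped_matrix(seed)
            res = collapse(matrix, groups, CollapseConfig(method=method))
            expected = oracle_collapse_selection(matrix, groups, method, False)
            assert res.group_to_row == expected


class TestModuleEigengene:
    def test_identical_rows_give_me_perfectly_correlated_with_them(self):
        m = _mat([[1, 2, 3]] * 3, ids=["a", "b", "c"])
        me = module_eigengene(m)
        assert np.corrcoef(me, [1, 2, 3])[0, 1] == pytest.approx(1.0)
        assert np.linalg.norm(me) == pytest.approx(1.0)

    def test_sign_flip_pair_is_deterministic(self):
        x = np.array([1.0, -2.0, 0.5, 3.0])
        m = _mat([x, -x], ids=["plus", "minus"])
        me1 = module_eigengene(m)
        me2 = module_eigengene(m)
        np.testing.assert_array_equal(me1, me2)
        assert np.linalg.norm(me1) == pytest.approx(1.0)

    def test_first_pc_explains_most_variance(self):
        rng = np.random.default_rng(8)
        m = _mat(rng.normal(size=(5, 10)), ids=list("abcde"))
        me = module_eigengene(m)
        z = (m.to_numpy() - m.to_numpy().mean(axis=1, keepdims=True)) / m.to_numpy().std(
            axis=1, keepdims=True
        )
        # projection variance of the eigengene direction vs any single row direction
        me_var = np.linalg.norm(z @ me) ** 2
        for i in range(5):
            direction = z[i] / np.linalg.norm(z[i])
            assert me_var >= np.linalg.norm(z @ direction) ** 2 - 1e-9
        # and matches the top singular value from an independent decomposition
        top_sv = np.linalg.svd(z, compute_uv=False)[0]
        assert me_var == pytest.approx(top_sv**2)

    def test_constant_group_returns_zeros_with_warning(self):
        m = _mat([[2, 2, 2], [5, 5, 5]], ids=["a", "b"])
        np.testing.assert_array_equal(module_eigengene(m), np.zeros(3))

    def test_me_orientation_follows_group_mean(self):
        rng = np.random.default_rng(9)
        s = rng.normal(size=12)
        m = _mat([s + 0.1 * rng.normal(size=12) for _ in range(4)], ids=list("abcd"))
        me = module_eigengene(m)
        assert np.corrcoef(me, m.to_numpy().mean(axis=0))[0, 1] > 0.9
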