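import itertools
import math

import numpy as np
import pytest

from prophagepop import diversity as dv


class TestUncertaintyCoefficient:
    def test_bijective_association_gives_one(self):
        res = dv.uncertainty_coefficient(list("aabb"), list("ppqq"))
        assert res.U_x_given_y == pytest.approx(1.0)
        assert res.U_y_given_x == pytest.approx(1.0)

    def test_exact_independence_gives_zero(self):
        res = dv.uncertainty_coefficient(list("abab"), list("ppqq"))
        assert res.mutual_information == pytest.approx(0.0, abs=1e-12)
        assert res.U_x_given_y == pytest.approx(0.0, abs=1e-12)
        assert res.U_y_given_x == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_three_point_example(self):
        res = dv.uncertainty_coefficient(list("aab"), list("pqq"))
        assert res.H_x == pytest.approx(0.6365, abs=1e-3)
        assert res.H_x_given_y == pytest.approx(0.4621, abs=1e-3)
        assert res.U_x_given_y == pytest.approx(0.2740, abs=1e-3)

    def test_degenerate_variable_is_fully_explained(self):
        res = dv.uncertainty_coefficient(["a", "a", "a"], ["p", "q", "p"])
        assert res.U_x_given_y == 1.0

    def test_base_invariance(self):
        x, y = list("aabbabca"), list("ppqqpqrp")
        res = dv.uncertainty_coefficient(x, y)
        # recompute U from base-2 entropies: the ratio is base-free
        ratio = math.log(2)
        u2 = (res.mutual_information / ratio) / (res.H_x / ratio)
        assert u2 == pytest.approx(res.U_x_given_y, abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            dv.uncertainty_coefficient(["a"], ["p", "q"])


class TestKruskalWallis:
    def test_two_group_rank_example(self):
        res = dv.kruskal_wallis([[1, 2], [3, 4]])
        assert res.statistic == pytest.approx(2.4)

    def test_identical_groups_give_zero(self):
        res = dv.kruskal_wallis([[5, 5, 5], [5, 5]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_type_one_error_calibration(self):
        rejections = 0
        n_rep = 400
        for i in range(n_rep):
            r = np.random.default_rng(1000 + i)
            groups = [r.normal(size=12) for _ in range(3)]
            rejections += dv.kruskal_wallis(groups).p_value <= 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            dv.kruskal_wallis([[1, 2], []])


class TestMannWhitneyHolm:
    def test_exact_small_sample_p(self):
        res = dv.mann_whitney_pairwise_holm([[1, 2], [3, 4]])
        row = res.pairwise.iloc[0]
        assert row["U"] == 0.0
        assert row["p_raw"] == pytest.approx(1 / 3, abs=1e-9)

    def test_identical_groups_p_one(self):
        res = dv.mann_whitney_pairwise_holm([[7, 7, 7], [7, 7, 7]])
        assert res.pairwise["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_holm_stepdown_example(self):
        adj = dv.holm_adjust([0.01, 0.04, 0.03])
        assert np.allclose(adj, [0.03, 0.06, 0.06])

    def test_holm_never_decreases_and_contains_bonferroni_rejections(self, rng):
        p = rng.uniform(size=10)
        adj = dv.holm_adjust(p)
        assert np.all(adj >= p - 1e-15)
        bonf = np.minimum(p * len(p), 1.0)
        assert set(np.where(bonf <= 0.05)[0]) <= set(np.where(adj <= 0.05)[0])

    def test_all_pairs_present(self):
        res = dv.mann_whitney_pairwise_holm({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        assert len(res.pairwise) == 3


def enumerate_expected_richness(counts, m):
    """Exhaustive expectation over all C(N, m) subsamples (oracle)."""
    individuals = []
    for sp, c in enumerate(counts):
        individuals.extend([sp] * c)
    total = 0
    n_subsets = 0
    for subset in itertools.combinations(range(len(individuals)), m):
        total += len({individuals[i] for i in subset})
        n_subsets += 1
    return total / n_subsets


class TestRarefaction:
    def test_all_singletons(self):
        assert dv.rarefy_expected_richness([1] * 8, 5) == pytest.approx(5.0)

    def test_single_species(self):
        assert dv.rarefy_expected_richness([9], 4) == pytest.approx(1.0)

    def test_two_one_community_at_depth_two(self):
        assert dv.rarefy_expected_richness([2, 1], 2) == pytest.approx(5 / 3)

    @pytest.mark.parametrize(
        "counts", [(2, 1), (3, 2, 1), (4, 4), (5, 3, 2, 1), (6, 1, 1)]
    )
    def test_matches_enumeration_oracle(self, counts):
        n = sum(counts)
        for m in range(0, n + 1):
            assert dv.rarefy_expected_richness(counts, m) == pytest.approx(
                enumerate_expected_richness(counts, m), abs=1e-9
            )

    def test_depth_beyond_total_raises(self):
        with pytest.raises(ValueError):
            dv.rarefy_expected_richness([2, 2], 5)

    def test_negative_depth_raises(self):
        with pytest.raises(ValueError):
            dv.rarefy_expected_richness([2, 2], -1)


class TestDepthRule:
    def test_isolation_source_depth_is_102(self):
        totals = {"animal": 300, "clinical": 136, "environmental": 500, "human": 2200}
        depth, retained = dv.rarefaction_depth_rule(totals, fraction=0.75)
        assert depth == 102
        assert retained == sorted(totals)

    def test_host_filter_depth_is_63(self):
        depth, retained = dv.rarefaction_depth_rule(
            {"h1": 84, "h2": 200, "h3": 20}, fraction=0.75, min_total=50
        )
        assert depth == 63
        assert retained == ["h1", "h2"]

    def test_single_group(self):
        depth, _ = dv.rarefaction_depth_rule({"g": 100}, fraction=0.75)
        assert depth == 75

    def test_no_group_survives_raises(self):
        with pytest.raises(ValueError):
            dv.rarefaction_depth_rule({"g": 10}, min_total=50)


class TestRarefactionCurve:
    def test_endpoints_and_monotone_concave(self):
        counts = (5, 3, 2)
        curve = dv.rarefaction_curve(counts, list(range(1, 11)))
        values = [v for _, v in curve]
        assert values[0] == pytest.approx(1.0)
        assert values[-1] == pytest.approx(3.0)
        diffs = np.diff(values)
        assert np.all(diffs >= -1e-12)
        assert np.all(np.diff(diffs) <= 1e-12)

    def test_matches_monte_carlo(self):
        counts = np.array([40, 25, 10, 5, 3, 1, 1])
        n = counts.sum()
        pool = np.repeat(np.arange(len(counts)), counts)
        r = np.random.default_rng(77)
        for m in (5, 20, 60):
            draws = np.array(
                [len(np.unique(r.choice(pool, size=m, replace=False))) for _ in range(2000)]
            )
            se = draws.std(ddof=1) / np.sqrt(len(draws))
            assert abs(dv.rarefy_expected_richness(counts, m) - draws.mean()) <= 3 * se

    def test_unsorted_depths_raise(self):
        with pytest.raises(ValueError):
            dv.rarefaction_curve([3, 2], [4, 2])


def test_community_matrix_counts():
    species = {"p1": "s1", "p2": "s1", "p3": "s2", "p4": "s3"}
    groups = {"p1": "human", "p2": "animal", "p3": "human", "p4": "human"}
    cm = dv.community_matrix(species, groups)
    assert cm.loc["human", "s1"] == 1
    assert cm.loc["animal", "s1"] == 1
    assert cm.loc["human"].sum() == 3
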