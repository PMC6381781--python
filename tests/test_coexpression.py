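import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qcoexp import (
    BaitSet,
    CoexpressionEdge,
    DiscretizationParams,
    ScreenParams,
    ValidationError,
    bf_null_pvalue,
    bf_score,
    compare_methods,
    condition_support_module,
    discretize_matrix,
    expected_null_bf,
    pearson_score,
    screen_baits,
)


def brute_force_bf(a, b, allow_opposite=False):
    """Position-by-position reference count, independent of the implementation."""
    n_same = sum(1 for x, y in zip(a, b) if x == y and x != 0)
    if not allow_opposite:
        return n_same
    n_opp = sum(1 for x, y in zip(a, b) if x == -y and x != 0)
    return n_same + n_opp


level_vectors = st.integers(2, 200).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(-1, 1), min_size=n, max_size=n),
        st.lists(st.integers(-1, 1), min_size=n, max_size=n),
    )
)


class TestBfScore:
    def test_self_match_counts_non_zeros(self):
        a = np.array([1, 0, -1, 1])
        bf, support, sign = bf_score(a, a)
        assert bf == 3
        assert set(support) == {0, 2, 3}
        assert sign == 1

    def test_opposite_profiles_score_zero_in_same_sign_mode(self):
        bf, support, _ = bf_score(np.array([1, 1, 1]), np.array([-1, -1, -1]))
        assert bf == 0 and support.size == 0

    def test_opposite_profiles_count_under_allow_opposite(self):
        bf, support, sign = bf_score(
            np.array([1, 1, 1]), np.array([-1, -1, -1]), "allow-opposite"
        )
        assert bf == 3 and sign == -1 and set(support) == {0, 1, 2}

    def test_majority_sign_under_allow_opposite(self):
        a = np.array([1, 1, -1, 0])
        b = np.array([1, 1, 1, 0])
        bf, _, sign = bf_score(a, b, "allow-opposite")
        assert bf == 3 and sign == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="shape"):
            bf_score(np.array([1, 0]), np.array([1, 0, 1]))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(pair=level_vectors, opposite=st.booleans())
    def test_matches_brute_force_and_is_symmetric(self, pair, opposite):
        a, b = np.array(pair[0]), np.array(pair[1])
        mode = "allow-opposite" if opposite else "same-sign-only"
        bf_ab, support, _ = bf_score(a, b, mode)
        bf_ba, _, _ = bf_score(b, a, mode)
        assert bf_ab == brute_force_bf(a, b, opposite)
        assert bf_ab == bf_ba
        assert bf_ab == len(support) <= a.size


class TestNullPvalue:
    def test_all_zero_profile_gives_p_one_conservatively(self):
        a = np.zeros(30, dtype=int)
        b = np.array([1, -1] * 15)
        params = ScreenParams(n_permutations=200, tie_break="conservative")
        assert bf_null_pvalue(0, a, b, params) == 1.0

    def test_identical_dense_profiles_are_significant(self, rng):
        a = rng.choice([-1, 0, 1], size=93, p=[0.25, 0.5, 0.25])
        bf, _, _ = bf_score(a, a)
        p = bf_null_pvalue(bf, a, a, ScreenParams(n_permutations=1000, rng_seed=4))
        assert p <= 0.01

    def test_monotone_non_increasing_in_bf_for_fixed_margins(self, rng):
        a = rng.choice([-1, 0, 1], size=60, p=[0.15, 0.7, 0.15])
        b = rng.choice([-1, 0, 1], size=60, p=[0.15, 0.7, 0.15])
        for mode in ("conservative", "randomized"):
            params = ScreenParams(n_permutations=500, rng_seed=9, tie_break=mode)
            ps = [bf_null_pvalue(k, a, b, params) for k in range(0, 12)]
            assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_deterministic_for_fixed_seed_and_pair(self, rng):
        a = rng.choice([-1, 0, 1], size=50)
        b = rng.choice([-1, 0, 1], size=50)
        params = ScreenParams(n_permutations=300, rng_seed=13)
        p1 = bf_null_pvalue(3, a, b, params, "bait", "partner")
        p2 = bf_null_pvalue(3, a, b, params, "bait", "partner")
        assert p1 == p2
        assert p1 != bf_null_pvalue(3, a, b, params, "bait", "other")

    def test_permutation_mean_matches_closed_form(self, rng):
        """E[BF] under permutation = sum_k n_k(a) n_k(b) / n, within 3 SE."""
        a = rng.choice([-1, 0, 1], size=93, p=[0.1, 0.8, 0.1])
        b = rng.choice([-1, 0, 1], size=93, p=[0.1, 0.8, 0.1])
        nperm = 4000
        perm_rng = np.random.default_rng(21)
        perms = perm_rng.permuted(np.broadcast_to(b, (nperm, b.size)).copy(), axis=1)
        scores = ((perms == a) & (a != 0)).sum(axis=1)
        expected = expected_null_bf(a, b)
        se = scores.std(ddof=1) / np.sqrt(nperm)
        assert abs(scores.mean() - expected) < 3 * se

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValidationError):
            ScreenParams(n_permutations=0)

    def test_few_permutations_warn(self):
        with pytest.warns(UserWarning, match="coarse"):
            ScreenParams(n_permutations=50)


class TestScreenBaits:
    def test_min_bf_above_condition_count_returns_nothing(self, planted, baits2):
        _, d, _ = planted
        params = ScreenParams(min_bf=d.n_conditions + 1, n_permutations=100)
        assert screen_baits(d, baits2, params) == []

    def test_planted_partners_recovered_with_planted_support(self, planted, baits2, fast_params):
        """Near-zero noise: every planted pair must surface with BF equal to
        the planted subset size and exactly the planted conditions."""
        _, d, truth = planted
        edges = screen_baits(d, baits2, fast_params)
        found = {(e.bait_id, e.partner_id): e for e in edges}
        for t in truth:
            e = found[(t.bait_id, t.partner_id)]
            assert e.bf == len(t.conditions)
            assert e.support == t.conditions
            assert e.pvalue <= fast_params.alpha

    def test_edges_sorted_by_bait_then_descending_bf(self, planted, baits2, fast_params):
        _, d, _ = planted
        edges = screen_baits(d, baits2, fast_params)
        keys = [(e.bait_id, -e.bf, e.partner_id) for e in edges]
        assert keys == sorted(keys)
        assert all(e.bait_id != e.partner_id for e in edges)

    def test_missing_bait_warns_and_continues(self, planted, fast_params, caplog):
        import logging

        _, d, _ = planted
        with caplog.at_level(logging.WARNING, logger="qcoexp"):
            edges = screen_baits(d, BaitSet(("B01", "NOT_THERE")), fast_params)
        assert any("NOT_THERE" in r.message for r in caplog.records)
        assert {e.bait_id for e in edges} == {"B01"}

    def test_no_bait_present_is_an_error(self, planted, fast_params):
        _, d, _ = planted
        with pytest.raises(ValidationError, match="no bait"):
            screen_baits(d, BaitSet(("nope",)), fast_params)

    def test_deterministic_across_calls(self, planted, baits2, fast_params):
        _, d, _ = planted
        assert screen_baits(d, baits2, fast_params) == screen_baits(d, baits2, fast_params)


def _edge(bait, partner, support, bf=None):
    s = frozenset(support)
    return CoexpressionEdge(bait, partner, bf if bf is not None else len(s), s, 1, 0.001)


class TestConditionSupportModule:
    def test_identical_support_collapses_to_one_group(self):
        sup = {"c1", "c2", "c3"}
        groups = condition_support_module([_edge("b", "x", sup), _edge("b", "y", sup)])
        assert groups == [(frozenset(sup), {"x", "y"})]

    def test_disjoint_supports_stay_separate_at_full_consistency(self):
        groups = condition_support_module(
            [_edge("b", "x", {"c1", "c2"}), _edge("b", "y", {"c3", "c4"})],
            consistency=1.0,
        )
        assert len(groups) == 2
        assert {tuple(sorted(g)) for _, g in groups} == {("x",), ("y",)}

    def test_planted_two_module_structure_recovered(self, planted, fast_params):
        _, d, truth = planted
        by_bait = {}
        for t in truth:
            by_bait.setdefault(t.bait_id, t.conditions)
        for bait, conditions in by_bait.items():
            edges = screen_baits(d, BaitSet((bait,)), fast_params)
            planted_edges = [e for e in edges if e.partner_id.startswith(bait)]
            groups = condition_support_module(planted_edges, consistency=0.95)
            assert groups[0][0] == conditions

    def test_mixed_baits_rejected(self):
        with pytest.raises(ValidationError, match="several baits"):
            condition_support_module([_edge("a", "x", {"c"}), _edge("b", "y", {"c"})])


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2, 3, 4])
        assert pearson_score(x, 2 * x + 1) == pytest.approx(1.0)

    def test_orthogonal_profiles(self):
        assert pearson_score(
            np.array([1.0, -1, 1, -1]), np.array([1.0, 1, -1, -1])
        ) == pytest.approx(0.0)

    def test_matches_closed_form_sum_formula(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        n = x.size
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = np.sqrt(n * (x ** 2).sum() - x.sum() ** 2) * np.sqrt(
            n * (y ** 2).sum() - y.sum() ** 2
        )
        assert pearson_score(x, y) == pytest.approx(num / den, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="zero-variance"):
            pearson_score(np.ones(5), np.arange(5.0))

    def test_short_profiles_rejected(self):
        with pytest.raises(ValidationError, match=">= 3"):
            pearson_score(np.array([1.0, 2]), np.array([2.0, 1]))


class TestCompareMethods:
    def test_bait_excluded_and_both_scores_present(self, planted, fast_params):
        matrix, d, _ = planted
        table = compare_methods(matrix, "B01", DiscretizationParams(q=0.25), fast_params, d=d)
        assert "B01" not in table.index
        assert list(table.columns) == ["bf", "bf_p", "pcc"]
        assert len(table) == matrix.n_genes - 1

    def test_planted_partner_ranks_in_top_decile_by_bf(self, planted, fast_params):
        matrix, d, truth = planted
        table = compare_methods(matrix, "B01", DiscretizationParams(q=0.25), fast_params, d=d)
        partners = [t.partner_id for t in truth if t.bait_id == "B01"]
        cutoff = table["bf"].quantile(0.9)
        assert (table.loc[partners, "bf"] >= cutoff).all()

    def test_unknown_bait_rejected(self, planted, fast_params):
        matrix, _, _ = planted
        with pytest.raises(ValidationError, match="absent"):
            compare_methods(matrix, "missing", DiscretizationParams(q=0.25), fast_params)
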