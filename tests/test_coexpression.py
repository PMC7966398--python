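"""R_sum sweep: Pearson/Spearman oracles, ranking semantics, extremes."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coexmod import (
    NormalizedMatrix,
    CorrelationProfile,
    pearson_profile,
    rsum_ranking,
    extract_extreme,
    spearman_confirm,
    correlation_count,
)
from coexmod.errors import ConfigurationError, DataError


def _norm(values, name="t"):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        values=values,
        factors=np.ones(values.shape[1]),
        tissue_name=name,
    )


def _pearson_oracle(x, y):
    """From-scratch covariance-formula Pearson coefficient."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def _midranks(v):
    """Average ranks for ties, 1-based."""
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for p in range(i, j + 1):
            ranks[order[p]] = avg
        i = j + 1
    return ranks


class TestPearsonProfile:
    def test_identical_gene_has_r_one(self, toy_norm):
        prof = pearson_profile(toy_norm, "g0")
        assert prof.r["g1"] == pytest.approx(1.0, abs=1e-12)
        assert prof.r["g0"] == 1.0

    def test_affine_anticorrelate_has_r_minus_one(self, toy_norm):
        prof = pearson_profile(toy_norm, "g0")
        assert prof.r["g2"] == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_gene_is_flagged_undefined(self, toy_norm):
        prof = pearson_profile(toy_norm, "g0")
        assert np.isnan(prof.r["g3"])

    def test_agrees_with_covariance_oracle_to_1e12(self):
        rng = np.random.default_rng(17)
        values = rng.normal(size=(6, 6))
        norm = _norm(values)
        prof = pearson_profile(norm, "g0")
        for i in range(1, 6):
            expected = _pearson_oracle(values[0], values[i])
            assert prof.r[f"g{i}"] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_seed_raises(self, toy_norm):
        with pytest.raises(DataError):
            pearson_profile(toy_norm, "g3")

    def test_missing_seed_raises(self, toy_norm):
        with pytest.raises(DataError):
            pearson_profile(toy_norm, "nope")


def _profile(tissue, r_map, seed="g0", n=10):
    return CorrelationProfile(
        tissue_name=tissue, seed_gene_id=seed,
        r=pd.Series(r_map), n_samples=n,
    )


class TestRsumRanking:
    def _hand_profiles(self):
        # 5 genes x 3 tissues, hand-written r tables
        t1 = {"g0": 1.0, "g1": 0.8, "g2": -0.2, "g3": 0.5, "g4": 0.0}
        t2 = {"g0": 1.0, "g1": 0.6, "g2": 0.1, "g3": 0.5, "g4": np.nan}
        t3 = {"g0": 1.0, "g1": 0.9, "g2": -0.5, "g3": 0.4, "g4": 0.3}
        return [_profile(f"t{i}", r) for i, r in enumerate((t1, t2, t3))]

    def test_matches_manual_summation(self):
        rk = rsum_ranking(self._hand_profiles())
        assert rk.rsum["g0"] == pytest.approx(3.0)
        assert rk.rsum["g1"] == pytest.approx(2.3)
        assert rk.rsum["g2"] == pytest.approx(-0.6)
        assert rk.rsum["g3"] == pytest.approx(1.4)
        assert rk.rsum["g4"] == pytest.approx(0.3)   # NaN contributes 0
        assert list(rk.rank[["g0", "g1", "g3", "g4", "g2"]]) == [1, 2, 3, 4, 5]

    def test_seed_attains_tissue_count_exactly(self, small_ranking, small_collection):
        cfg, _, truth = small_collection
        assert small_ranking.rsum[truth.seed_gene_id] == float(cfg.n_tissues)
        assert small_ranking.rank[truth.seed_gene_id] == 1

    def test_rsum_bounded_by_tissue_count(self, small_ranking):
        T = len(small_ranking.tissues_used)
        assert (small_ranking.rsum.abs() <= T + 1e-12).all()

    def test_ranks_are_a_permutation(self, small_ranking):
        assert sorted(small_ranking.rank) == list(range(1, small_ranking.n_genes + 1))

    def test_gene_undefined_everywhere_scores_zero(self):
        profs = self._hand_profiles()
        for p in profs:
            p.r["g4"] = np.nan
        rk = rsum_ranking(profs, policy="zero")
        assert rk.rsum["g4"] == 0.0

    def test_drop_gene_policy_removes_partially_undefined_genes(self):
        rk = rsum_ranking(self._hand_profiles(), policy="drop-gene")
        assert "g4" not in rk.rsum.index
        assert rk.n_genes == 4

    def test_ties_break_lexicographically(self):
        r = {"g0": 1.0, "gb": 0.5, "ga": 0.5}
        rk = rsum_ranking([_profile("t", r)])
        assert rk.rank["ga"] == 2 and rk.rank["gb"] == 3

    def test_universe_is_intersection_with_drop_count(self):
        p1 = _profile("t1", {"g0": 1.0, "g1": 0.5, "g2": 0.2})
        p2 = _profile("t2", {"g0": 1.0, "g1": 0.3, "g9": 0.8})
        rk = rsum_ranking([p1, p2])
        assert set(rk.rsum.index) == {"g0", "g1"}
        assert rk.n_dropped_genes == 2

    def test_all_undefined_tissue_leaves_order_unchanged(self):
        profs = self._hand_profiles()
        base_order = rsum_ranking(profs).rank.sort_values().index.tolist()
        dead = _profile("dead", {g: np.nan for g in ("g0", "g1", "g2", "g3", "g4")})
        order = rsum_ranking(profs + [dead]).rank.sort_values().index.tolist()
        assert order == base_order

    def test_antisymmetry_negating_gene_negates_rsum(self):
        rng = np.random.default_rng(23)
        mats = [rng.normal(size=(6, 12)) for _ in range(3)]
        rs_before = rsum_ranking(
            [pearson_profile(_norm(m, f"t{i}"), "g0") for i, m in enumerate(mats)]
        ).rsum["g4"]
        for m in mats:
            m[4] = -m[4]
        rs_after = rsum_ranking(
            [pearson_profile(_norm(m, f"t{i}"), "g0") for i, m in enumerate(mats)]
        ).rsum["g4"]
        assert rs_after == pytest.approx(-rs_before, abs=1e-12)

    def test_empty_profile_list_raises(self):
        with pytest.raises(DataError):
            rsum_ranking([])

    def test_mismatched_seeds_raise(self):
        p1 = _profile("t1", {"g0": 1.0}, seed="g0")
        p2 = _profile("t2", {"g1": 1.0}, seed="g1")
        with pytest.raises(DataError):
            rsum_ranking([p1, p2])


class TestExtractExtreme:
    def test_full_k_returns_whole_universe(self, small_ranking):
        mod = extract_extreme(small_ranking, k=small_ranking.n_genes, include_seed=True)
        assert set(mod.member_gene_ids) == set(small_ranking.rsum.index)

    def test_k_one_with_seed_is_the_seed(self, small_ranking):
        mod = extract_extreme(small_ranking, k=1, include_seed=True)
        assert mod.member_gene_ids == [small_ranking.seed_gene_id]

    def test_seed_excluded_by_default(self, small_ranking):
        mod = extract_extreme(small_ranking, k=10)
        assert small_ranking.seed_gene_id not in mod
        assert len(mod.member_gene_ids) == 10

    def test_members_are_top_ranks_in_order(self, small_ranking):
        mod = extract_extreme(small_ranking, k=5, include_seed=True)
        ranks = [small_ranking.rank[g] for g in mod.member_gene_ids]
        assert ranks == [1, 2, 3, 4, 5]

    @pytest.mark.parametrize("k", [0, -3, 10**6])
    def test_k_out_of_range_raises(self, small_ranking, k):
        with pytest.raises(ConfigurationError):
            extract_extreme(small_ranking, k=k)


class TestSpearmanConfirm:
    def test_monotone_transform_gives_rho_one(self):
        x = np.array([0.1, 2.0, -1.0, 3.0, 0.5, 7.0])
        values = np.vstack([x, np.exp(x)])
        res = spearman_confirm(_norm(values), "g0", "g1")
        assert res.rho == pytest.approx(1.0)
        assert not res.undefined

    def test_reversed_ordering_gives_rho_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        values = np.vstack([x, -(x**3)])
        res = spearman_confirm(_norm(values), "g0", "g1")
        assert res.rho == pytest.approx(-1.0)

    def test_tied_data_matches_hand_midrank_oracle(self):
        a = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0]   # tie at 1.0
        b = [2.0, 7.0, 1.0, 8.0, 2.0, 3.0, 6.0, 4.0]   # tie at 2.0
        res = spearman_confirm(_norm(np.vstack([a, b])), "g0", "g1")
        expected = _pearson_oracle(_midranks(a), _midranks(b))
        assert res.rho == pytest.approx(expected, abs=1e-12)
        # two-sided t approximation with n - 2 df
        n, rho = len(a), expected
        t = rho * math.sqrt((n - 2) / (1 - rho**2))
        from scipy.stats import t as tdist
        assert res.p_value == pytest.approx(2 * tdist.sf(abs(t), n - 2), rel=1e-9)

    def test_zero_rank_variance_is_flagged_not_zero(self):
        values = np.vstack([np.ones(5), np.arange(5.0)])
        res = spearman_confirm(_norm(values), "g0", "g1")
        assert res.undefined and np.isnan(res.rho)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_spearman_equals_pearson_on_midranks(self, seed):
        rng = np.random.default_rng(seed)
        values = np.round(rng.normal(size=(2, 12)), 1)   # rounding forces ties
        if np.all(values[0] == values[0][0]) or np.all(values[1] == values[1][0]):
            return
        res = spearman_confirm(_norm(values), "g0", "g1")
        expected = _pearson_oracle(_midranks(list(values[0])), _midranks(list(values[1])))
        assert res.rho == pytest.approx(expected, abs=1e-12)


class TestCorrelationCount:
    def test_paper_scale_exceeds_one_million(self):
        assert correlation_count(56202, 20) == 1_124_040 > 10**6

    @pytest.mark.parametrize("g,t,expected", [(1, 1, 1), (5000, 20, 100_000)])
    def test_arithmetic(self, g, t, expected):
        assert correlation_count(g, t) == expected

    def test_nonpositive_raises(self):
        with pytest.raises(ConfigurationError):
            correlation_count(0, 5)
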