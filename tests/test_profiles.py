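"""Phylogenetic-profile metrics against hand computations and
brute-force enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genomecontext import profiles
from genomecontext.iokit import HomologyHit
from genomecontext.profiles import (ProfilePairCounts, build_profiles,
                                    count_runs, pair_counts,
                                    pp_hypergeom_pval, pp_jaccard,
                                    pp_mutual_info, pp_pearson,
                                    pp_weighted_pval, pp_wpval_with_runs,
                                    runs_pvalue, score_all_pairs_pp)


def brute_force_weighted_pval(p1, p2, weights):
    """Independent oracle: enumerate every pair of binary vectors, weight
    each outcome by the product of Bernoulli(w_i) probabilities, condition
    on the observed numbers of ones, and sum the co-occurrence tail."""
    p1, p2 = np.asarray(p1), np.asarray(p2)
    M = p1.size
    n1, n2, obs = int(p1.sum()), int(p2.sum()), int((p1 & p2).sum())
    total = tail = 0.0
    for v1 in itertools.product((0, 1), repeat=M):
        if sum(v1) != n1:
            continue
        pr1 = math.prod(w if b else 1 - w for b, w in zip(v1, weights))
        for v2 in itertools.product((0, 1), repeat=M):
            if sum(v2) != n2:
                continue
            pr2 = math.prod(w if b else 1 - w for b, w in zip(v2, weights))
            both = sum(a & b for a, b in zip(v1, v2))
            total += pr1 * pr2
            if both >= obs:
                tail += pr1 * pr2
    return tail / total


class TestBuildProfiles:
    def test_strict_threshold_inequality(self):
        hits = [HomologyHit("g1", "o1", "r1", 1e-5, 90),
                HomologyHit("g1", "o2", "r2", 1e-4, 90)]
        prof = build_profiles(hits, ["g1", "g2"], ["o1", "o2"], e_threshold=1e-4)
        assert prof.row("g1").tolist() == [1, 0]  # 1e-4 itself excluded
        assert prof.row("g2").tolist() == [0, 0]

    def test_empty_organism_list_rejected(self):
        with pytest.raises(ValueError):
            build_profiles([], ["g1"], [], 1e-4)


class TestSimpleMetrics:
    def test_pair_counts_contingency(self):
        c = pair_counts([1, 1, 0, 0], [1, 0, 1, 0])
        assert (c.M, c.n1_1, c.n2_1, c.n11, c.n00) == (4, 2, 2, 1, 1)

    @pytest.mark.parametrize("p1,p2,expected", [
        ([1, 1, 0, 0], [1, 0, 1, 0], 1 / 3),
        ([1, 1, 0, 0], [1, 1, 0, 0], 1.0),
        ([0, 0, 0], [0, 0, 0], 0.0),      # both empty: no evidence
    ])
    def test_jaccard(self, p1, p2, expected):
        assert pp_jaccard(pair_counts(p1, p2)) == pytest.approx(expected)

    @pytest.mark.parametrize("p1,p2,expected", [
        ([1, 1, 0, 0], [1, 1, 0, 0], 1.0),
        ([1, 0], [0, 1], -1.0),
        ([1, 1, 1], [1, 0, 1], 0.0),      # constant profile: no evidence
    ])
    def test_pearson(self, p1, p2, expected):
        assert pp_pearson(p1, p2) == pytest.approx(expected)

    def test_mutual_info_identical_profiles_is_ln2(self):
        c = pair_counts([1, 1, 0, 0], [1, 1, 0, 0])
        assert pp_mutual_info(c) == pytest.approx(math.log(2))

    def test_mutual_info_independent_joint_is_zero(self):
        assert pp_mutual_info(pair_counts([1, 1, 0, 0], [1, 0, 1, 0])) == 0.0
        assert pp_mutual_info(pair_counts([1, 1, 1, 1], [1, 0, 1, 0])) == 0.0

    @pytest.mark.parametrize("p1,p2,expected", [
        ([1, 1, 0, 0], [1, 1, 0, 0], 1 / 6),   # 1 of C(4,2) placements
        ([1, 1, 0, 0], [0, 0, 1, 1], 1.0),     # overlap 0: whole support
        ([1, 0, 0], [1, 0, 0], 1 / 3),
    ])
    def test_hypergeom_pval(self, p1, p2, expected):
        assert pp_hypergeom_pval(pair_counts(p1, p2)) == pytest.approx(expected)

    def test_hypergeom_tail_decreases_with_overlap(self):
        tails = [pp_hypergeom_pval(ProfilePairCounts(10, 5, 4, k))
                 for k in range(5)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))


class TestWeightedPval:
    def test_equal_weights_reduce_to_hypergeometric(self):
        p1, p2 = [1, 1, 0, 0], [1, 1, 0, 0]
        assert pp_weighted_pval(p1, p2, [0.5] * 4) == pytest.approx(1 / 6, abs=1e-12)

    def test_overlap_zero_gives_one(self):
        assert pp_weighted_pval([1, 0, 0], [0, 1, 0], [0.9, 0.5, 0.1]) == 1.0

    @pytest.mark.parametrize("p1,p2,w", [
        ([1, 0, 0], [1, 0, 0], [0.9, 0.5, 0.1]),
        ([1, 1, 0, 0], [1, 0, 1, 0], [0.8, 0.6, 0.4, 0.2]),
        ([1, 1, 1, 0, 0], [1, 1, 0, 1, 0], [0.9, 0.7, 0.5, 0.3, 0.2]),
    ])
    def test_matches_brute_force_enumeration(self, p1, p2, w):
        got = pp_weighted_pval(p1, p2, w)
        want = brute_force_weighted_pval(np.array(p1), np.array(p2), w)
        assert got == pytest.approx(want, abs=1e-12)


class TestRuns:
    @pytest.mark.parametrize("vec,expected", [
        ([1, 1, 0, 1], 2), ([0, 0, 0], 0), ([1, 0, 1, 0, 1], 3),
        ([1, 1, 1], 1), ([], 0),
    ])
    def test_count_runs(self, vec, expected):
        assert count_runs(np.array(vec, dtype=np.uint8)) == expected

    @pytest.mark.parametrize("M,k,r,expected", [
        (4, 3, 2, 0.5),   # 2 of the 4 placements of 3 ones have 2 runs
        (5, 2, 2, 0.6),   # 6 of 10 placements are non-adjacent
        (6, 0, 1, 1.0),   # empty product profile
    ])
    def test_runs_pvalue_hand_cases(self, M, k, r, expected):
        assert runs_pvalue(M, k, r) == pytest.approx(expected)

    def test_run_count_distribution_sums_to_total(self):
        """Sum over r of #{exactly r runs} recovers C(M, k), all M <= 12."""
        for M in range(1, 13):
            for k in range(1, M + 1):
                total = sum(math.comb(k - 1, r - 1) * math.comb(M - k + 1, r)
                            for r in range(1, min(k, M - k + 1) + 1))
                assert total == math.comb(M, k)

    def test_runs_tail_matches_exhaustive_enumeration(self):
        for M in range(2, 13):
            for k in range(1, M + 1):
                counts = {}
                for ones in itertools.combinations(range(M), k):
                    v = np.zeros(M, dtype=np.uint8)
                    v[list(ones)] = 1
                    r = count_runs(v)
                    counts[r] = counts.get(r, 0) + 1
                total = math.comb(M, k)
                for r_obs in range(1, max(counts) + 1):
                    want = sum(c for r, c in counts.items() if r >= r_obs) / total
                    if want > 0:
                        assert runs_pvalue(M, k, r_obs) == pytest.approx(want)

    def test_ratio_score_composes_the_two_pvalues(self):
        p1 = np.array([1, 1, 0, 0])
        w = [0.5] * 4
        # product profile 1100: k=2, one run; P(R >= 1) = 1
        assert pp_wpval_with_runs(p1, p1, w, [0, 1, 2, 3]) == pytest.approx(1 / 6)
        # reorder so the product profile is 1010: two runs; P(R >= 2) = 0.5
        assert pp_wpval_with_runs(p1, p1, w, [0, 2, 1, 3]) == pytest.approx((1 / 6) / 0.5)

    def test_empty_product_profile_ratio_is_one(self):
        assert pp_wpval_with_runs(np.array([1, 0]), np.array([0, 1]),
                                  [0.5, 0.5], [0, 1]) == pytest.approx(1.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=2, max_size=16))
def test_metric_ranges_and_symmetry(pairs):
    """Range and symmetry invariants hold for arbitrary profile pairs."""
    p1 = np.array([a for a, _ in pairs], dtype=np.uint8)
    p2 = np.array([b for _, b in pairs], dtype=np.uint8)
    c12, c21 = pair_counts(p1, p2), pair_counts(p2, p1)
    assert 0.0 <= pp_jaccard(c12) <= 1.0
    assert pp_jaccard(c12) == pp_jaccard(c21)
    assert -1.0 <= pp_pearson(p1, p2) <= 1.0
    assert pp_pearson(p1, p2) == pytest.approx(pp_pearson(p2, p1))
    assert pp_mutual_info(c12) >= 0.0
    assert pp_mutual_info(c12) == pytest.approx(pp_mutual_info(c21))
    pv = pp_hypergeom_pval(c12)
    assert 0.0 < pv <= 1.0
    assert pv == pytest.approx(pp_hypergeom_pval(c21))
    w = np.linspace(0.2, 0.8, p1.size)
    wp = pp_weighted_pval(p1, p2, w)
    assert 0.0 < wp <= 1.0 + 1e-12
    assert wp == pytest.approx(pp_weighted_pval(p2, p1, w), abs=1e-10)


class TestScoreAllPairs:
    def test_matrix_is_symmetric_with_missing_diagonal(self, small_world):
        prof = build_profiles(small_world.hits, small_world.genes,
                              small_world.organisms)
        m = score_all_pairs_pp(prof, "mutual-info")
        assert np.allclose(m.values, m.values.T, equal_nan=True)
        assert np.isnan(np.diag(m.values)).all()

    def test_pval_metric_is_orientation_normalized(self):
        bits = np.array([[1, 1, 0, 0], [1, 1, 0, 0], [1, 0, 1, 0]], dtype=np.uint8)
        prof = profiles.ProfileMatrix(["a", "b", "c"], list("wxyz"), bits)
        m = score_all_pairs_pp(prof, "pval")
        # identical profiles (small p-value) must outrank independent ones
        assert m.get("a", "b") > m.get("a", "c")

    def test_gene_permutation_permutes_scores_consistently(self):
        rng = np.random.default_rng(3)
        bits = rng.integers(0, 2, size=(6, 9)).astype(np.uint8)
        prof1 = profiles.ProfileMatrix([f"g{i}" for i in range(6)],
                                       [f"o{j}" for j in range(9)], bits)
        perm = [3, 1, 4, 0, 5, 2]
        prof2 = profiles.ProfileMatrix([f"g{i}" for i in perm],
                                       [f"o{j}" for j in range(9)], bits[perm])
        m1 = score_all_pairs_pp(prof1, "jaccard")
        m2 = score_all_pairs_pp(prof2, "jaccard")
        for a in m1.genes:
            for b in m1.genes:
                if a != b:
                    assert m1.get(a, b) == pytest.approx(m2.get(a, b))

    def test_weight_metrics_require_weights(self):
        prof = profiles.ProfileMatrix(["a", "b"], ["x", "y"],
                                      np.array([[1, 0], [0, 1]], dtype=np.uint8))
        with pytest.raises(ValueError):
            score_all_pairs_pp(prof, "wpval")


def test_organism_weights_are_column_fractions():
    bits = np.array([[1, 0, 1], [1, 0, 1], [1, 0, 0], [0, 0, 1]], dtype=np.uint8)
    prof = profiles.ProfileMatrix(list("abcd"), list("xyz"), bits)
    assert profiles.organism_weights(prof).tolist() == [0.75, 0.0, 0.75]
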