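"""Gene cluster and gene fusion: adjacency/strand rules, the intergenic
normalization factor, Rosetta Stone thresholds, and the hypergeometric
fusion p-value against exhaustive enumeration."""

import itertools
import math

import numpy as np
import pytest

from genomecontext.iokit import GeneRecord, HomologyHit, RepliconInfo
from genomecontext.proximity import (find_rosetta, gene_cluster_scores,
                                     gene_fusion_pval, intergenic_factor,
                                     score_all_pairs_gf)


def linear_genome(gaps, strands, org="T"):
    """Genome on one circular replicon with the given inter-gene gaps."""
    genes, pos = [], 1
    for i, (gap, strand) in enumerate(zip([0] + list(gaps), strands)):
        pos += gap
        genes.append(GeneRecord(f"g{i}", org, "chr", pos, pos + 99, strand, i + 1))
        pos += 100
    # wrap gap sized so the test controls the total
    rep = RepliconInfo("chr", org, pos + 400 - 1, circular=True)
    return genes, [rep]


class TestIntergenicFactor:
    def test_direct_division(self):
        genes, reps = linear_genome([100, 100, 100], "++++")
        # three internal gaps of 100 plus a 400-base wrap gap
        assert intergenic_factor(genes, reps) == pytest.approx(4 / 700)

    def test_doubling_gaps_halves_m(self):
        g1, r1 = linear_genome([50, 50, 50], "++++")   # 150 internal + 400 wrap
        genes2, pos = [], 1
        for i, gap in enumerate([0, 100, 100, 100]):
            pos += gap
            genes2.append(GeneRecord(f"g{i}", "T", "chr", pos, pos + 99, "+", i + 1))
            pos += 100
        r2 = [RepliconInfo("chr", "T", pos - 1 + 800, circular=True)]
        m1 = intergenic_factor(g1, r1)      # total 550 intergenic bases
        m2 = intergenic_factor(genes2, r2)  # total 1100 intergenic bases
        assert m1 == pytest.approx(2 * m2)

    def test_overlapping_genes_contribute_zero_gap(self):
        genes = [GeneRecord("a", "T", "chr", 1, 200, "+", 1),
                 GeneRecord("b", "T", "chr", 150, 300, "+", 2)]
        reps = [RepliconInfo("chr", "T", 400, circular=False)]
        with pytest.raises(ValueError):  # only the overlap gap: zero bases
            intergenic_factor(genes, reps)


class TestGeneCluster:
    def test_adjacent_same_strand_scores_scaled_gap(self):
        genes, reps = linear_genome([50, 200, 100], "++-+")
        m = intergenic_factor(genes, reps)
        sm = gene_cluster_scores(genes, reps)
        assert sm.get("g0", "g1") == pytest.approx(-(50 * m))
        assert np.isnan(sm.get("g1", "g2"))  # opposite strands
        assert np.isnan(sm.get("g0", "g2"))  # not adjacent

    def test_coverage_bounded_by_gene_count(self, small_world):
        sm = gene_cluster_scores(small_world.target_genes,
                                 small_world.target_replicons,
                                 gene_order=small_world.genes)
        iu = np.triu_indices(len(sm.genes), 1)
        assert np.isfinite(sm.values[iu]).sum() <= len(small_world.genes)

    def test_raw_score_invariant_to_coordinate_rescaling(self):
        genes, reps = linear_genome([50, 80, 120], "++++")
        scaled = [GeneRecord(g.gene_id, g.organism, g.replicon_id,
                             (g.start - 1) * 3 + 1, (g.end - 1) * 3 + 3,
                             g.strand, g.rank) for g in genes]
        reps_scaled = [RepliconInfo("chr", "T", reps[0].length_bases * 3, True)]
        a = gene_cluster_scores(genes, reps)
        b = gene_cluster_scores(scaled, reps_scaled)
        for x, y in zip(a.pair_series(), b.pair_series()):
            if np.isfinite(x) or np.isfinite(y):
                assert x == pytest.approx(y, rel=0.05)

    def test_circular_wraparound_pair_is_scored(self):
        genes, reps = linear_genome([50, 50, 50], "++++")
        sm = gene_cluster_scores(genes, reps)
        assert np.isfinite(sm.get("g0", "g3"))  # last-first wrap adjacency


class TestRosetta:
    HITS = [
        HomologyHit("g1", "o1", "rF", 1e-6, 60),
        HomologyHit("g2", "o1", "rF", 1e-7, 55),
        HomologyHit("g1", "o2", "rG", 1e-6, 40),
        HomologyHit("g2", "o2", "rG", 1e-6, 90),
        HomologyHit("g1", "o3", "rH", 1e-5, 50),
        HomologyHit("g2", "o3", "rH", 1e-6, 50),
    ]

    def test_acceptance_and_rejection_rules(self):
        cands = find_rosetta(self.HITS, "g1", "g2", Q=50, E=1e-4)
        names = {c.ref_gene for c in cands}
        assert "rF" in names          # both thresholds met
        assert "rG" not in names      # g1 coverage 40 < Q
        assert "rH" in names          # boundary coverage 50 is inclusive

    def test_identical_genes_rejected(self):
        with pytest.raises(ValueError):
            find_rosetta(self.HITS, "g1", "g1")


def brute_force_fusion_tail(K, n1, n2, f):
    """Enumerate all placements of the n2-set against a fixed n1-set."""
    fixed = set(range(n1))
    hits = total = 0
    for other in itertools.combinations(range(K), n2):
        total += 1
        if len(fixed & set(other)) >= f:
            hits += 1
    return hits / total


class TestFusionPval:
    def test_hand_case(self):
        assert gene_fusion_pval(10, 2, 2, 2) == pytest.approx(1 / 45)

    def test_zero_overlap_gives_one(self):
        assert gene_fusion_pval(10, 3, 4, 0) == 1.0

    def test_matches_exhaustive_enumeration_small_K(self):
        for K in range(2, 13):
            for n1 in range(1, K + 1):
                for n2 in range(1, n1 + 1):
                    for f in range(max(0, n1 + n2 - K), min(n1, n2) + 1):
                        want = brute_force_fusion_tail(K, n1, n2, f)
                        assert gene_fusion_pval(K, n1, n2, f) == \
                            pytest.approx(want, abs=1e-12), (K, n1, n2, f)

    def test_more_fusions_at_fixed_margins_score_better(self):
        tails = [gene_fusion_pval(20, 5, 5, f) for f in range(6)]
        assert all(a > b for a, b in zip(tails, tails[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            gene_fusion_pval(5, 3, 4, 4)


class TestScoreAllPairsGf:
    def test_no_candidate_pairs_stay_missing(self):
        hits = [HomologyHit("g1", "o1", "r1", 1e-9, 90),
                HomologyHit("g2", "o1", "r2", 1e-9, 90)]
        m = score_all_pairs_gf(hits, ["g1", "g2"])
        assert np.isnan(m.get("g1", "g2"))
        assert m.restricted

    def test_fusion_rate_zero_world_has_no_coverage(self, small_world):
        m = score_all_pairs_gf(small_world.hits, small_world.genes)
        iu = np.triu_indices(len(m.genes), 1)
        assert np.isfinite(m.values[iu]).sum() == 0

    def test_fusion_rich_world_scores_module_partners(self):
        from genomecontext import synthetic
        w = synthetic.simulate_world(synthetic.PRESETS["fusion-rich"], seed=2)
        m = score_all_pairs_gf(w.hits, w.genes)
        iu = np.triu_indices(len(m.genes), 1)
        scored = int(np.isfinite(m.values[iu]).sum())
        assert scored > 0
        gi = {g: i for i, g in enumerate(m.genes)}
        for i, j in zip(*iu):
            if np.isfinite(m.values[i, j]):
                key = frozenset((m.genes[i], m.genes[j]))
                assert w.labels[key] == 1  # fused pairs are module partners
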