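"""Restricted-coverage methods: gene cluster and gene fusion.

Gene cluster scores only pairs of genes that are adjacent in rank on the
same replicon and transcribed on the same strand: the raw score is the
intergenic distance in bases times m = (genes in genome) / (total
intergenic bases), which makes the distance genome independent.  All other
pairs are semantically at infinite distance and carry the missing sentinel.

Gene fusion (Rosetta Stone) scores pairs for which some reference gene is
hit by both target genes with coverage >= Q percent and E-value <= E.  The
score is the upper-tail hypergeometric p-value of the number of shared
matches given each gene's own match count, which down-ranks promiscuous
domains.  Pairs with no Rosetta Stone semantically have p-value 1 and carry
the sentinel.

Raw scores are negated at the ScoreMatrix boundary (higher = more related).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

from .iokit import GeneRecord, HomologyHit, RepliconInfo, ScoreMatrix

__all__ = [
    "FusionCandidate",
    "intergenic_factor",
    "gene_cluster_scores",
    "find_rosetta",
    "gene_fusion_pval",
    "score_all_pairs_gf",
]

DEFAULT_Q = 50.0
DEFAULT_E = 1e-4


@dataclass(frozen=True)
class FusionCandidate:
    """A reference gene accepted as a Rosetta Stone for a gene pair."""

    ref_gene: str
    organism: str
    cov1: float
    cov2: float
    e1: float
    e2: float


def _gaps(genes: Sequence[GeneRecord], replicon: RepliconInfo) -> list[tuple[str, str, str, int]]:
    """Intergenic gaps between rank-consecutive genes of one replicon:
    (gene_a, gene_b, strand_pair, gap_bases).  Overlaps clamp to 0; a
    circular replicon includes the wrap-around pair."""
    recs = sorted((g for g in genes if g.replicon_id == replicon.replicon_id
                   and g.organism == replicon.organism),
                  key=lambda g: (g.start, g.gene_id))
    out = []
    for a, b in zip(recs, recs[1:]):
        gap = max(0, b.start - a.end - 1)
        out.append((a.gene_id, b.gene_id, a.strand + b.strand, gap))
    if replicon.circular and len(recs) >= 2:
        last, first = recs[-1], recs[0]
        gap = max(0, (replicon.length_bases - last.end) + (first.start - 1))
        out.append((last.gene_id, first.gene_id, last.strand + first.strand, gap))
    return out


def intergenic_factor(genes: Sequence[GeneRecord],
                      replicons: Sequence[RepliconInfo]) -> float:
    """m = gene count / total intergenic bases for one genome."""
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    total = sum(gap for rep in replicons for *_, gap in _gaps(genes, rep))
    if total <= 0:
        raise ValueError("zero intergenic bases; factor m undefined")
    return len(genes) / total


def gene_cluster_scores(genes: Sequence[GeneRecord],
                        replicons: Sequence[RepliconInfo],
                        gene_order: Sequence[str] | None = None) -> ScoreMatrix:
    """Gene-cluster score matrix for the target genome.

    Rank-adjacent same-strand pairs score -(gap_bases * m); everything else
    keeps the sentinel ("infinitely distant").
    """
    m = intergenic_factor(genes, replicons)
    order = list(gene_order) if gene_order is not None else [g.gene_id for g in genes]
    out = ScoreMatrix.empty(order, restricted=True, method="gc")
    known = set(order)
    best: dict[frozenset, float] = {}
    for rep in replicons:
        for a, b, strands, gap in _gaps(genes, rep):
            if strands in ("++", "--") and a in known and b in known and a != b:
                key = frozenset((a, b))
                # a 2-gene circular replicon is adjacent both ways: keep the
                # shorter separation
                best[key] = min(best.get(key, np.inf), gap * m)
    for key, raw in best.items():
        a, b = sorted(key)
        out.set_pair(a, b, -raw)
    return out


def find_rosetta(hits: Sequence[HomologyHit], g1: str, g2: str,
                 Q: float = DEFAULT_Q, E: float = DEFAULT_E) -> list[FusionCandidate]:
    """Reference genes hit by both g1 and g2 with coverage >= Q (inclusive)
    and E-value <= E (inclusive)."""
    if g1 == g2:
        raise ValueError("gene fusion requires two distinct genes")
    if not 0 < Q <= 100 or E <= 0:
        raise ValueError("need Q in (0, 100] and E > 0")
    by_ref_1 = {(h.organism, h.ref_gene): h for h in hits
                if h.target_gene == g1 and h.coverage_pct >= Q and h.e_value <= E}
    out: list[FusionCandidate] = []
    for h in hits:
        if h.target_gene != g2 or h.coverage_pct < Q or h.e_value > E:
            continue
        mate = by_ref_1.get((h.organism, h.ref_gene))
        if mate is not None:
            out.append(FusionCandidate(h.ref_gene, h.organism,
                                       mate.coverage_pct, h.coverage_pct,
                                       mate.e_value, h.e_value))
    return out


def gene_fusion_pval(K: int, n1: int, n2: int, f: int) -> float:
    """Upper-tail hypergeometric P(overlap >= f | K candidate genes, n1 and
    n2 matched by each gene alone)."""
    if not (0 <= f <= min(n1, n2) <= max(n1, n2) <= K):
        raise ValueError(f"inconsistent fusion counts K={K} n1={n1} n2={n2} f={f}")
    return float(hypergeom.sf(f - 1, K, n1, n2))


def score_all_pairs_gf(hits: Sequence[HomologyHit], genes: Sequence[str],
                       Q: float = DEFAULT_Q, E: float = DEFAULT_E,
                       n_reference_genes: int | None = None) -> ScoreMatrix:
    """Gene-fusion score matrix.

    ``n_reference_genes`` is the total number of candidate genes scanned
    across the reference genomes (K of the hypergeometric); when omitted it
    defaults to the number of distinct reference genes observed in the
    homology table.  Pairs with >= 1 Rosetta Stone store -pval; all others
    keep the sentinel (semantically p-value 1).
    """
    # matches per gene at (Q, E), as sets of (organism, ref_gene)
    matches: dict[str, set[tuple[str, str]]] = {g: set() for g in genes}
    all_refs: set[tuple[str, str]] = set()
    for h in hits:
        all_refs.add((h.organism, h.ref_gene))
        if h.target_gene in matches and h.coverage_pct >= Q and h.e_value <= E:
            matches[h.target_gene].add((h.organism, h.ref_gene))
    K = n_reference_genes if n_reference_genes is not None else len(all_refs)
    out = ScoreMatrix.empty(genes, restricted=True, method="gf")
    gene_list = list(genes)
    for i in range(len(gene_list)):
        mi = matches[gene_list[i]]
        if not mi:
            continue
        for j in range(i + 1, len(gene_list)):
            mj = matches[gene_list[j]]
            f = len(mi & mj)
            if f == 0:
                continue
            pv = gene_fusion_pval(K, len(mi), len(mj), f)
            out.values[i, j] = out.values[j, i] = -pv
    return out
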