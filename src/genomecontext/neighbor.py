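"""Gene-neighbor scores.

For two target genes, each reference genome that contains homologs of both
contributes the minimum gene-rank distance d between any homolog pair
(adjacent genes have d = 1; a shared homolog counts as d = 1; on a circular
replicon the shorter arc is used).  Under independence, on a circular
chromosome with N genes the relative distance p = 2d/(N - 1) is uniform on
(0, 1], so across the M~ genomes containing both genes:

* ``gn-lnX``       -ln x  with  x = prod_i p_i                (higher = closer)
* ``gn-norm-lnX``  -ln(x) / M~
* ``gn-pval``      P(X <= x), the Gamma(M~, 1) upper tail of -ln x; small
                   values flag dependence between the gene locations.

gn-pval is stored negated so every ScoreMatrix is higher = more related.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaincc

from .iokit import MISSING, GeneRecord, HomologyHit, ScoreMatrix

__all__ = [
    "NeighborEvidence",
    "NeighborScore",
    "pair_rank_distance",
    "relative_distance",
    "gamma_tail",
    "gn_scores",
    "score_all_pairs_gn",
    "GN_VARIANTS",
]

GN_VARIANTS = ("lnX", "norm-lnX", "pval")


@dataclass(frozen=True)
class NeighborEvidence:
    """One reference genome's contribution to a gene pair."""

    organism: str
    d: int       # gene-rank distance >= 1
    N: int       # genes in that genome
    p: float     # relative distance in (0, 1]


@dataclass(frozen=True)
class NeighborScore:
    M_tilde: int
    lnX: float
    norm_lnX: float
    pval: float


def pair_rank_distance(
    g1_ranks: Iterable[int],
    g2_ranks: Iterable[int],
    N: int,
    circular: bool = True,
) -> int:
    """Minimum rank distance between any homolog of gene 1 and any homolog
    of gene 2 on one replicon of N genes.  A shared homolog gives 1, as do
    adjacent genes; a circular replicon uses the shorter arc."""
    r1 = np.asarray(list(g1_ranks), dtype=int)
    r2 = np.asarray(list(g2_ranks), dtype=int)
    if r1.size == 0 or r2.size == 0:
        raise ValueError("both homolog rank sets must be non-empty")
    diff = np.abs(r1[:, None] - r2[None, :])
    if circular:
        diff = np.minimum(diff, N - diff)
    d = int(diff.min())
    return max(d, 1)  # shared homolog: distance defined to be 1, not 0


def relative_distance(d: int, N: int, circular: bool = True) -> float:
    """Relative distance p in (0, 1].

    Circular: p = 2d/(N - 1), the uniform null over distances 1..(N-1)/2.
    Linear:   p = d/(N - 1), null support 1..(N-1).
    Clipped at 1 so -ln p >= 0 always.
    """
    if N < 3:
        raise ValueError("genome too small for a relative distance (N < 3)")
    if d < 1:
        raise ValueError("rank distance must be >= 1")
    p = (2 * d if circular else d) / (N - 1)
    return min(p, 1.0)


def gamma_tail(x: float, M_tilde: int) -> float:
    """P(X <= x) = x * sum_{k=0}^{M~-1} (-ln x)^k / k!  — the Gamma(M~, 1)
    survival function at -ln x, evaluated stably via the regularized upper
    incomplete gamma function."""
    if M_tilde < 1:
        raise ValueError("M_tilde must be >= 1")
    if not 0.0 <= x <= 1.0:
        raise ValueError("x must lie in [0, 1]")
    if x == 0.0:
        warnings.warn("gamma_tail at x = 0: returning 0 by continuity")
        return 0.0
    return float(gammaincc(M_tilde, -np.log(x)))


def gn_scores(evidence: Sequence[NeighborEvidence]) -> NeighborScore:
    """Aggregate per-genome relative distances into the three scores."""
    if len(evidence) == 0:
        raise ValueError("no evidence: gene-neighbor score undefined")
    logs = -np.log([e.p for e in evidence])
    m = len(evidence)
    lnx = float(logs.sum())
    x = float(np.exp(-lnx))
    return NeighborScore(M_tilde=m, lnX=lnx, norm_lnX=lnx / m,
                         pval=gamma_tail(x, m))


def _homolog_ranks(
    hits: Sequence[HomologyHit],
    annotations: Sequence[GeneRecord],
    e_threshold: float,
) -> tuple[dict[str, dict[str, dict[str, list[int]]]], dict[tuple[str, str], int]]:
    """Index homolog rank positions: gene -> organism -> replicon -> ranks,
    plus genes per (organism, replicon)."""
    pos: dict[tuple[str, str], tuple[str, int]] = {}
    n_by_rep: dict[tuple[str, str], int] = {}
    for g in annotations:
        pos[(g.organism, g.gene_id)] = (g.replicon_id, g.rank)
        key = (g.organism, g.replicon_id)
        n_by_rep[key] = max(n_by_rep.get(key, 0), g.rank)
    ranks: dict[str, dict[str, dict[str, list[int]]]] = {}
    for h in hits:
        if h.e_value >= e_threshold:
            continue
        loc = pos.get((h.organism, h.ref_gene))
        if loc is None:
            continue
        rep, rank = loc
        ranks.setdefault(h.target_gene, {}).setdefault(h.organism, {}) \
             .setdefault(rep, []).append(rank)
    return ranks, n_by_rep


def pair_evidence(
    g1: str,
    g2: str,
    ranks: dict,
    n_by_rep: dict[tuple[str, str], int],
    circular_by_rep: dict[tuple[str, str], bool] | None = None,
) -> list[NeighborEvidence]:
    """Evidence items for one gene pair: one per organism where both genes
    have homologs on a common replicon.  Homologs confined to different
    replicons of the same organism contribute nothing (the uniform null
    assumes a single chromosome)."""
    out: list[NeighborEvidence] = []
    orgs1 = ranks.get(g1, {})
    orgs2 = ranks.get(g2, {})
    for org in orgs1.keys() & orgs2.keys():
        shared_reps = orgs1[org].keys() & orgs2[org].keys()
        best: NeighborEvidence | None = None
        for rep in sorted(shared_reps):
            N = n_by_rep[(org, rep)]
            if N < 3:
                warnings.warn(f"replicon {rep} of {org} too small; skipped")
                continue
            circ = True if circular_by_rep is None else circular_by_rep[(org, rep)]
            d = pair_rank_distance(orgs1[org][rep], orgs2[org][rep], N, circ)
            p = relative_distance(d, N, circ)
            cand = NeighborEvidence(org, d, N, p)
            if best is None or cand.p < best.p:
                best = cand
        if best is not None:
            out.append(best)
    return out


def score_all_pairs_gn(
    hits: Sequence[HomologyHit],
    annotations: Sequence[GeneRecord],
    genes: Sequence[str],
    e_threshold: float = 1e-4,
    variant: str = "pval",
    circular_by_rep: dict[tuple[str, str], bool] | None = None,
) -> ScoreMatrix:
    """All-pairs gene-neighbor score matrix.

    Pairs whose homologs never co-occur carry the missing sentinel.  For
    ``variant='pval'`` the stored score is -pval (orientation contract);
    ``lnX`` and ``norm-lnX`` are already higher = more related.
    """
    if variant not in GN_VARIANTS:
        raise ValueError(f"unknown gn variant {variant!r}")
    ranks, n_by_rep = _homolog_ranks(hits, annotations, e_threshold)
    out = ScoreMatrix.empty(genes, method=f"gn-{variant}")
    gene_list = list(genes)
    for i in range(len(gene_list)):
        for j in range(i + 1, len(gene_list)):
            ev = pair_evidence(gene_list[i], gene_list[j], ranks, n_by_rep,
                               circular_by_rep)
            if not ev:
                continue
            s = gn_scores(ev)
            if variant == "lnX":
                v = s.lnX
            elif variant == "norm-lnX":
                v = s.norm_lnX
            else:
                v = -s.pval
            out.values[i, j] = out.values[j, i] = v
    np.fill_diagonal(out.values, MISSING)
    return out
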