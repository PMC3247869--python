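"""Phylogenetic-profile similarity scores.

A phylogenetic profile is a binary vector over a reference organism list:
1 where the gene has a homolog (E-value strictly below the homology
threshold), 0 elsewhere.  Six pairwise similarity measures are provided:

* ``jaccard``            n11 / (M - n00)
* ``pearson``            Pearson correlation of the binary vectors
* ``mutual-info``        plug-in mutual information of the empirical 2x2
                         joint, in nats
* ``pval``               upper-tail hypergeometric p-value of the overlap
* ``wpval``              weighted hypergeometric p-value: organism i
                         contains a homolog of any target gene with its own
                         probability w_i (the fraction of target genes it
                         contains); computed by an exact dynamic program
                         conditioning on the observed profile margins
* ``wpval-with-runs``    wpval divided by a p-value for the number of runs
                         of consecutive 1s in the product profile, read in a
                         phylogenetically sorted organism order

All measures are symmetric in the two profiles.  p-value measures are
negated at the ScoreMatrix boundary so that higher always means more
related.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

from .iokit import MISSING, HomologyHit, ProfileMatrix, ScoreMatrix

__all__ = [
    "ProfilePairCounts",
    "build_profiles",
    "pair_counts",
    "pp_jaccard",
    "pp_pearson",
    "pp_mutual_info",
    "pp_hypergeom_pval",
    "organism_weights",
    "pp_weighted_pval",
    "count_runs",
    "runs_pvalue",
    "pp_wpval_with_runs",
    "score_all_pairs_pp",
    "PP_METRICS",
]

PP_METRICS = ("jaccard", "pearson", "mutual-info", "pval", "wpval", "wpval-with-runs")

_WEIGHT_CLAMP = 1e-6  # guards the wpval recursion against weights at 0 or 1


@dataclass(frozen=True)
class ProfilePairCounts:
    """2x2 contingency counts for a pair of profiles over M organisms."""

    M: int
    n1_1: int
    n2_1: int
    n11: int

    @property
    def n00(self) -> int:
        return self.M - self.n1_1 - self.n2_1 + self.n11

    def table(self) -> np.ndarray:
        """Joint counts n12(x, y) indexed [x][y] for x, y in {0, 1}."""
        n10 = self.n1_1 - self.n11
        n01 = self.n2_1 - self.n11
        return np.array([[self.n00, n01], [n10, self.n11]], dtype=float)


def build_profiles(
    hits: Sequence[HomologyHit],
    genes: Sequence[str],
    organisms: Sequence[str],
    e_threshold: float = 1e-4,
) -> ProfileMatrix:
    """Presence/absence matrix: bit = 1 iff some hit for (gene, organism)
    has ``e_value`` strictly below ``e_threshold``."""
    if len(organisms) == 0:
        raise ValueError("empty organism list")
    if e_threshold <= 0:
        raise ValueError("e_threshold must be positive")
    gi = {g: i for i, g in enumerate(genes)}
    oi = {o: j for j, o in enumerate(organisms)}
    bits = np.zeros((len(genes), len(organisms)), dtype=np.uint8)
    for h in hits:
        if h.target_gene in gi and h.organism in oi and h.e_value < e_threshold:
            bits[gi[h.target_gene], oi[h.organism]] = 1
    return ProfileMatrix(list(genes), list(organisms), bits)


def pair_counts(p1: np.ndarray, p2: np.ndarray) -> ProfilePairCounts:
    p1 = np.asarray(p1, dtype=np.uint8)
    p2 = np.asarray(p2, dtype=np.uint8)
    if p1.shape != p2.shape:
        raise ValueError("profile length mismatch")
    return ProfilePairCounts(
        M=p1.size,
        n1_1=int(p1.sum()),
        n2_1=int(p2.sum()),
        n11=int((p1 & p2).sum()),
    )


def pp_jaccard(counts: ProfilePairCounts) -> float:
    denom = counts.M - counts.n00
    if denom == 0:  # both profiles empty: no evidence
        return 0.0
    return counts.n11 / denom


def pp_pearson(p1: np.ndarray, p2: np.ndarray) -> float:
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("profile length mismatch")
    if p1.std() == 0 or p2.std() == 0:  # constant profile: no evidence
        return 0.0
    return float(np.corrcoef(p1, p2)[0, 1])


def pp_mutual_info(counts: ProfilePairCounts) -> float:
    """Plug-in mutual information of the empirical 2x2 joint, in nats."""
    joint = counts.table() / counts.M
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mi = 0.0
    for x in (0, 1):
        for y in (0, 1):
            if joint[x, y] > 0:
                mi += joint[x, y] * math.log(joint[x, y] / (px[x] * py[y]))
    return max(mi, 0.0)


def pp_hypergeom_pval(counts: ProfilePairCounts) -> float:
    """P(overlap >= n11) drawing n2_1 of M organisms with n1_1 marked."""
    return float(hypergeom.sf(counts.n11 - 1, counts.M, counts.n1_1, counts.n2_1))


def organism_weights(profiles: ProfileMatrix) -> np.ndarray:
    """w_i = fraction of target genes with a homolog in organism i."""
    return profiles.bits.mean(axis=0)


def _joint_margin_dist(weights: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """DP over organisms: P(S1 = s1, S2 = s2, S12 = s12) for independent
    per-organism Bernoulli(w_i) placements of both genes, truncated to
    s1 <= n1, s2 <= n2 (states beyond the target margins can never return).

    Returns the co-occurrence distribution P(S12 = . , S1 = n1, S2 = n2).
    """
    mmax = min(n1, n2)
    P = np.zeros((n1 + 1, n2 + 1, mmax + 1))
    P[0, 0, 0] = 1.0
    for w in weights:
        a, b, c, d = w * w, w * (1 - w), (1 - w) * w, (1 - w) * (1 - w)
        Q = d * P
        Q[1:, :, :] += b * P[:-1, :, :]
        Q[:, 1:, :] += c * P[:, :-1, :]
        Q[1:, 1:, 1:] += a * P[:-1, :-1, :-1]
        P = Q
    return P[n1, n2, :]


def pp_weighted_pval(p1: np.ndarray, p2: np.ndarray, weights: np.ndarray) -> float:
    """Weighted hypergeometric p-value.

    P(co-occurrences >= observed | row sums), where organism i contains a
    homolog of either gene independently with probability w_i.  With all
    weights equal the conditional law is exactly hypergeometric.
    """
    counts = pair_counts(p1, p2)
    w = np.clip(np.asarray(weights, dtype=float), _WEIGHT_CLAMP, 1 - _WEIGHT_CLAMP)
    if w.size != counts.M:
        raise ValueError("weights length mismatch")
    if np.all((w <= _WEIGHT_CLAMP) | (w >= 1 - _WEIGHT_CLAMP)):
        warnings.warn("all organism weights at the clamping boundary; "
                      "weighted p-value is numerically fragile")
    dist = _joint_margin_dist(w, counts.n1_1, counts.n2_1)
    total = dist.sum()
    if total <= 0:
        # margins unreachable numerically; fall back to the unweighted law
        return pp_hypergeom_pval(counts)
    tail = dist[counts.n11:].sum() / total
    return float(min(max(tail, 0.0), 1.0))


def count_runs(product_profile_ordered: np.ndarray) -> int:
    """Number of maximal blocks of consecutive 1s (linear, not circular)."""
    p = np.asarray(product_profile_ordered, dtype=np.uint8)
    if p.size == 0:
        return 0
    starts = (p[1:] == 1) & (p[:-1] == 0)
    return int(p[0] == 1) + int(starts.sum())


def _runs_count(M: int, k: int, r: int) -> int:
    """#{linear arrangements of k ones in M slots with exactly r runs}."""
    return math.comb(k - 1, r - 1) * math.comb(M - k + 1, r)


def runs_pvalue(M: int, k: int, r_obs: int, tail: str = "greater") -> float:
    """Tail probability of the number of runs of 1s under uniformly random
    placement of k ones in M linear positions.

    ``tail='greater'`` gives P(R >= r_obs) (default); ``'less'`` gives
    P(R <= r_obs).  k = 0 returns 1.
    """
    if not 0 <= k <= M:
        raise ValueError("need 0 <= k <= M")
    if k == 0:
        return 1.0
    rmax = min(k, M - k + 1)
    total = math.comb(M, k)
    if tail == "greater":
        rs = range(max(r_obs, 1), rmax + 1)
    elif tail == "less":
        rs = range(1, min(r_obs, rmax) + 1)
    else:
        raise ValueError("tail must be 'greater' or 'less'")
    mass = sum(_runs_count(M, k, r) for r in rs)
    if mass == 0:
        # r_obs beyond the support: report the most extreme achievable term
        extreme = rmax if tail == "greater" else 1
        mass = _runs_count(M, k, extreme)
    return mass / total


def pp_wpval_with_runs(
    p1: np.ndarray,
    p2: np.ndarray,
    weights: np.ndarray,
    leaf_order: Sequence[int],
    tail: str = "greater",
) -> float:
    """Ratio of the weighted hypergeometric p-value to the runs p-value of
    the product profile read in the (phylogenetically sorted) ``leaf_order``.
    Smaller = stronger evidence; negated at the ScoreMatrix boundary."""
    p1 = np.asarray(p1, dtype=np.uint8)
    p2 = np.asarray(p2, dtype=np.uint8)
    order = np.asarray(leaf_order, dtype=int)
    prod = (p1 & p2)[order]
    k = int(prod.sum())
    r_obs = count_runs(prod)
    wp = pp_weighted_pval(p1, p2, weights)
    rp = runs_pvalue(prod.size, k, r_obs, tail=tail)
    return wp / rp


def score_all_pairs_pp(
    profiles: ProfileMatrix,
    metric: str = "mutual-info",
    weights: np.ndarray | None = None,
    leaf_order: Sequence[int] | None = None,
) -> ScoreMatrix:
    """Symmetric all-pairs score matrix for one profile metric, oriented
    higher = more related (p-values stored negated)."""
    if metric not in PP_METRICS:
        raise ValueError(f"unknown pp metric {metric!r}")
    if metric in ("wpval", "wpval-with-runs") and weights is None:
        raise ValueError(f"metric {metric!r} requires organism weights")
    if metric == "wpval-with-runs" and leaf_order is None:
        leaf_order = np.arange(len(profiles.organisms))

    B = profiles.bits.astype(np.int64)
    n_genes, M = B.shape
    out = ScoreMatrix.empty(profiles.genes, method=f"pp-{metric}")

    if metric in ("jaccard", "pearson", "mutual-info", "pval"):
        n11 = B @ B.T
        n1 = B.sum(axis=1)
        if metric == "jaccard":
            union = n1[:, None] + n1[None, :] - n11
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = np.where(union > 0, n11 / np.maximum(union, 1), 0.0)
        elif metric == "pearson":
            mu = B.mean(axis=1)
            sd = B.std(axis=1)
            cov = n11 / M - np.outer(mu, mu)
            denom = np.outer(sd, sd)
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
        elif metric == "mutual-info":
            vals = np.empty((n_genes, n_genes))
            for i in range(n_genes):
                for j in range(i, n_genes):
                    c = ProfilePairCounts(M, int(n1[i]), int(n1[j]), int(n11[i, j]))
                    vals[i, j] = vals[j, i] = pp_mutual_info(c)
        else:  # pval
            vals = np.empty((n_genes, n_genes))
            for i in range(n_genes):
                for j in range(i, n_genes):
                    c = ProfilePairCounts(M, int(n1[i]), int(n1[j]), int(n11[i, j]))
                    vals[i, j] = vals[j, i] = -pp_hypergeom_pval(c)
        out.values[:, :] = vals
    else:
        for i in range(n_genes):
            for j in range(i + 1, n_genes):
                if metric == "wpval":
                    v = -pp_weighted_pval(B[i], B[j], weights)
                else:
                    v = -pp_wpval_with_runs(B[i], B[j], weights, leaf_order)
                out.values[i, j] = out.values[j, i] = v
    np.fill_diagonal(out.values, MISSING)
    return out
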