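"""Reference-organism list construction.

Most genome-context scores assume the reference genomes are independent; a
list stuffed with near-identical strains violates that.  Organisms (columns
of the profile matrix) are hierarchically clustered under the Jaccard
distance, the tree is pruned so that no cluster exceeds a maximum
within-cluster distortion (cluster diameter by default), and each cluster
is represented by the organism with the smallest average distance to its
cluster mates.  Random subsets of matching sizes serve as a baseline.

The same tree, *swiveled* so that the summed distance between adjacent
leaves is minimal, supplies the organism ordering used by the runs
heuristic of the profile module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .iokit import ProfileMatrix

__all__ = [
    "OrganismTree",
    "organism_distance",
    "build_tree",
    "cut_by_distortion",
    "pick_representatives",
    "random_subsets",
    "swivel_leaf_order",
    "swivel_objective",
]


@dataclass
class OrganismTree:
    """Hierarchical merge tree over organisms (scipy linkage encoding)."""

    organisms: list[str]
    Z: np.ndarray          # scipy linkage matrix
    distances: np.ndarray  # condensed-square organism distance matrix

    @property
    def n_leaves(self) -> int:
        return len(self.organisms)


def organism_distance(profiles: ProfileMatrix) -> np.ndarray:
    """Jaccard distance between organism profiles (columns):
    d(a, b) = 1 - |both| / |either|, with d = 1 when the union is empty."""
    B = profiles.bits.astype(np.int64).T  # organisms x genes
    inter = B @ B.T
    sums = B.sum(axis=1)
    union = sums[:, None] + sums[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return d


def build_tree(distances: np.ndarray, organisms: list[str] | None = None,
               method: str = "average") -> OrganismTree:
    """Agglomerative tree (average linkage default, ``complete`` optional).
    scipy's linkage is deterministic: equal merge distances resolve to the
    lowest-index pair."""
    if method not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    d = np.asarray(distances, dtype=float)
    if organisms is None:
        organisms = [f"org{i}" for i in range(d.shape[0])]
    if d.shape[0] < 2:
        raise ValueError("need at least 2 organisms")
    Z = linkage(squareform(d, checks=False), method=method)
    return OrganismTree(list(organisms), Z, d)


def _subtree_leaves(tree: OrganismTree) -> dict[int, list[int]]:
    """Leaf sets for every node id in the linkage encoding."""
    n = tree.n_leaves
    leaves: dict[int, list[int]] = {i: [i] for i in range(n)}
    for k, (a, b, *_rest) in enumerate(tree.Z):
        leaves[n + k] = leaves[int(a)] + leaves[int(b)]
    return leaves


def cut_by_distortion(tree: OrganismTree, max_distortion: float,
                      criterion: str = "diameter") -> list[list[int]]:
    """Minimal set of subtrees whose within-cluster distortion stays within
    ``max_distortion``.  Distortion = maximum pairwise distance (diameter)
    by default, or mean pairwise distance with ``criterion='mean'``.
    A threshold of 0 yields singletons (for distinct organisms); a threshold
    at or above the diameter of the whole set yields one cluster."""
    if max_distortion < 0:
        raise ValueError("max_distortion must be >= 0")
    leaves = _subtree_leaves(tree)
    d = tree.distances

    def distortion(idx: list[int]) -> float:
        if len(idx) < 2:
            return 0.0
        sub = d[np.ix_(idx, idx)]
        if criterion == "diameter":
            return float(sub.max())
        iu = np.triu_indices(len(idx), k=1)
        return float(sub[iu].mean())

    root = tree.n_leaves + len(tree.Z) - 1
    clusters: list[list[int]] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node < tree.n_leaves:
            clusters.append([node])
            continue
        if distortion(leaves[node]) <= max_distortion:
            clusters.append(sorted(leaves[node]))
        else:
            k = node - tree.n_leaves
            stack.extend([int(tree.Z[k, 1]), int(tree.Z[k, 0])])
    clusters.sort(key=lambda c: c[0])
    return clusters


def pick_representatives(clusters: list[list[int]], distances: np.ndarray) -> list[int]:
    """One organism per cluster: the member with the smallest average
    distance to the others (ties to the lowest index); a singleton
    represents itself."""
    reps = []
    for c in clusters:
        if len(c) == 1:
            reps.append(c[0])
            continue
        sub = distances[np.ix_(c, c)]
        avg = sub.sum(axis=1) / (len(c) - 1)
        reps.append(c[int(np.argmin(avg))])  # argmin takes the first = lowest index
    return reps


def random_subsets(organisms: list[str], size: int, n_reps: int = 3,
                   seed: int = 0) -> list[list[str]]:
    """Reproducible uniform subsets without replacement (baseline lists)."""
    if size > len(organisms):
        raise ValueError("subset size exceeds organism count")
    rng = np.random.default_rng(seed)
    return [sorted(rng.choice(organisms, size=size, replace=False).tolist())
            for _ in range(n_reps)]


def swivel_objective(order: np.ndarray, distances: np.ndarray) -> float:
    """Sum of distances between neighboring leaves for a leaf order."""
    order = np.asarray(order, dtype=int)
    return float(distances[order[:-1], order[1:]].sum())


def _greedy_swivel(tree: OrganismTree) -> np.ndarray:
    """Greedy local swiveling: sweep the internal nodes bottom-up, flipping
    each node's children whenever the flip lowers the adjacent-leaf
    objective; repeat until no flip helps."""
    n = tree.n_leaves
    flipped = np.zeros(len(tree.Z), dtype=bool)

    def order_for(flips: np.ndarray) -> np.ndarray:
        def emit(node: int) -> list[int]:
            if node < n:
                return [node]
            k = node - n
            a, b = int(tree.Z[k, 0]), int(tree.Z[k, 1])
            if flips[k]:
                a, b = b, a
            return emit(a) + emit(b)
        return np.array(emit(n + len(tree.Z) - 1), dtype=int)

    best = swivel_objective(order_for(flipped), tree.distances)
    improved = True
    while improved:
        improved = False
        for k in range(len(tree.Z)):
            flipped[k] = ~flipped[k]
            obj = swivel_objective(order_for(flipped), tree.distances)
            if obj < best - 1e-12:
                best = obj
                improved = True
            else:
                flipped[k] = ~flipped[k]
    return order_for(flipped)


def _exact_swivel(tree: OrganismTree) -> np.ndarray:
    """Exact optimal leaf ordering: a dynamic program over subtrees keyed
    by the (first, last) leaf of the subtree's ordering.  Minimizes the
    summed distance between adjacent leaves over all 2^(internal nodes)
    swivel choices."""
    n = tree.n_leaves
    d = tree.distances
    memo: dict[int, dict[tuple[int, int], tuple[float, list[int]]]] = {
        i: {(i, i): (0.0, [i])} for i in range(n)
    }
    for k, (za, zb, *_rest) in enumerate(tree.Z):
        a, b = int(za), int(zb)
        cur: dict[tuple[int, int], tuple[float, list[int]]] = {}
        for left, right in ((a, b), (b, a)):
            for (f1, l1), (c1, o1) in memo[left].items():
                for (f2, l2), (c2, o2) in memo[right].items():
                    cost = c1 + d[l1, f2] + c2
                    key = (f1, l2)
                    if key not in cur or cost < cur[key][0]:
                        cur[key] = (cost, o1 + o2)
        memo[n + k] = cur
    root = memo[n + len(tree.Z) - 1]
    _, order = min(root.values(), key=lambda t: t[0])
    return np.array(order, dtype=int)


def swivel_leaf_order(tree: OrganismTree, method: str = "auto",
                      exact_max_leaves: int = 25) -> np.ndarray:
    """Leaf order minimizing the summed distance between adjacent leaves
    over all subtree rotations (swivels) of the dendrogram.

    ``exact`` runs the optimal-leaf-ordering dynamic program; ``greedy``
    uses local swivels; ``auto`` picks exact up to ``exact_max_leaves``
    organisms and greedy beyond.
    """
    if method == "auto":
        method = "exact" if tree.n_leaves <= exact_max_leaves else "greedy"
    if method == "exact":
        return _exact_swivel(tree)
    if method == "greedy":
        return _greedy_swivel(tree)
    raise ValueError(f"unknown swivel method {method!r}")
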