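"""Combining genome-context scores into a single measure.

Two combiners, both exposed as sklearn-compatible estimators over a pair x
feature score table:

* :class:`ConfidenceProductCombiner` — each method's score is mapped to a
  confidence in [0, 1] by a cubic smoothing spline fitted to the cumulative
  accuracy on a training set (made monotone by an isotonic pass), and the
  confidences are merged as s = 1 - prod_i (1 - s_i) (or by the maximum).
  A method that could not score a pair contributes confidence 0.
* :class:`BaggedTreeCombiner` — the average of 10 probability-estimation
  decision trees (cost-complexity pruned, Laplace-smoothed leaf
  probabilities), each trained on P positives and 10 P negatives resampled
  with replacement.

Cross-validation folds are assigned at the level of *similar-gene group
pairs* (connected components of the within-target similarity graph), so
near-duplicate gene pairs never straddle train and test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression
from sklearn.tree import DecisionTreeClassifier

from . import evaluate, neighbor, normalize, profiles, proximity
from .iokit import GeneRecord, HomologyHit, RepliconInfo, ScoreMatrix

__all__ = [
    "ConfidenceMap",
    "fit_confidence_map",
    "product_combine",
    "max_combine",
    "ConfidenceProductCombiner",
    "BaggedTreeCombiner",
    "group_genes_by_similarity",
    "grouped_cv_folds",
    "score_table",
    "run_combination_experiment",
    "ORIG_SCORES",
    "ORIG_NEW_SCORES",
]

#: the four scores standard in the genome-context literature
ORIG_SCORES = ("gn-pval", "pp-mutual-info", "gc", "gf")
#: plus the additional scores this package provides
ORIG_NEW_SCORES = ORIG_SCORES + ("gn-lnX", "gn-lnX.znorm", "pp-mutual-info.znorm")


@dataclass
class ConfidenceMap:
    """Monotone score -> confidence mapping, constant-extended outside the
    fitted range."""

    x: np.ndarray  # increasing score knots
    y: np.ndarray  # confidences in [0, 1], non-decreasing

    def __call__(self, scores: np.ndarray) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        out = np.interp(s, self.x, self.y)
        out[np.isnan(s)] = 0.0  # unscorable pair: no confidence
        return out


def fit_confidence_map(scores: np.ndarray, labels: np.ndarray,
                       smoothing: float | None = None,
                       isotonic: bool = True) -> ConfidenceMap:
    """Fit the score -> confidence transform.

    Cumulative accuracy (precision among pairs scoring at or above each
    distinct value) is smoothed by a cubic smoothing spline (GCV-chosen
    penalty unless ``smoothing`` is given), clamped to [0, 1] and made
    monotone non-decreasing by an isotonic pass.  Missing scores are
    excluded from fitting.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    ok = ~np.isnan(s)
    s, y = s[ok], y[ok]
    if s.size == 0:
        raise ValueError("no scored pairs to fit a confidence map")
    prevalence = y.mean()
    ca = evaluate.cumulative_accuracy(s, y)  # threshold desc, CA
    xs = ca["threshold"].to_numpy()[::-1]
    ys = ca["cumulative_accuracy"].to_numpy()[::-1]
    finite = np.isfinite(xs)
    xs, ys = xs[finite], ys[finite]
    if xs.size < 2:
        return ConfidenceMap(np.array([0.0, 1.0]),
                             np.array([prevalence, prevalence]))
    if xs.size >= 5:
        try:
            spline = make_smoothing_spline(xs, ys, lam=smoothing)
            fitted = spline(xs)
        except Exception:  # degenerate knot layout: keep the raw curve
            fitted = ys
    else:
        fitted = ys
    fitted = np.clip(fitted, 0.0, 1.0)
    if isotonic:
        fitted = IsotonicRegression(y_min=0.0, y_max=1.0,
                                    increasing=True).fit_transform(xs, fitted)
    return ConfidenceMap(xs, fitted)


def product_combine(confidences: Sequence[float] | np.ndarray) -> float | np.ndarray:
    """s = 1 - prod_i (1 - s_i) over per-method confidences in [0, 1]."""
    c = np.asarray(confidences, dtype=float)
    return 1.0 - np.prod(1.0 - c, axis=-1)


def max_combine(confidences: Sequence[float] | np.ndarray) -> float | np.ndarray:
    c = np.asarray(confidences, dtype=float)
    return np.max(c, axis=-1)


class ConfidenceProductCombiner(BaseEstimator):
    """STRING-style combiner: per-method confidence maps + product rule.

    Parameters
    ----------
    rule : {'product', 'max'}
        How per-method confidences merge into one score.
    smoothing : float or None
        Spline penalty; None selects it by generalized cross-validation.
    isotonic : bool
        Apply the monotone post-pass to each confidence map.
    """

    def __init__(self, rule: str = "product", smoothing: float | None = None,
                 isotonic: bool = True):
        self.rule = rule
        self.smoothing = smoothing
        self.isotonic = isotonic

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if self.rule not in ("product", "max"):
            raise ValueError("rule must be 'product' or 'max'")
        self.maps_ = [fit_confidence_map(X[:, j], y, self.smoothing,
                                         self.isotonic)
                      for j in range(X.shape[1])]
        self.n_features_in_ = X.shape[1]
        return self

    def confidences(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.column_stack([m(X[:, j]) for j, m in enumerate(self.maps_)])

    def predict_proba(self, X) -> np.ndarray:
        c = self.confidences(X)
        s = product_combine(c) if self.rule == "product" else max_combine(c)
        return np.column_stack([1.0 - s, s])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]


class BaggedTreeCombiner(BaseEstimator):
    """Bagged probability-estimation decision trees.

    Each of ``n_trees`` trees trains on P positives and ``neg_per_pos`` * P
    negatives, both resampled with replacement.  Trees are cost-complexity
    pruned (``ccp_alpha``); predictions average the per-tree positive-class
    leaf probabilities with Laplace smoothing (n_pos + 1) / (n + 2).
    Missing features are imputed at fit time with a worst-case constant
    (below the observed minimum of the column), serialized with the model.
    """

    def __init__(self, n_trees: int = 10, neg_per_pos: int = 10,
                 ccp_alpha: float = 1e-4, min_samples_leaf: int = 5,
                 random_state: int = 0):
        self.n_trees = n_trees
        self.neg_per_pos = neg_per_pos
        self.ccp_alpha = ccp_alpha
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def _impute(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float).copy()
        for j in range(X.shape[1]):
            col = X[:, j]
            col[np.isnan(col)] = self.fill_values_[j]
        return X

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        if pos.size == 0:
            raise ValueError("no positive training pairs")
        self.fill_values_ = np.array([
            (np.nanmin(X[:, j]) - 1.0) if np.isfinite(np.nanmin(X[:, j])) else 0.0
            for j in range(X.shape[1])
        ])
        Xi = self._impute(X)
        rng = np.random.default_rng(self.random_state)
        self.trees_ = []
        for _ in range(self.n_trees):
            ip = rng.choice(pos, size=pos.size, replace=True)
            nneg = min(self.neg_per_pos * pos.size, neg.size * 10)
            ineg = rng.choice(neg, size=nneg, replace=True)
            idx = np.concatenate([ip, ineg])
            tree = DecisionTreeClassifier(
                ccp_alpha=self.ccp_alpha,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(Xi[idx], y[idx])
            self.trees_.append(tree)
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _laplace_proba(tree: DecisionTreeClassifier, X: np.ndarray) -> np.ndarray:
        leaves = tree.apply(X)
        counts = tree.tree_.value[leaves][:, 0, :]  # per-leaf class counts
        if counts.shape[1] == 1:  # single-class tree
            only = tree.classes_[0]
            n = counts[:, 0]
            npos = n if only == 1 else np.zeros_like(n)
        else:
            n = counts.sum(axis=1)
            npos = counts[:, list(tree.classes_).index(1)]
        return (npos + 1.0) / (n + 2.0)

    def predict_proba(self, X) -> np.ndarray:
        Xi = self._impute(X)
        p = np.mean([self._laplace_proba(t, Xi) for t in self.trees_], axis=0)
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# grouped cross-validation
# ---------------------------------------------------------------------------

def group_genes_by_similarity(within_target_hits: Sequence[tuple[str, str, float]],
                              genes: Sequence[str],
                              e_cut: float = 1e-2) -> list[list[str]]:
    """Connected components of the within-target similarity graph
    (edges where E-value < e_cut; self-hits ignored); singletons allowed."""
    G = nx.Graph()
    G.add_nodes_from(genes)
    for a, b, e in within_target_hits:
        if a != b and e < e_cut:
            G.add_edge(a, b)
    comps = [sorted(c) for c in nx.connected_components(G)]
    comps.sort(key=lambda c: c[0])
    return comps


def grouped_cv_folds(groups: list[list[str]], k: int = 10,
                     seed: int = 0) -> dict[frozenset, int]:
    """Random fold per unordered *group* pair, expanded to gene pairs.

    Gene pairs inherit the fold of their group pair, so if G1~G3 and G2~G4
    the pairs (G1, G2) and (G3, G4) land in the same fold.  Returns
    {frozenset(gene_a, gene_b): fold}.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    n = len(groups)
    n_group_pairs = n * (n + 1) // 2  # includes within-group pairs
    if n_group_pairs < k:
        raise ValueError("fewer group pairs than folds")
    rng = np.random.default_rng(seed)
    fold_of_gp: dict[tuple[int, int], int] = {}
    for i in range(n):
        for j in range(i, n):
            fold_of_gp[(i, j)] = int(rng.integers(k))
    gene_group = {g: i for i, grp in enumerate(groups) for g in grp}
    out: dict[frozenset, int] = {}
    for i in range(n):
        for j in range(i, n):
            f = fold_of_gp[(i, j)]
            for a in groups[i]:
                for b in groups[j]:
                    if a != b:
                        out[frozenset((a, b))] = f
    return out


# ---------------------------------------------------------------------------
# score tables and the combination experiment
# ---------------------------------------------------------------------------

def _matrix_column(m: ScoreMatrix, pairs: list[tuple[str, str]]) -> np.ndarray:
    gi = {g: i for i, g in enumerate(m.genes)}
    return np.array([m.values[gi[a], gi[b]] for a, b in pairs])


def score_table(hits: Sequence[HomologyHit],
                ref_annotations: Sequence[GeneRecord],
                target_annotations: Sequence[GeneRecord],
                target_replicons: Sequence[RepliconInfo],
                genes: Sequence[str],
                organisms: Sequence[str],
                labels: dict[frozenset, int],
                score_set: Sequence[str] = ORIG_NEW_SCORES,
                e_threshold: float = 1e-4,
                Q: float = 50.0, E: float = 1e-4) -> pd.DataFrame:
    """Per-pair feature table for the combiners: one column per genome
    context score in ``score_set`` plus a ``label`` column.  Gene pairs
    involving genes with no homology information at all are excluded (their
    scores are outliers that distort training)."""
    prof = profiles.build_profiles(hits, genes, organisms, e_threshold)
    has_hom = prof.bits.sum(axis=1) > 0
    kept = [g for g, ok in zip(genes, has_hom) if ok]
    pairs = [(a, b) for a, b in evaluate.enumerate_pairs(kept)
             if frozenset((a, b)) in labels]

    mats: dict[str, ScoreMatrix] = {}
    need = set(score_set)
    if {"gn-pval"} & need:
        mats["gn-pval"] = neighbor.score_all_pairs_gn(
            hits, ref_annotations, genes, e_threshold, "pval")
    if {"gn-lnX", "gn-lnX.znorm"} & need:
        mats["gn-lnX"] = neighbor.score_all_pairs_gn(
            hits, ref_annotations, genes, e_threshold, "lnX")
        if "gn-lnX.znorm" in need:
            mats["gn-lnX.znorm"] = normalize.normalize(mats["gn-lnX"], "znorm")
    if {"pp-mutual-info", "pp-mutual-info.znorm"} & need:
        mats["pp-mutual-info"] = profiles.score_all_pairs_pp(prof, "mutual-info")
        if "pp-mutual-info.znorm" in need:
            mats["pp-mutual-info.znorm"] = normalize.normalize(
                mats["pp-mutual-info"], "znorm")
    if "gc" in need:
        mats["gc"] = proximity.gene_cluster_scores(
            target_annotations, target_replicons, gene_order=genes)
    if "gf" in need:
        mats["gf"] = proximity.score_all_pairs_gf(hits, genes, Q, E)

    data = {name: _matrix_column(mats[name], pairs) for name in score_set}
    data["label"] = np.array([labels[frozenset(p)] for p in pairs])
    return pd.DataFrame(data, index=pd.MultiIndex.from_tuples(pairs))


def _sens_at_spec(scores: np.ndarray, y: np.ndarray, floor: float) -> float:
    return evaluate.sensitivity_at_specificity(scores, y, floor)


def run_combination_experiment(
    train_tables: Sequence[pd.DataFrame],
    test_table: pd.DataFrame,
    score_set: Sequence[str] = ORIG_NEW_SCORES,
    protocol: str = "train-distant",
    k_folds: int = 10,
    groups: list[list[str]] | None = None,
    spec_floor: float = 0.99,
    seed: int = 0,
) -> dict[str, float]:
    """Sensitivity at specificity >= ``spec_floor`` for the two combiners
    and the best single score.

    ``grouped-cv``: ``test_table`` is also the training pool; group-pair
    folds produce out-of-fold combined scores for every pair.
    ``train-distant``: combiners fit on the concatenated ``train_tables``
    (worlds other than the test one) and apply to ``test_table``.
    """
    feats = list(score_set)
    y_test = test_table["label"].to_numpy()
    X_test = test_table[feats].to_numpy()

    def make_combiners():
        return {
            "product": ConfidenceProductCombiner(rule="product"),
            "trees": BaggedTreeCombiner(random_state=seed),
        }

    out: dict[str, float] = {}
    if protocol == "grouped-cv":
        if groups is None:
            groups = [[g] for g in sorted({g for p in test_table.index for g in p})]
        folds = grouped_cv_folds(groups, k=k_folds, seed=seed)
        fold_arr = np.array([folds[frozenset(p)] for p in test_table.index])
        for name, template in make_combiners().items():
            pred = np.full(len(test_table), np.nan)
            for f in range(k_folds):
                tr, te = fold_arr != f, fold_arr == f
                if te.sum() == 0 or y_test[tr].sum() == 0:
                    continue
                model = make_combiners()[name]
                model.fit(X_test[tr], y_test[tr])
                pred[te] = model.decision_function(X_test[te])
            out[name] = _sens_at_spec(pred, y_test, spec_floor)
    elif protocol == "train-distant":
        train = pd.concat(train_tables, axis=0)
        X_tr = train[feats].to_numpy()
        y_tr = train["label"].to_numpy()
        for name, model in make_combiners().items():
            model.fit(X_tr, y_tr)
            out[name] = _sens_at_spec(model.decision_function(X_test),
                                      y_test, spec_floor)
    else:
        raise ValueError("protocol must be 'grouped-cv' or 'train-distant'")

    singles = {f: _sens_at_spec(X_test[:, j], y_test, spec_floor)
               for j, f in enumerate(feats)}
    out["best_single"] = max(singles.values())
    out["best_single_name"] = max(singles, key=singles.get)
    out.update({f"single:{f}": v for f, v in singles.items()})
    return out


def combination_study(seed: int = 0, spec_floor: float = 0.99) -> dict[str, dict]:
    """The full combination experiment under both protocols.

    Study conditions: a well-curated target world (moderate co-presence and
    co-location signal, clean gold standard) evaluated by similarity-grouped
    cross-validation, and a train-distant condition whose training worlds
    come from a different regime — twice as many reference organisms, higher
    and flatter homolog frequencies (rescaling gn-lnX and the mutual-
    information margins), looser co-location, wider intergenic gaps, and an
    unreliable gold standard (30% curation error), as expected when training
    on phylogenetically distant, less-curated organisms.
    """
    from .synthetic import SimulationParams, simulate_world

    matched = SimulationParams(n_organisms=30, n_genes=80, n_modules=10,
                               co_presence_boost=0.65, co_location_prob=0.5,
                               fusion_rate=0.3, noise_rate=0.05)
    distant = SimulationParams(n_organisms=60, n_genes=80, n_modules=10,
                               presence_rate=0.8, rate_spread=0.05,
                               co_presence_boost=0.5, co_location_prob=0.4,
                               fusion_rate=0.2, noise_rate=0.08,
                               gap_scale=3.0, label_noise=0.3)

    def table(params, s):
        w = simulate_world(params, s)
        return score_table(w.hits, w.ref_genes, w.target_genes,
                           w.target_replicons, w.genes, w.organisms, w.labels)

    test = table(matched, seed + 13)
    train = [table(distant, seed + 11), table(distant, seed + 12)]
    cv_world = table(matched, seed + 11)
    return {
        "grouped-cv": run_combination_experiment(
            [], cv_world, protocol="grouped-cv", spec_floor=spec_floor,
            seed=seed),
        "train-distant": run_combination_experiment(
            train, test, protocol="train-distant", spec_floor=spec_floor,
            seed=seed),
    }
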