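"""Evaluation against a gold standard of functionally related gene pairs.

Scores are assumed oriented higher = more related.  Pairs a restricted-
coverage method could not score (the missing sentinel) rank strictly below
every scored pair.  Because ~99% of gene pairs are negative, the useful
operating region is the high-specificity corner, so alongside full ROC
curves the module reports sensitivity within the top p% of pairs and
cumulative accuracy (precision among pairs at or above a threshold).
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "enumerate_pairs",
    "confusion_at_threshold",
    "roc_curve",
    "sensitivity_at_top",
    "sensitivity_at_specificity",
    "cumulative_accuracy",
    "fold_improvement",
    "prepare_scores",
]


def enumerate_pairs(genes: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered distinct pairs; count = e(e-1)/2."""
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    return list(combinations(sorted(genes), 2))


def prepare_scores(scores: np.ndarray) -> np.ndarray:
    """Missing scores rank last: replace the sentinel with -inf."""
    s = np.asarray(scores, dtype=float).copy()
    s[np.isnan(s)] = -np.inf
    return s


def confusion_at_threshold(scores: np.ndarray, labels: np.ndarray,
                           t: float) -> dict[str, float]:
    """Counts and rates for the rule: positive call iff score >= t."""
    s = prepare_scores(scores)
    y = np.asarray(labels, dtype=int)
    p = int(y.sum())
    n = int(y.size - p)
    if p == 0 or n == 0:
        raise ValueError("need both positive and negative pairs")
    call = s >= t
    tp = int((call & (y == 1)).sum())
    fp = int((call & (y == 0)).sum())
    fn = p - tp
    tn = n - fp
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "sensitivity": tp / p, "specificity": tn / n}


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """(threshold, sensitivity, specificity) at every distinct score value
    plus the degenerate endpoints.  Tied scores move together."""
    s = prepare_scores(scores)
    y = np.asarray(labels, dtype=int)
    p = int(y.sum())
    n = int(y.size - p)
    if p == 0 or n == 0:
        raise ValueError("need both positive and negative pairs")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # last index of each tied block
    last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    rows = [(np.inf, 0.0, 1.0)]
    for i in np.flatnonzero(last):
        rows.append((s_sorted[i], tps[i] / p, (n - fps[i]) / n))
    return pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity"])


def sensitivity_at_top(scores: np.ndarray, labels: np.ndarray,
                       p_pct: float) -> float:
    """Sensitivity when the top p% of all pairs are called positive.

    k = round(p% of pairs) highest scores; ties at the cut resolve by the
    stable original pair order.
    """
    if not 0 < p_pct <= 100:
        raise ValueError("p_pct must be in (0, 100]")
    s = prepare_scores(scores)
    y = np.asarray(labels, dtype=int)
    total = s.size
    k = int(round(total * p_pct / 100.0))
    k = max(k, 1)
    order = np.argsort(-s, kind="stable")
    top = order[:k]
    p = int(y.sum())
    return float(y[top].sum() / p)


def sensitivity_at_specificity(scores: np.ndarray, labels: np.ndarray,
                               min_specificity: float) -> float:
    """Highest sensitivity attainable at specificity >= the given floor."""
    roc = roc_curve(scores, labels)
    ok = roc["specificity"] >= min_specificity
    return float(roc.loc[ok, "sensitivity"].max()) if ok.any() else 0.0


def cumulative_accuracy(scores: np.ndarray, labels: np.ndarray,
                        mode: str = "precision") -> pd.DataFrame:
    """Step function over score values.

    ``precision`` (default): CA(t) = positives among pairs with score >= t
    divided by pairs with score >= t.  ``recall``: the same numerator
    divided by the total number of positives.
    """
    if mode not in ("precision", "recall"):
        raise ValueError("mode must be 'precision' or 'recall'")
    s = prepare_scores(scores)
    y = np.asarray(labels, dtype=int)
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    ranks = np.arange(1, s.size + 1)
    last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    idx = np.flatnonzero(last)
    denom = ranks[idx] if mode == "precision" else int(y.sum())
    return pd.DataFrame({
        "threshold": s_sorted[idx],
        "cumulative_accuracy": tps[idx] / denom,
    })


def fold_improvement(precision_pct: float, prevalence_pct: float) -> float:
    """Precision as a multiple of the prevalence of positives (the accuracy
    of a random decision)."""
    if prevalence_pct <= 0:
        raise ValueError("prevalence must be positive")
    return precision_pct / prevalence_pct
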