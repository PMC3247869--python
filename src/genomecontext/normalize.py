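"""Score-matrix normalization.

Genome-context scores carry per-gene biases (e.g. frequent genes accumulate
small products of relative distances regardless of function), so raw scores
for different genes are not comparable under a single decision threshold.
Two row-wise normalizations borrowed from microarray analysis equalize the
per-gene score distributions:

* ``znorm``  per-row z-score: (M_ij - mu_i) / sigma_i;
* ``rnorm``  quantile normalization: each row's empirical distribution is
  mapped onto the mean of the row-sorted distributions.

Row normalization breaks symmetry, so the result is averaged with its
transpose.  The *composed* variants transpose the row-normalized matrix and
normalize again before symmetrizing, compensating for the second gene's
bias after the first has been removed.  Restricted-coverage matrices (gene
cluster, gene fusion) are rejected: too few scored pairs per row exist to
estimate row statistics.
"""

from __future__ import annotations

import warnings


import numpy as np
import pandas as pd

from .iokit import ProfileMatrix, ScoreMatrix

__all__ = [
    "znorm_rows",
    "rnorm_rows",
    "symmetrize",
    "normalize",
    "frequency_strata_report",
    "NORMALIZATIONS",
]

NORMALIZATIONS = ("znorm", "rnorm", "znorm-comp", "rnorm-comp")


def _row_normalized(values: np.ndarray, method: str, rnorm_target: str) -> np.ndarray:
    if method == "znorm":
        return _znorm_values(values)
    return _rnorm_values(values, rnorm_target)


def _znorm_values(values: np.ndarray) -> np.ndarray:
    out = np.full_like(values, np.nan)
    for i in range(values.shape[0]):
        row = values[i]
        ok = ~np.isnan(row)
        if ok.sum() < 2:
            continue
        mu = row[ok].mean()
        sd = row[ok].std()  # population SD
        if sd == 0:
            warnings.warn(f"constant row {i}: znorm sets it to 0")
            out[i, ok] = 0.0
        else:
            out[i, ok] = (row[ok] - mu) / sd
    return out


def _rnorm_values(values: np.ndarray, target: str = "mean") -> np.ndarray:
    """Quantile normalization of rows.  Rows with differing non-missing
    counts are mapped through interpolated quantile positions; tied entries
    share the mean of their tied target positions."""
    n = values.shape[0]
    counts = [int((~np.isnan(values[i])).sum()) for i in range(n)]
    full = max(counts) if counts else 0
    if full == 0:
        return values.copy()
    # target distribution: column summary of the row-sorted matrix,
    # interpolated onto a common quantile grid for ragged rows
    grid = np.linspace(0.0, 1.0, full)
    sorted_rows = []
    for i in range(n):
        row = values[i]
        vals = np.sort(row[~np.isnan(row)])
        if vals.size == 0:
            continue
        if vals.size == full:
            sorted_rows.append(vals)
        else:
            q = np.linspace(0.0, 1.0, vals.size)
            sorted_rows.append(np.interp(grid, q, vals))
    stacked = np.vstack(sorted_rows)
    if target == "mean":
        tdist = stacked.mean(axis=0)
    elif target == "median":
        tdist = np.median(stacked, axis=0)
    elif target == "uniform":
        tdist = grid.copy()
    else:
        raise ValueError(f"unknown rnorm target {target!r}")

    out = np.full_like(values, np.nan)
    for i in range(n):
        row = values[i]
        ok = ~np.isnan(row)
        k = int(ok.sum())
        if k == 0:
            continue
        # average rank for ties, mapped to target quantile positions
        ranks = pd.Series(row[ok]).rank(method="average").to_numpy() - 1.0
        q = ranks / (k - 1) if k > 1 else np.zeros(1)
        out[i, ok] = np.interp(q, grid, tdist) if full > 1 else tdist[0]
    return out


def znorm_rows(matrix: ScoreMatrix) -> ScoreMatrix:
    """Per-row z-normalization (asymmetric intermediate).  Missing entries
    and the diagonal are excluded from row statistics and stay missing."""
    out = matrix.copy()
    out.values = _znorm_values(matrix.values)
    out.method = f"{matrix.method}.znorm-rows"
    return out

def rnorm_rows(matrix: ScoreMatrix, target: str = "mean") -> ScoreMatrix:
    """Per-row quantile normalization (asymmetric intermediate)."""
    out = matrix.copy()
    out.values = _rnorm_values(matrix.values, target)
    out.method = f"{matrix.method}.rnorm-rows"
    return out


def symmetrize(matrix: ScoreMatrix) -> ScoreMatrix:
    """(M + M^T)/2; a pair missing on one side takes the present side's
    value; missing on both sides stays missing."""
    v = matrix.values
    vt = v.T
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        sym = np.where(
            np.isnan(v), vt,
            np.where(np.isnan(vt), v, (v + vt) / 2.0),
        )
    out = matrix.copy()
    out.values = sym
    return out


def normalize(matrix: ScoreMatrix, method: str = "znorm",
              rnorm_target: str = "mean") -> ScoreMatrix:
    """Full normalization pipeline on a full-coverage score matrix.

    ``znorm``/``rnorm``: row-normalize then symmetrize.  ``*-comp``:
    row-normalize, transpose, row-normalize again, then symmetrize.
    Normalization always runs on the full gene x gene matrix, even when
    evaluation later uses a gene subset.
    """
    if method not in NORMALIZATIONS:
        raise ValueError(f"unknown normalization {method!r}")
    if matrix.restricted:
        raise ValueError(
            "restricted-coverage matrices (gene cluster / gene fusion) are "
            "not normalized: too few scored pairs per row"
        )
    base = method.removesuffix("-comp")
    v = _row_normalized(matrix.values, base, rnorm_target)
    if method.endswith("-comp"):
        v = _row_normalized(v.T, base, rnorm_target)
    out = matrix.copy()
    out.values = v
    out.method = f"{matrix.method}.{method}"
    return symmetrize(out)


def frequency_strata_report(
    matrix: ScoreMatrix,
    profiles: ProfileMatrix,
    labels: dict[frozenset, int],
    n_strata: int = 3,
) -> pd.DataFrame:
    """Score distributions stratified by gene frequency.

    Frequency of a gene is the proportion of reference organisms containing
    a homolog.  Pairs are assigned to the stratum of their *lower*-frequency
    gene (terciles by default), split by gold-standard label, and summarized
    (count, median, mean, SD).  Comparing this report before and after
    normalization shows whether a single decision threshold can serve both
    frequent and infrequent genes.  Empty strata are omitted.
    """
    freq = {g: float(profiles.bits[i].mean())
            for i, g in enumerate(profiles.genes)}
    edges = np.quantile(list(freq.values()), np.linspace(0, 1, n_strata + 1))
    edges[0], edges[-1] = -np.inf, np.inf

    def stratum(g: str) -> int:
        return int(np.searchsorted(edges[1:-1], freq[g], side="right"))

    rows = []
    gi = {g: i for i, g in enumerate(matrix.genes)}
    for key, label in labels.items():
        a, b = sorted(key)
        if a not in gi or b not in gi or a not in freq or b not in freq:
            continue
        v = matrix.values[gi[a], gi[b]]
        if np.isnan(v):
            continue
        rows.append((min(stratum(a), stratum(b)), label, v))
    df = pd.DataFrame(rows, columns=["stratum", "label", "score"])
    if df.empty:
        return pd.DataFrame(columns=["stratum", "label", "count", "median", "mean", "sd"])
    rep = (df.groupby(["stratum", "label"])["score"]
             .agg(count="count", median="median", mean="mean", sd="std")
             .reset_index())
    return rep
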