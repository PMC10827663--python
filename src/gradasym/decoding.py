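"""Percentile-binned weighted-score decoding of a statistic map.

A statistic map (e.g. the per-parcel group-difference t values of one
hemisphere) is ranked and cut into equal-size contiguous bins (20 bins =
5% per bin by default); each bin's loading is the mean statistic of its
parcels. A cognitive term's score is the sum over bins of the mean
positive activation (z > 0) of the term's map within the bin, weighted by
the bin loading. Higher scores mean the term's activation pattern
concentrates where the statistic is large.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DimensionError, ParameterError


def bin_map(stat_map: np.ndarray, n_bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Rank parcels by the statistic and cut into contiguous equal bins.

    Returns (bin assignment per parcel, loading per bin). Bin 0 holds the
    lowest values. When n_bins does not divide the parcel count, the
    remainder is spread deterministically over the lowest bins (one extra
    parcel each). Ties break by parcel index (stable sort).
    """
    v = np.asarray(stat_map, dtype=float)
    if v.ndim != 1:
        raise DimensionError("stat_map must be 1-D")
    n = v.size
    if not (1 <= n_bins <= n):
        raise ParameterError(f"n_bins must be in [1, {n}], got {n_bins}")
    order = np.argsort(v, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base)
    sizes[:rem] += 1
    assignment = np.empty(n, dtype=int)
    loadings = np.empty(n_bins)
    start = 0
    for b in range(n_bins):
        members = order[start : start + sizes[b]]
        assignment[members] = b
        loadings[b] = v[members].mean()
        start += sizes[b]
    return assignment, loadings


def weighted_term_score(
    term_z: np.ndarray, assignment: np.ndarray, loadings: np.ndarray
) -> float:
    """Sum over bins of (mean positive activation in bin) x (bin loading).

    A bin with no positive activation contributes 0.
    """
    z = np.asarray(term_z, dtype=float)
    if z.shape != assignment.shape:
        raise DimensionError("term map and bin assignment differ in length")
    score = 0.0
    for b in range(loadings.size):
        zb = z[assignment == b]
        pos = zb[zb > 0]
        if pos.size:
            score += pos.mean() * loadings[b]
    return float(score)


def decode(
    stat_map: np.ndarray,
    term_dictionary: pd.DataFrame,
    n_bins: int = 20,
    absolute_loadings: bool = False,
) -> pd.DataFrame:
    """Score every term in the dictionary against one statistic map.

    ``term_dictionary`` is a wide table: one column per term, one row per
    parcel. Negative bin loadings contribute as-is (signed) by default;
    ``absolute_loadings`` switches to |loading|. Returns terms ranked by
    descending score.
    """
    if term_dictionary.shape[1] < 1:
        raise ParameterError("term dictionary is empty")
    v = np.asarray(stat_map, dtype=float)
    if len(term_dictionary) != v.size:
        raise DimensionError(
            f"dictionary has {len(term_dictionary)} parcels, map has {v.size}"
        )
    assignment, loadings = bin_map(v, n_bins)
    if absolute_loadings:
        loadings = np.abs(loadings)
    rows = [
        {"term": col, "score": weighted_term_score(
            term_dictionary[col].to_numpy(), assignment, loadings)}
        for col in term_dictionary.columns
    ]
    out = pd.DataFrame(rows).sort_values(
        "score", ascending=False, kind="stable"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
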