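"""Prioritisation of population pairs for common-garden bioassays.

Every trait and proxy distance matrix is min-max standardised to [0, 1],
averaged over replicates to the population-pair level, and summed per pair
across proxies (and, separately, across traits).  The pair sums are split
into indifference groups by 1-D k-means — k chosen by the Elbow method —
and groups are lettered A, B, C... by descending mean sum, cluster A being
the shortlist of pairs most likely to diverge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrices import DistanceMatrix, POPULATION

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# standardisation and pair aggregation
# --------------------------------------------------------------------------


def minmax_standardise(m: DistanceMatrix) -> DistanceMatrix:
    """Rescale off-diagonal distances to [0, 1]; the diagonal stays 0."""
    off = m.condensed()
    lo, hi = off.min(), off.max()
    if hi == lo:
        raise ValueError("degenerate matrix: all off-diagonal distances equal")
    vals = (m.values - lo) / (hi - lo)
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(m.labels, vals, level=m.level)


def pair_means(
    m: DistanceMatrix, population_map: Mapping[str, str] | None = None
) -> pd.Series:
    """Average distances down to one value per unordered population pair.

    Replicate-level matrices need ``population_map`` (replicate label ->
    population); the mean is over all cross-population replicate pairs.
    Population-level matrices pass through unchanged.
    """
    if m.level == POPULATION:
        pops = m.labels
        values = {}
        for i, a in enumerate(pops):
            for j in range(i):
                values[_pair_key(a, pops[j])] = m.values[i, j]
        return pd.Series(values, name="distance")
    if population_map is None:
        raise ValueError("replicate-level matrix needs a population_map")
    unmapped = [r for r in m.labels if r not in population_map]
    if unmapped:
        raise KeyError(f"unmapped replicates: {unmapped}")
    pops = list(dict.fromkeys(population_map[r] for r in m.labels))
    groups = {p: [i for i, r in enumerate(m.labels) if population_map[r] == p] for p in pops}
    values = {}
    for i, a in enumerate(pops):
        for j in range(i):
            block = m.values[np.ix_(groups[a], groups[pops[j]])]
            values[_pair_key(a, pops[j])] = float(block.mean())
    return pd.Series(values, name="distance")


def _pair_key(a: str, b: str) -> str:
    return f"{a}-{b}"


def sum_distances(per_matrix: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Componentwise per-pair sum across matrices (one column per matrix)."""
    df = pd.DataFrame(per_matrix)
    if df.isna().any().any():
        missing = df[df.isna().any(axis=1)].index.tolist()
        raise ValueError(f"pairs missing from some matrices: {missing}")
    df["sum"] = df.sum(axis=1)
    return df


# --------------------------------------------------------------------------
# 1-D k-means with exact dynamic-programming verification
# --------------------------------------------------------------------------


def _segment_costs(sorted_vals: np.ndarray) -> np.ndarray:
    """cost[i, j] = within-segment sum of squares of sorted_vals[i..j]."""
    n = len(sorted_vals)
    s1 = np.concatenate([[0.0], np.cumsum(sorted_vals)])
    s2 = np.concatenate([[0.0], np.cumsum(sorted_vals**2)])
    cost = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            cnt = j - i + 1
            tot = s1[j + 1] - s1[i]
            cost[i, j] = (s2[j + 1] - s2[i]) - tot * tot / cnt
    return cost


def _dp_partition(sorted_vals: np.ndarray, k: int) -> tuple[list[int], float]:
    """Optimal contiguous k-partition of sorted 1-D values (exact WSS)."""
    n = len(sorted_vals)
    cost = _segment_costs(sorted_vals)
    dp = np.full((k + 1, n + 1), np.inf)
    cut = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            for i in range(kk - 1, j):
                c = dp[kk - 1, i] + cost[i, j - 1]
                if c < dp[kk, j]:
                    dp[kk, j] = c
                    cut[kk, j] = i
    bounds = [n]
    for kk in range(k, 0, -1):
        bounds.append(cut[kk, bounds[-1]])
    bounds = bounds[::-1]
    labels = np.zeros(n, dtype=int)
    for g in range(k):
        labels[bounds[g]:bounds[g + 1]] = g
    return labels.tolist(), float(dp[k, n])


def _lloyd(values: np.ndarray, k: int, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    centroids = rng.choice(np.unique(values), size=k, replace=False).astype(float)
    for _ in range(300):
        labels = np.argmin(np.abs(values[:, None] - centroids[None, :]), axis=1)
        new = np.array([
            values[labels == g].mean() if np.any(labels == g) else centroids[g]
            for g in range(k)
        ])
        if np.allclose(new, centroids):
            break
        centroids = new
    wss = float(sum(((values[labels == g] - centroids[g]) ** 2).sum() for g in range(k)))
    return labels, wss


def kmeans_1d(
    values: Sequence[float], k: int, seed: int | None = None, restarts: int = 50
) -> np.ndarray:
    """Optimal 1-D k-means labels (0..k-1, arbitrary group numbering).

    Best-of-``restarts`` Lloyd iterations, cross-checked against the exact
    dynamic-programming partition (optimal 1-D clusters are contiguous in
    sorted order); the exact partition is returned, with a log message if
    Lloyd's best restart missed it.
    """
    values = np.asarray(values, dtype=float)
    n_distinct = len(np.unique(values))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds {n_distinct} distinct values")
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    dp_labels_sorted, dp_wss = _dp_partition(sorted_vals, k)
    labels = np.empty(len(values), dtype=int)
    labels[order] = dp_labels_sorted
    rng = np.random.default_rng(seed)
    best_lloyd = np.inf
    for _ in range(restarts):
        _, wss = _lloyd(values, k, rng)
        best_lloyd = min(best_lloyd, wss)
    if best_lloyd > dp_wss + 1e-9:
        logger.info(
            "Lloyd best WSS %.6g above exact optimum %.6g; using exact partition",
            best_lloyd, dp_wss,
        )
    return labels


def wss_for_k(values: Sequence[float], k: int) -> float:
    """Exact within-cluster sum of squares of the optimal k-clustering."""
    values = np.asarray(values, dtype=float)
    return _dp_partition(np.sort(values), k)[1]


def elbow_k(values: Sequence[float], k_max: int = 10) -> int:
    """Pick k by the Elbow rule on the exact WSS curve.

    k in 1..k_max maximising the perpendicular distance from (k, WSS(k)) to
    the chord joining (1, WSS(1)) and (k_max, WSS(k_max)).
    """
    values = np.asarray(values, dtype=float)
    n_distinct = len(np.unique(values))
    if k_max >= n_distinct:
        logger.warning("k_max %d >= %d distinct values; lowering", k_max, n_distinct)
        k_max = n_distinct - 1
    if k_max < 2:
        return 1
    ks = np.arange(1, k_max + 1)
    wss = np.array([wss_for_k(values, k) for k in ks])
    # chord from (1, wss[0]) to (k_max, wss[-1])
    x0, y0, x1, y1 = 1.0, wss[0], float(k_max), wss[-1]
    norm = np.hypot(x1 - x0, y1 - y0)
    dist = np.abs((y1 - y0) * ks - (x1 - x0) * wss + x1 * y0 - y1 * x0) / norm
    return int(ks[np.argmax(dist)])


# --------------------------------------------------------------------------
# cluster ranking and the prioritisation table
# --------------------------------------------------------------------------


def rank_clusters(
    labels: np.ndarray, values: Sequence[float], letters: bool = True
) -> list[str]:
    """Name clusters by descending mean value: A, B, C... (or 1, 2, 3...).

    Tied means fall back to descending cluster maximum, with a log message.
    """
    labels = np.asarray(labels)
    values = np.asarray(values, dtype=float)
    groups = np.unique(labels)
    means = {g: values[labels == g].mean() for g in groups}
    maxima = {g: values[labels == g].max() for g in groups}
    if len({round(m, 12) for m in means.values()}) < len(groups):
        logger.warning("tied cluster means; ordering by descending cluster maximum")
    ranked = sorted(groups, key=lambda g: (-means[g], -maxima[g]))
    if letters:
        name = {g: chr(ord("A") + i) for i, g in enumerate(ranked)}
    else:
        name = {g: str(i + 1) for i, g in enumerate(ranked)}
    return [name[g] for g in labels]


def prioritise(
    matrices: Mapping[str, DistanceMatrix],
    population_map: Mapping[str, str] | None = None,
    k: int | None = None,
    k_max: int = 10,
    seed: int | None = None,
    letters: bool = True,
    standardise_first: bool = True,
) -> pd.DataFrame:
    """Full prioritisation: standardise, pair-average, sum, cluster, letter.

    Returns a table with one row per population pair: the standardised
    distance under each matrix, their sum, and the cluster identity.  By
    default matrices are standardised at their native (replicate) level and
    then averaged to pairs; ``standardise_first=False`` flips that order for
    sensitivity checks.
    """
    per_matrix = {}
    for name, m in matrices.items():
        if standardise_first:
            per_matrix[name] = pair_means(minmax_standardise(m), population_map)
        else:
            means = pair_means(m, population_map)
            lo, hi = means.min(), means.max()
            if hi == lo:
                raise ValueError(f"degenerate matrix {name!r}")
            per_matrix[name] = (means - lo) / (hi - lo)
    table = sum_distances(per_matrix)
    sums = table["sum"].to_numpy()
    if k is None:
        k = elbow_k(sums, k_max=k_max)
        logger.info("elbow method selected k=%d", k)
    labels = kmeans_1d(sums, k, seed=seed)
    table["cluster"] = rank_clusters(labels, sums, letters=letters)
    return table.sort_values("sum", ascending=False)
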