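"""Builders for the five distance matrices the analysis runs on.

* trait distances        — per-trait Euclidean distances between replicates
* habitat divergence     — PCA of z-scored environmental variables
                           (Kaiser-Guttman axis retention) followed by
                           Bray-Curtis distance on the retained scores
* geographic distance    — Vincenty geodesic on the WGS84 ellipsoid
* hydrologic distance    — circuit-theory effective resistance on a
                           conductance raster (rivers/lakes conduct 1+k,
                           plain land 1)
* genetic distance       — pairwise PhiST from aligned haplotypes, the
                           two-level AMOVA fixation index
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .matrices import DistanceMatrix, POPULATION, REPLICATE

logger = logging.getLogger(__name__)

# WGS84 ellipsoid
WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
WGS84_B = WGS84_A * (1.0 - WGS84_F)


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class ConductanceRaster:
    """Per-cell conductance grid with a site -> cell mapping.

    ``grid`` holds conductances (> 0); NaN marks NODATA barrier cells that
    are removed from the resistance graph.  ``site_cells`` maps each site
    label to its (row, col) cell; sites must occupy distinct cells.
    """

    grid: np.ndarray
    site_cells: dict[str, tuple[int, int]]
    cellsize: float = 1.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    k: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        valid = self.grid[np.isfinite(self.grid)]
        if np.any(valid <= 0):
            raise ValueError("conductance must be positive everywhere")
        nrows, ncols = self.grid.shape
        seen: dict[tuple[int, int], str] = {}
        for label, (r, c) in self.site_cells.items():
            if not (0 <= r < nrows and 0 <= c < ncols):
                raise ValueError(f"site {label!r} cell ({r},{c}) outside raster bounds")
            if (r, c) in seen:
                raise ValueError(f"sites {seen[(r, c)]!r} and {label!r} share cell ({r},{c})")
            seen[(r, c)] = label


@dataclass
class HaplotypeSet:
    """Aligned haplotype sequences for one population.

    Sequences are uppercase strings over {A, C, G, T, -}; multi-step repeat
    array differences are assumed pre-collapsed to single sites.
    """

    population: str
    sequences: list[str]

    def __post_init__(self) -> None:
        self.sequences = [s.upper() for s in self.sequences]
        if not self.sequences:
            raise ValueError(f"population {self.population!r} has no sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment in population {self.population!r}: lengths {sorted(lengths)}")
        bad = set("".join(self.sequences)) - set("ACGT-N")
        if bad:
            raise ValueError(f"invalid characters in {self.population!r}: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])


# --------------------------------------------------------------------------
# trait distances
# --------------------------------------------------------------------------


def euclidean_trait_distance(values: pd.Series, level: str = REPLICATE) -> DistanceMatrix:
    """Pairwise |x_i - x_j| for one scalar trait measured per replicate."""
    if values.isna().any():
        missing = values[values.isna()].index.tolist()
        raise ValueError(f"missing replicate values: {missing}")
    labels = ["::".join(map(str, i)) if isinstance(i, tuple) else str(i) for i in values.index]
    x = values.to_numpy(dtype=float)
    return DistanceMatrix(labels, np.abs(x[:, None] - x[None, :]), level=level)


# --------------------------------------------------------------------------
# habitat divergence
# --------------------------------------------------------------------------


def pca_scores(env: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, int]:
    """Z-score variables, eigendecompose, apply the Kaiser-Guttman rule.

    Returns (scores, eigenvalues, n_retained).  Constant variables are
    dropped with a warning before standardisation.  The mean eigenvalue is
    taken over all variables (for a correlation matrix this is the classic
    'eigenvalue > 1' rule).
    """
    if env.shape[0] < 2:
        raise ValueError("need >= 2 sites")
    if env.shape[1] < 2:
        raise ValueError("need >= 2 environmental variables")
    sd = env.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        logger.warning("dropping constant environmental variables: %s", constant)
        env = env.drop(columns=constant)
        sd = sd.drop(constant)
    z = (env - env.mean()) / sd
    x = z.to_numpy(dtype=float)
    cov = np.cov(x, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    n_keep = int(np.sum(eigval > eigval.mean()))
    n_keep = max(n_keep, 1)
    scores = x @ eigvec
    total = eigval.sum()
    logger.info(
        "habitat PCA: retaining %d axes (Kaiser-Guttman), %.1f%% of variance",
        n_keep, 100.0 * eigval[:n_keep].sum() / total if total else 0.0,
    )
    return scores, eigval, n_keep


def bray_curtis(a: np.ndarray, b: np.ndarray) -> float:
    """BC = sum|x-y| / sum(x+y); 0 when both vectors are all-zero."""
    num = float(np.abs(a - b).sum())
    den = float((a + b).sum())
    return num / den if den != 0 else 0.0


def habitat_divergence(
    env: pd.DataFrame,
    replicate_map: Mapping[str, str] | None = None,
    mode: str = "shifted",
) -> DistanceMatrix:
    """Habitat divergence between sites (or their replicates).

    PCA scores on the retained axes feed a Bray-Curtis distance.  In the
    default ``"shifted"`` mode each retained axis is translated so its
    minimum is zero, keeping Bray-Curtis within [0, 1]; ``"raw"`` applies
    the formula to the signed scores literally.  With a ``replicate_map``
    (replicate label -> site) every replicate inherits its site's scores, so
    within-site replicate distances are exactly zero.
    """
    if mode not in ("shifted", "raw"):
        raise ValueError(f"unknown mode {mode!r}")
    scores, _, n_keep = pca_scores(env)
    s = scores[:, :n_keep].copy()
    if mode == "shifted":
        s -= s.min(axis=0, keepdims=True)
    site_scores = {site: s[i] for i, site in enumerate(env.index.astype(str))}
    if replicate_map is None:
        labels = list(site_scores)
        level = POPULATION
        rows = [site_scores[l] for l in labels]
    else:
        missing = set(replicate_map.values()) - set(site_scores)
        if missing:
            raise KeyError(f"replicate_map references unknown sites: {sorted(missing)}")
        labels = list(replicate_map)
        level = REPLICATE
        rows = [site_scores[replicate_map[l]] for l in labels]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i):
            d[i, j] = d[j, i] = bray_curtis(rows[i], rows[j])
    return DistanceMatrix(labels, d, level=level)


# --------------------------------------------------------------------------
# geographic distance (Vincenty inverse on WGS84)
# --------------------------------------------------------------------------


def vincenty(lat1: float, lon1: float, lat2: float, lon2: float,
             tol: float = 1e-12, max_iter: int = 200) -> float:
    """Geodesic distance in metres between two WGS84 points.

    Vincenty's inverse iteration; nearly-antipodal pairs that fail to
    converge fall back to the spherical great-circle on the mean radius,
    with a logged warning.
    """
    if abs(lat1) > 90 or abs(lat2) > 90 or abs(lon1) > 180 or abs(lon2) > 180:
        raise ValueError("coordinates out of range")
    if lat1 == lat2 and lon1 == lon2:
        return 0.0
    a, b, f = WGS84_A, WGS84_B, WGS84_F
    U1 = math.atan((1 - f) * math.tan(math.radians(lat1)))
    U2 = math.atan((1 - f) * math.tan(math.radians(lat2)))
    L = math.radians(lon2 - lon1)
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)
    lam = L
    for _ in range(max_iter):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
        if sin_sigma == 0:
            return 0.0  # coincident
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha**2
        cos_2sigma_m = cos_sigma - 2 * sinU1 * sinU2 / cos2_alpha if cos2_alpha else 0.0
        C = f / 16 * cos2_alpha * (4 + f * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = L + (1 - C) * f * sin_alpha * (
            sigma + C * sin_sigma * (cos_2sigma_m + C * cos_sigma * (-1 + 2 * cos_2sigma_m**2))
        )
        if abs(lam - lam_prev) < tol:
            break
    else:
        logger.warning(
            "Vincenty failed to converge for (%.6f,%.6f)-(%.6f,%.6f); "
            "falling back to spherical great-circle", lat1, lon1, lat2, lon2,
        )
        return _haversine(lat1, lon1, lat2, lon2)
    u2 = cos2_alpha * (a**2 - b**2) / b**2
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    delta_sigma = B * sin_sigma * (
        cos_2sigma_m + B / 4 * (
            cos_sigma * (-1 + 2 * cos_2sigma_m**2)
            - B / 6 * cos_2sigma_m * (-3 + 4 * sin_sigma**2) * (-3 + 4 * cos_2sigma_m**2)
        )
    )
    return b * A * (sigma - delta_sigma)


def _haversine(lat1, lon1, lat2, lon2) -> float:
    r = (2 * WGS84_A + WGS84_B) / 3
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp, dl = p2 - p1, math.radians(lon2 - lon1)
    h = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * r * math.asin(math.sqrt(h))


def great_circle_distance(coords: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Vincenty distances in km between sites.

    ``coords`` is indexed by site with columns ``latitude`` and ``longitude``
    in decimal degrees (WGS84).
    """
    labels = coords.index.astype(str).tolist()
    lat = coords["latitude"].to_numpy(dtype=float)
    lon = coords["longitude"].to_numpy(dtype=float)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i):
            d[i, j] = d[j, i] = vincenty(lat[i], lon[i], lat[j], lon[j]) / 1000.0
    return DistanceMatrix(labels, d, level=POPULATION)


# --------------------------------------------------------------------------
# hydrologic distance (circuit-theory effective resistance)
# --------------------------------------------------------------------------


def resistance_distance(raster: ConductanceRaster) -> DistanceMatrix:
    """Pairwise effective resistance between site cells.

    Cells are nodes; 4-neighbour edges carry conductance equal to the mean
    of the two cell conductances.  Effective resistance comes from the graph
    Laplacian pseudoinverse: R_ij = L+_ii + L+_jj - 2 L+_ij, which sums the
    contribution of every path between the two cells.
    """
    grid = raster.grid
    nrows, ncols = grid.shape
    valid = np.isfinite(grid)
    index = -np.ones(grid.shape, dtype=int)
    index[valid] = np.arange(valid.sum())
    n = int(valid.sum())

    rows, cols, w = [], [], []
    for dr, dc in ((0, 1), (1, 0)):
        a = np.zeros_like(valid)
        a[: nrows - dr, : ncols - dc] = valid[: nrows - dr, : ncols - dc] & valid[dr:, dc:]
        r0, c0 = np.nonzero(a)
        g = 0.5 * (grid[r0, c0] + grid[r0 + dr, c0 + dc])
        rows.extend(index[r0, c0]); cols.extend(index[r0 + dr, c0 + dc]); w.extend(g)

    adj = coo_matrix((w + w, (rows + cols, cols + rows)), shape=(n, n)).tocsr()
    site_nodes = {label: index[rc] for label, rc in raster.site_cells.items()}
    n_comp, comp = connected_components(adj, directed=False)
    if n_comp > 1:
        by_comp: dict[int, list[str]] = {}
        for label, node in site_nodes.items():
            by_comp.setdefault(int(comp[node]), []).append(label)
        if len(by_comp) > 1:
            parts = "; ".join(f"component {k}: {sorted(v)}" for k, v in sorted(by_comp.items()))
            raise ValueError(f"sites are not hydrologically connected ({parts})")

    lap = (np.diag(np.asarray(adj.sum(axis=1)).ravel()) - adj.toarray())
    lplus = np.linalg.pinv(lap, hermitian=True)
    labels = list(site_nodes)
    idx = np.array([site_nodes[l] for l in labels])
    diag = lplus[idx, idx]
    r = diag[:, None] + diag[None, :] - 2 * lplus[np.ix_(idx, idx)]
    r = np.clip((r + r.T) / 2.0, 0.0, None)  # pinv round-off hygiene
    np.fill_diagonal(r, 0.0)
    return DistanceMatrix(labels, r, level=POPULATION)


# --------------------------------------------------------------------------
# genetic distance (pairwise PhiST, two-level AMOVA)
# --------------------------------------------------------------------------


def hamming(a: str, b: str) -> int:
    """Count of differing aligned positions (gaps count as a fifth state)."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))


def pairwise_phi_st(pop_a: HaplotypeSet, pop_b: HaplotypeSet) -> float:
    """PhiST between two populations from molecular pairwise differences.

    Standard two-level AMOVA on haplotype data: pairwise difference counts
    serve as squared molecular distances; sums of squared deviations within
    and among populations yield the variance components sigma2_w and
    sigma2_a, and PhiST = sigma2_a / (sigma2_a + sigma2_w).  Zero total
    variance returns 0 by convention.
    """
    seqs = pop_a.sequences + pop_b.sequences
    na, nb = len(pop_a.sequences), len(pop_b.sequences)
    n_tot = na + nb
    enc = np.array([np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs])
    d2 = (enc[:, None, :] != enc[None, :, :]).sum(axis=2).astype(float)
    ssd_total = d2[np.tril_indices(n_tot, -1)].sum() / n_tot
    ssd_wa = d2[:na, :na][np.tril_indices(na, -1)].sum() / na
    ssd_wb = d2[na:, na:][np.tril_indices(nb, -1)].sum() / nb
    ssd_within = ssd_wa + ssd_wb
    ssd_among = ssd_total - ssd_within
    df_within = n_tot - 2
    sigma_w = ssd_within / df_within if df_within > 0 else 0.0
    n0 = (n_tot - (na**2 + nb**2) / n_tot)  # df_among = 1
    sigma_a = (ssd_among - sigma_w) / n0
    denom = sigma_a + sigma_w
    if denom == 0:
        return 0.0
    return sigma_a / denom


def phi_st(pops: Sequence[HaplotypeSet]) -> DistanceMatrix:
    """Pairwise PhiST matrix over populations.

    Finite-sample estimates can dip slightly below zero; negatives are
    clamped to 0 so the result is a valid distance matrix, the convention
    used downstream (:func:`pairwise_phi_st` gives the raw estimate).
    """
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    lengths = {p.length for p in pops}
    if len(lengths) != 1:
        raise ValueError(f"populations are not aligned to a common length: {sorted(lengths)}")
    for p in pops:
        if len(p.sequences) < 2:
            raise ValueError(f"population {p.population!r} needs >= 2 sequences")
    labels = [p.population for p in pops]
    n = len(pops)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i):
            v = pairwise_phi_st(pops[i], pops[j])
            if v < 0:
                logger.debug("clamping negative PhiST %.4g for %s-%s", v, labels[i], labels[j])
                v = 0.0
            d[i, j] = d[j, i] = v
    return DistanceMatrix(labels, d, level=POPULATION)
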