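"""MRDM-CA: regression on distance matrices with commonality partitioning.

The statistical core of the pipeline.  A trait (KTA) distance matrix is
regressed on a set of standardised proxy distance matrices (multiple
regression on distance matrices, MRDM), with inference by unit-level
permutation of the response matrix.  The model R2 is then decomposed by
commonality analysis (CA) into the 2^p - 1 unique and common variance
contributions of the proxies.  Total suppressors — proxies whose apparent
effect is an artefact of collinearity — are detected from the partition
(classical suppression: negative common contribution cancelling the unique
one) or from the fit (cross-over suppression: beta and r of opposite sign)
and removed iteratively until none remain.  Mantel tests give the simple
(one-proxy-at-a-time) correlations, and Benjamini-Hochberg correction
controls the false discovery rate across trait models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .matrices import DistanceMatrix, check_same_labels

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# unfolding
# --------------------------------------------------------------------------


@dataclass
class UnfoldedVectors:
    """Lower-triangle vectorisation of a response and its predictors.

    ``response`` is the strict lower triangle (row-major) of the trait
    matrix; each predictor column is the same unfolding of a proxy matrix,
    z-scored to mean 0 / sd 1.  ``n_units`` is the number of matrix rows, so
    vectors have length n_units * (n_units - 1) / 2.
    """

    response: np.ndarray
    predictors: np.ndarray
    names: list[str]
    n_units: int
    response_matrix: np.ndarray = field(repr=False, default=None)

    def subset(self, keep: list[str]) -> "UnfoldedVectors":
        cols = [self.names.index(k) for k in keep]
        return UnfoldedVectors(
            self.response, self.predictors[:, cols], list(keep),
            self.n_units, self.response_matrix,
        )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("constant predictor vector cannot be standardised")
    return (x - x.mean()) / sd


def unfold(kta: DistanceMatrix, proxies: dict[str, DistanceMatrix]) -> UnfoldedVectors:
    """Vectorise a trait matrix and proxy matrices into regression form.

    All matrices must share the same labels in the same order (expand
    population-level proxies to replicate level first when the trait matrix
    is replicate-level).
    """
    check_same_labels(kta, *proxies.values())
    y = kta.condensed()
    x = np.column_stack([_zscore(m.condensed()) for m in proxies.values()])
    return UnfoldedVectors(y, x, list(proxies), kta.n, kta.values)


# --------------------------------------------------------------------------
# MRDM
# --------------------------------------------------------------------------


@dataclass
class MRDMResult:
    r_squared: float
    p_r_squared: float | None
    r: dict[str, float]        # simple Pearson correlation per predictor
    beta: dict[str, float]     # standardised regression weight per predictor
    n_perm: int = 0


def _r_squared(y: np.ndarray, x: np.ndarray) -> float:
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss == 0:
        raise ValueError("constant response")
    q, rmat = np.linalg.qr(x - x.mean(axis=0))
    if np.min(np.abs(np.diag(rmat))) < 1e-10 * max(1.0, np.max(np.abs(rmat))):
        raise np.linalg.LinAlgError("singular design")
    proj = q.T @ yc
    return float(proj @ proj) / tss


def mrdm(u: UnfoldedVectors, n_perm: int = 1000, seed: int | None = None) -> MRDMResult:
    """OLS of the unfolded trait distances on the standardised proxies.

    The permutation null relabels the response matrix's units (joint
    row/column permutation) before re-unfolding — element-wise shuffling
    would break the dependence structure of distances.  The p-value uses the
    add-one convention p = (1 + #{R2_perm >= R2_obs}) / (1 + n_perm).
    """
    y, x = u.response, u.predictors
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss == 0:
        raise ValueError("constant response matrix")
    xc = x - x.mean(axis=0)
    q, rmat = np.linalg.qr(xc)
    rdiag = np.abs(np.diag(rmat))
    if np.min(rdiag) < 1e-10 * max(1.0, rdiag.max()):
        bad = [u.names[i] for i in np.argsort(rdiag)[:2]]
        raise np.linalg.LinAlgError(f"singular design; near-collinear predictors involve {bad}")
    coef = np.linalg.solve(rmat, q.T @ yc)
    r2 = float((q.T @ yc) @ (q.T @ yc)) / tss
    sy = y.std()
    beta = {name: float(c) / sy for name, c in zip(u.names, coef)}
    r = {
        name: float(np.corrcoef(y, x[:, k])[0, 1])
        for k, name in enumerate(u.names)
    }
    p = None
    if n_perm >= 1:
        rng = np.random.default_rng(seed)
        tri = np.tril_indices(u.n_units, k=-1)
        d = u.response_matrix
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(u.n_units)
            yp = d[np.ix_(perm, perm)][tri]
            ypc = yp - yp.mean()
            tssp = float(ypc @ ypc)
            proj = q.T @ ypc
            r2p = float(proj @ proj) / tssp
            if r2p >= r2 - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm)
    return MRDMResult(r2, p, r, beta, n_perm)


# --------------------------------------------------------------------------
# commonality analysis
# --------------------------------------------------------------------------


@dataclass
class CommonalityPartition:
    """All 2^p - 1 commonality coefficients of a fitted MRDM.

    ``coefficients`` maps each non-empty predictor subset (a sorted tuple of
    names) to its commonality coefficient.  ``unique[i]`` is the coefficient
    of the singleton {i}; ``common[i]`` sums the coefficients of every
    subset of size >= 2 containing i.  The coefficients sum to the full
    model R2 exactly.
    """

    coefficients: dict[tuple[str, ...], float]
    unique: dict[str, float]
    common: dict[str, float]
    r_squared: float


def commonality(u: UnfoldedVectors) -> CommonalityPartition:
    """Decompose the full-model R2 over all predictor subsets.

    For each non-empty subset S of the predictor set P the coefficient is
    the inclusion-exclusion combination
    C(S) = - sum_{T subset of S} (-1)^{|T|} R2((P \\ S) union T),
    the variance in the response attributable to S jointly and to no
    predictor outside S.
    """
    names = list(u.names)
    p = len(names)
    if p > 10:
        raise ValueError("commonality analysis limited to <= 10 predictors (2^p subsets)")
    cols = {name: k for k, name in enumerate(names)}
    r2_cache: dict[frozenset, float] = {frozenset(): 0.0}
    for size in range(1, p + 1):
        for sub in combinations(names, size):
            idx = [cols[s] for s in sub]
            r2_cache[frozenset(sub)] = _r_squared(u.response, u.predictors[:, idx])
    full = frozenset(names)
    coeffs: dict[tuple[str, ...], float] = {}
    for size in range(1, p + 1):
        for sub in combinations(names, size):
            rest = full - frozenset(sub)
            total = 0.0
            for tsize in range(0, size + 1):
                for t in combinations(sub, tsize):
                    total += (-1) ** tsize * r2_cache[rest | frozenset(t)]
            coeffs[tuple(sorted(sub))] = -total
    unique = {n: coeffs[(n,)] for n in names}
    common = {
        n: sum(v for s, v in coeffs.items() if n in s and len(s) >= 2) for n in names
    }
    return CommonalityPartition(coeffs, unique, common, r2_cache[full])


# --------------------------------------------------------------------------
# suppressor detection and the iterative MRDM-CA loop
# --------------------------------------------------------------------------

CLASSICAL = "classical"
CROSS_OVER = "cross-over"


def detect_suppressors(
    m: MRDMResult, c: CommonalityPartition, tol: float = 1e-9
) -> list[tuple[str, str]]:
    """Flag total suppressors from a fitted MRDM and its CA partition.

    Classical suppression: the unique contribution is counter-balanced by a
    negative common contribution (C_i < 0 and U_i + C_i <= tol).  Cross-over
    suppression: the regression weight and the simple correlation disagree
    in sign (both clearly non-zero).
    """
    flagged = []
    for name in m.beta:
        u_i, c_i = c.unique[name], c.common[name]
        if c_i < 0 and u_i + c_i <= tol:
            flagged.append((name, CLASSICAL))
        elif (
            abs(m.beta[name]) > tol
            and abs(m.r[name]) > tol
            and np.sign(m.beta[name]) != np.sign(m.r[name])
        ):
            flagged.append((name, CROSS_OVER))
    return flagged


@dataclass
class SuppressorRound:
    removed: list[tuple[str, str]]
    mrdm: MRDMResult
    commonality: CommonalityPartition
    predictors: list[str]


@dataclass
class SuppressorTrace:
    rounds: list[SuppressorRound] = field(default_factory=list)


@dataclass
class MrdmCaReport:
    mrdm: MRDMResult | None
    commonality: CommonalityPartition | None
    trace: SuppressorTrace
    significant: list[str]
    predictors: list[str]


def mrdm_ca_loop(
    kta: DistanceMatrix,
    proxies: dict[str, DistanceMatrix],
    n_perm: int = 1000,
    seed: int | None = None,
    u_threshold: float = 0.05,
    alpha: float = 0.05,
    tol: float = 1e-9,
) -> MrdmCaReport:
    """Iterate MRDM + CA, removing all flagged suppressors each round.

    Stops when a round flags nothing or a single predictor remains.  A proxy
    is reported significant when the final model's permutation p is below
    ``alpha`` (callers running several trait models should BH-adjust those
    p-values and re-apply the rule) and its unique contribution exceeds
    ``u_threshold``.
    """
    if not proxies:
        raise ValueError("need at least one proxy")
    remaining = list(proxies)
    trace = SuppressorTrace()
    m = c = None
    while remaining:
        u = unfold(kta, {k: proxies[k] for k in remaining})
        m = mrdm(u, n_perm=n_perm, seed=seed)
        c = commonality(u)
        flagged = detect_suppressors(m, c, tol=tol) if len(remaining) > 1 else []
        trace.rounds.append(SuppressorRound(flagged, m, c, list(remaining)))
        if not flagged:
            break
        for name, reason in flagged:
            logger.info("removing %s suppressor: %s", reason, name)
        remaining = [x for x in remaining if x not in {n for n, _ in flagged}]
    if not remaining:
        logger.warning("all predictors removed as suppressors; empty model")
        return MrdmCaReport(None, None, trace, [], [])
    significant = [
        name for name in remaining
        if m.p_r_squared is not None
        and m.p_r_squared < alpha
        and c.unique[name] > u_threshold
    ]
    return MrdmCaReport(m, c, trace, significant, remaining)


# --------------------------------------------------------------------------
# Mantel test
# --------------------------------------------------------------------------


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


def mantel(
    a: DistanceMatrix, b: DistanceMatrix, n_perm: int = 9999, seed: int | None = None
) -> MantelResult:
    """One-sided Mantel test between two distance matrices.

    Pearson r between the unfolded lower triangles; the null permutes the
    units (joint row/column relabelling) of the first matrix.
    """
    check_same_labels(a, b)
    va, vb = a.condensed(), b.condensed()
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("Mantel r undefined for a constant matrix")
    r = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    tri = np.tril_indices(a.n, k=-1)
    vbz = (vb - vb.mean()) / vb.std()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(a.n)
        vp = a.values[np.ix_(perm, perm)][tri]
        rp = float(np.mean((vp - vp.mean()) / vp.std() * vbz))
        if rp >= r - 1e-12:
            count += 1
    return MantelResult(r, (1 + count) / (1 + n_perm), n_perm)


# --------------------------------------------------------------------------
# multiple testing
# --------------------------------------------------------------------------


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out.tolist()
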