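"""Ordination and hypothesis-testing statistics.

Implemented from first principles:

- :func:`nmds` — non-metric multidimensional scaling by alternating
  isotonic regression of configuration distances on dissimilarity ranks
  (pool-adjacent-violators) with Guttman-transform updates, minimizing
  Kruskal stress-1 with step-halving so the per-iteration stress trace is
  monotone non-increasing; multiple seeded random restarts plus one
  classical-scaling start.
- :func:`permanova` — one-factor distance-based pseudo-F with whole-label
  permutations (vectorized), the (+1)/(+1) p-value convention, and an
  exhaustive-enumeration mode for small designs.
- :func:`fisher_exact_2x2` — two-sided Fisher's exact test by summation of
  hypergeometric point probabilities no larger than the observed table's.
- :func:`chi_square_rxc` — Pearson chi-square without continuity correction.
- :func:`mann_whitney_u` — rank-sum U with midranks; exact p by enumeration
  for small untied samples, otherwise normal approximation with tie and
  continuity corrections.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from scipy.stats import hypergeom, norm, rankdata


def _as_square(d) -> np.ndarray:
    """Accept an skbio DistanceMatrix or a square ndarray."""
    data = getattr(d, "data", d)
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] != data.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(np.abs(data - data.T) > 1e-12):
        raise ValueError("distance matrix must be symmetric")
    return data


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # (n_samples, k)
    stress: float  # Kruskal stress-1 of the best restart
    n_restarts: int
    converged: bool
    seed: Optional[int]
    stress_trace: list[float] = field(default_factory=list, repr=False)


def _classical_scaling(D: np.ndarray, k: int) -> np.ndarray:
    """Metric (Torgerson) scaling start: eigendecomposition of -J D^2 J / 2."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    coords = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))
    return coords


def _stress1(dist: np.ndarray, disp: np.ndarray) -> float:
    denom = np.sum(dist**2)
    if denom == 0:
        return np.inf
    return float(np.sqrt(np.sum((dist - disp) ** 2) / denom))


def _disparities(dist: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Isotonic (PAV) fit of configuration distances in dissimilarity-rank order."""
    disp = np.empty_like(dist)
    disp[order] = isotonic_regression(dist[order], increasing=True).x
    return disp


def _guttman(X: np.ndarray, dist: np.ndarray, disp: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dist > 0, disp / dist, 0.0)
    B = -squareform(ratio)
    np.fill_diagonal(B, -B.sum(axis=1))
    return B @ X / n


def _nmds_single(D: np.ndarray, X: np.ndarray, order: np.ndarray, tol: float, max_iter: int):
    trace = []
    dist = pdist(X)
    disp = _disparities(dist, order)
    stress = _stress1(dist, disp)
    trace.append(stress)
    converged = False
    for _ in range(max_iter):
        step = _guttman(X, dist, disp) - X
        alpha = 1.0
        improved = False
        # step-halving keeps the stress-1 trace monotone non-increasing
        for _ in range(12):
            Xc = X + alpha * step
            dist_c = pdist(Xc)
            disp_c = _disparities(dist_c, order)
            stress_c = _stress1(dist_c, disp_c)
            if stress_c <= stress + 1e-15:
                improved = True
                break
            alpha *= 0.5
        if not improved:
            converged = True
            break
        delta = stress - stress_c
        X, dist, disp, stress = Xc, dist_c, disp_c, stress_c
        trace.append(stress)
        if delta < tol:
            converged = True
            break
    return X, stress, trace, converged


def nmds(
    d,
    k: int = 2,
    n_restarts: int = 20,
    seed: Optional[int] = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> OrdinationResult:
    """Kruskal NMDS of a dissimilarity matrix into ``k`` dimensions.

    Runs one classical-scaling start plus ``n_restarts`` seeded random
    starts and returns the lowest-stress configuration (coordinates
    centered; stress is Kruskal stress-1).
    """
    D = _as_square(d)
    n = D.shape[0]
    if n < k + 1:
        raise ValueError("need at least k+1 samples")
    dvec = squareform(D, checks=False)
    if np.all(dvec == 0):
        raise ValueError("degenerate distance matrix: all zeros")
    order = np.argsort(dvec, kind="stable")
    rng = np.random.default_rng(seed)
    starts = [_classical_scaling(D, k)]
    scale = dvec.mean()
    starts += [rng.standard_normal((n, k)) * scale for _ in range(n_restarts)]
    best = None
    for X0 in starts:
        X, stress, trace, converged = _nmds_single(D, np.array(X0, dtype=float), order, tol, max_iter)
        if best is None or stress < best[1]:
            best = (X, stress, trace, converged)
    X, stress, trace, converged = best
    return OrdinationResult(
        coordinates=X - X.mean(axis=0),
        stress=stress,
        n_restarts=n_restarts,
        converged=converged,
        seed=seed,
        stress_trace=trace,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: Optional[int]

    def __post_init__(self):
        # semi-metric dissimilarities (e.g. Bray-Curtis) can push SS_between
        # marginally below zero; anything further negative signals a bug
        if not -0.05 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("R^2 outside [0, 1]")


def _ss_parts(D2: np.ndarray, codes: np.ndarray, n_groups: int):
    n = D2.shape[0]
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size:
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    return ss_total, ss_within


def _pseudo_f(ss_total, ss_within, n, a):
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore"):
        # ss_within = 0 (perfect separation) legitimately gives F = inf
        return (ss_between / (a - 1)) / (ss_within / (n - a)), ss_between / ss_total


def _batch_pseudo_f(D2: np.ndarray, perm_codes: np.ndarray, n_groups: int, group_sizes: np.ndarray):
    """Pseudo-F for many label permutations at once (P x n codes)."""
    n = D2.shape[0]
    a = n_groups
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = np.zeros(perm_codes.shape[0])
    for g in range(a):
        Z = (perm_codes == g).astype(float)
        quad = np.einsum("pi,ij,pj->p", Z, D2, Z) / 2.0
        ss_within += quad / group_sizes[g]
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore"):
        return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    d,
    grouping: Sequence,
    n_permutations: int = 9999,
    seed: Optional[int] = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    ``grouping`` is aligned with the distance matrix's row order. The
    p-value uses whole-label permutations and the (+1)/(+1) convention; with
    ``exhaustive=True`` every distinct labelling is enumerated instead (the
    identity is included, so p = #{F_perm >= F_obs} / #labellings).
    """
    D = _as_square(d)
    labels = np.asarray(list(grouping))
    n = D.shape[0]
    if labels.shape[0] != n:
        raise ValueError("grouping length does not match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = uniq.size
    if a < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(codes, minlength=a)
    if np.any(sizes == 0) or n <= a:
        raise ValueError("each group must be non-empty and N > number of groups")
    D2 = D**2
    ss_total, ss_within = _ss_parts(D2, codes, a)
    f_obs, r2 = _pseudo_f(ss_total, ss_within, n, a)

    if exhaustive:
        seen = sorted(set(itertools.permutations(codes.tolist())))
        perm_codes = np.array(seen)
        f_perm = _batch_pseudo_f(D2, perm_codes, a, sizes.astype(float))
        p = float(np.mean(f_perm >= f_obs - 1e-12))
        n_perm = len(seen)
    else:
        rng = np.random.default_rng(seed)
        perm_codes = rng.permuted(np.tile(codes, (n_permutations, 1)), axis=1)
        f_perm = _batch_pseudo_f(D2, perm_codes, a, sizes.astype(float))
        p = (1.0 + np.sum(f_perm >= f_obs - 1e-12)) / (n_permutations + 1.0)
        n_perm = n_permutations
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(r2),
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Contingency and rank tests
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table of counts.

    Sums hypergeometric point probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's (with a
    1 + 1e-7 relative slack against floating-point ties).
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(np.mod(t, 1) != 0):
        raise ValueError("need a 2x2 table of non-negative integers")
    t = t.astype(np.int64)
    n = int(t.sum())
    if n == 0:
        raise ValueError("all-zero table")
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    kmin = max(0, r1 - (n - c1))
    kmax = min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(ks, n, c1, r1)
    p_obs = pmf[int(t[0, 0]) - kmin]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def chi_square_rxc(table) -> tuple[float, int]:
    """Pearson chi-square statistic and df for an RxC count table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0):
        raise ValueError("need an RxC table of non-negative counts")
    n = t.sum()
    if n <= 0:
        raise ValueError("empty table")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero margin: expected count undefined")
    expected = np.outer(rows, cols) / n
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, df


def _mwu_exact_p(m: int, n: int, u_obs: float) -> float:
    """Exact two-sided p by enumerating rank assignments (no ties)."""
    total = m + n
    mu = m * n / 2.0
    dev = abs(u_obs - mu)
    hits = 0
    count = 0
    ranks = np.arange(1, total + 1)
    for combo in itertools.combinations(range(total), m):
        r1 = ranks[list(combo)].sum()
        u1 = r1 - m * (m + 1) / 2.0
        count += 1
        if abs(u1 - mu) >= dev - 1e-12:
            hits += 1
    return hits / count


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U (for the first sample) and a two-sided p-value.

    Midranks handle ties. The p-value is exact (full enumeration of rank
    assignments) when m + n <= 12 and there are no ties; otherwise a normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = x.size, y.size
    if m == 0 or n == 0:
        raise ValueError("empty sample")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    u1 = float(ranks[:m].sum() - m * (m + 1) / 2.0)
    has_ties = np.unique(combined).size < combined.size
    if m + n <= 12 and not has_ties:
        return u1, _mwu_exact_p(m, n, u1)
    mu = m * n / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    total = m + n
    var = m * n / 12.0 * ((total + 1) - tie_term / (total * (total - 1)))
    if var == 0:
        return u1, 1.0
    z = (abs(u1 - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return u1, float(min(1.0, 2.0 * norm.sf(z)))
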