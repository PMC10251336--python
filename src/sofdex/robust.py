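"""Minimum covariance determinant (MCD) by concentration steps.

FastMCD in the classic form: many elemental starts, each refined by C-steps
(take the h points with smallest Mahalanobis distance under the current
estimate, recompute location/scatter, repeat until the determinant stops
decreasing). The theorem behind the C-step guarantees the determinant is
non-increasing, so each start converges to a local minimum; many starts make
the global minimum overwhelmingly likely at the problem sizes used here.

The raw h-subset scatter is rescaled by the median-distance consistency
factor ``median(d^2) / chi2.ppf(0.5, d)`` so that squared robust Mahalanobis
distances are approximately chi2_d distributed for Gaussian data, which is
what the chi-square outlier cutoff assumes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

_DEGENERATE_REL = 1e-12


def _is_degenerate(det: float, cov: np.ndarray) -> bool:
    """Singular relative to the covariance scale (collinear/identical data)."""
    d = cov.shape[0]
    scale = np.trace(cov) / d
    return not np.isfinite(det) or det <= (scale ** d) * _DEGENERATE_REL


@dataclass
class MCDResult:
    """Robust location/scatter plus outlier calls.

    ``raw_covariance``/``raw_determinant`` are the uncorrected h-subset
    sample covariance (ddof=1) — the quantity the exhaustive-subset oracle
    minimizes. ``covariance`` and ``distances`` (squared robust Mahalanobis)
    include the consistency correction; ``outliers`` flags points with
    ``distances > chi2.ppf(cutoff, d)``.
    """

    location: np.ndarray
    covariance: np.ndarray
    raw_covariance: np.ndarray
    raw_determinant: float
    support: np.ndarray
    distances: np.ndarray
    outliers: np.ndarray
    h: int
    cutoff: float


def default_h(n: int, d: int) -> int:
    """Maximal-breakdown support size floor((n + d + 1) / 2)."""
    return (n + d + 1) // 2


def _subset_stats(X: np.ndarray, idx: np.ndarray):
    sub = X[idx]
    loc = sub.mean(axis=0)
    cov = np.cov(sub, rowvar=False, ddof=1)
    return loc, np.atleast_2d(cov)


def _mahalanobis_sq(X: np.ndarray, loc: np.ndarray, cov: np.ndarray) -> np.ndarray:
    diff = X - loc
    sol = np.linalg.solve(cov, diff.T)
    return np.einsum("ij,ji->i", diff, sol)


def _c_steps(X: np.ndarray, idx: np.ndarray, h: int, max_iter: int = 100):
    """Concentrate from a starting subset until the determinant stabilizes."""
    loc, cov = _subset_stats(X, idx)
    det = np.linalg.det(cov)
    if _is_degenerate(det, cov):
        return None
    for _ in range(max_iter):
        d2 = _mahalanobis_sq(X, loc, cov)
        new_idx = np.argpartition(d2, h - 1)[:h]
        new_loc, new_cov = _subset_stats(X, new_idx)
        new_det = np.linalg.det(new_cov)
        if _is_degenerate(new_det, new_cov):
            return None
        if new_det >= det * (1 - 1e-12):
            return new_det, new_loc, new_cov, new_idx
        det, loc, cov, idx = new_det, new_loc, new_cov, new_idx
    return det, loc, cov, idx


def fast_mcd(points, *, h: int | None = None, n_starts: int = 500,
             cutoff: float = 0.975, random_state: int = 0) -> MCDResult:
    """MCD location/scatter and chi-square outlier calls.

    Parameters
    ----------
    points
        (n, d) finite array; requires ``n >= 2 * (d + 1)``.
    h
        Support size; default ``floor((n + d + 1) / 2)``.
    n_starts
        Number of seeded elemental starts, each a random (d+1)-point subset
        refined by C-steps.
    cutoff
        Chi-square quantile for flagging outliers by squared robust distance.

    Raises
    ------
    ValueError
        For too-few points, non-finite input, or degenerate data where every
        candidate subset has (numerically) zero covariance determinant —
        e.g. all points identical or exactly collinear.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ValueError("points must be a 2-D array")
    n, d = X.shape
    if not np.isfinite(X).all():
        raise ValueError("points must be finite")
    if n < 2 * (d + 1):
        raise ValueError(f"need at least {2 * (d + 1)} points for d={d}")
    if h is None:
        h = default_h(n, d)
    if not d + 1 <= h <= n:
        raise ValueError(f"h={h} outside [{d + 1}, {n}]")

    rng = np.random.default_rng(random_state)
    from itertools import combinations
    from math import comb

    if comb(n, d + 1) <= n_starts:
        # small n: every elemental subset is a start (still concentration-based)
        starts = [np.array(c) for c in combinations(range(n), d + 1)]
    else:
        starts = [rng.choice(n, size=d + 1, replace=False)
                  for _ in range(n_starts)]

    best = None
    for idx in starts:
        size = d + 1
        # expand an exactly-singular elemental subset with random extra points
        while size < n:
            _, cov = _subset_stats(X, idx)
            if not _is_degenerate(np.linalg.det(cov), cov):
                break
            size += 1
            extra = rng.choice(np.setdiff1d(np.arange(n), idx), size=1)
            idx = np.concatenate([idx, extra])
        result = _c_steps(X, idx, h)
        if result is None:
            continue
        if best is None or result[0] < best[0]:
            best = result
    if best is None:
        raise ValueError(
            "degenerate data: every candidate h-subset has a singular "
            "covariance (identical or collinear points)")

    det, loc, cov_raw, idx = best
    d2_raw = _mahalanobis_sq(X, loc, cov_raw)
    correction = np.median(d2_raw) / stats.chi2.ppf(0.5, d)
    cov_corr = cov_raw * correction
    d2 = d2_raw / correction
    thresh = stats.chi2.ppf(cutoff, d)
    support = np.zeros(n, dtype=bool)
    support[idx] = True
    return MCDResult(location=loc, covariance=cov_corr, raw_covariance=cov_raw,
                     raw_determinant=float(det), support=support,
                     distances=d2, outliers=d2 > thresh, h=h, cutoff=cutoff)
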