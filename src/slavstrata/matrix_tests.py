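"""Mantel and partial Mantel permutation tests between distance matrices.

The Mantel statistic is the Pearson correlation over the n(n-1)/2 upper-
triangle entries of two labelled distance matrices (aligned by label).  The
null distribution is obtained by simultaneous row/column permutation of the
second matrix.  The first-order partial correlation controls a third matrix:

    r_AB.C = (r_AB - r_AC r_BC) / sqrt((1 - r_AC^2)(1 - r_BC^2))

and its null permutes the raw entries of B (the most common implementation
lineage), recomputing the partial statistic each time; a residual-
permutation variant is available behind a flag.  p-values are
(b + 1) / (m + 1); tests are one-sided for positive association by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from slavstrata.popdata_io import DistanceMatrix

__all__ = ["MantelResult", "mantel", "partial_mantel"]


@dataclass
class MantelResult:
    r: float
    p_value: float
    permutations: int
    alternative: str = "greater"
    partial_on: str | None = None


def _aligned(A: DistanceMatrix, *others: DistanceMatrix) -> list[np.ndarray]:
    labels = list(A.labels)
    mats = [A.d]
    for M in others:
        if set(M.labels) != set(labels):
            raise ValueError("matrices carry different label sets")
        mats.append(M.reorder(labels).d)
    return mats


def _upper(m: np.ndarray) -> np.ndarray:
    return m[np.triu_indices(m.shape[0], k=1)]


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    xs = x - x.mean()
    ys = y - y.mean()
    vx, vy = float(xs @ xs), float(ys @ ys)
    if vx == 0 or vy == 0:
        raise ValueError("constant matrix: zero variance in off-diagonal entries")
    return float(xs @ ys / np.sqrt(vx * vy))


def _pvalue(observed: float, perm_stats: np.ndarray, alternative: str) -> float:
    m = perm_stats.size
    if alternative == "greater":
        b = int(np.sum(perm_stats >= observed - 1e-12))
    elif alternative == "two-sided":
        b = int(np.sum(np.abs(perm_stats) >= abs(observed) - 1e-12))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (b + 1) / (m + 1)


def mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    permutations: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
    exact: bool = False,
) -> MantelResult:
    """Mantel test of matrix association; ``B`` is the permuted matrix.

    With ``exact=True`` all n! row/column permutations are enumerated (small
    n only) and the p-value is the exact fraction of permutations at least
    as extreme as the observed statistic (the identity included).
    """
    a, b = _aligned(A, B)
    n = a.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs n >= 4")
    x = _upper(a)
    r_obs = _corr(x, _upper(b))
    if exact:
        if n > 8:
            raise ValueError("exact enumeration is limited to n <= 8")
        from itertools import permutations as iterperm

        perm = np.array([
            _corr(x, _upper(b[np.ix_(p, p)])) for p in iterperm(range(n))
        ])
        m = perm.size
        if alternative == "greater":
            p_val = float(np.sum(perm >= r_obs - 1e-12)) / m
        elif alternative == "two-sided":
            p_val = float(np.sum(np.abs(perm) >= abs(r_obs) - 1e-12)) / m
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return MantelResult(r=r_obs, p_value=p_val, permutations=m, alternative=alternative)
    rng = np.random.default_rng(seed)
    perm = np.empty(permutations)
    for k in range(permutations):
        p = rng.permutation(n)
        perm[k] = _corr(x, _upper(b[np.ix_(p, p)]))
    return MantelResult(r=r_obs, p_value=_pvalue(r_obs, perm, alternative),
                        permutations=permutations, alternative=alternative)


def _partial_r(rab: float, rac: float, rbc: float) -> float:
    denom = (1.0 - rac**2) * (1.0 - rbc**2)
    if denom <= 0.0:
        raise ValueError("collinear control matrix: |r| = 1 with the controlled matrix")
    return (rab - rac * rbc) / np.sqrt(denom)


def partial_mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    C: DistanceMatrix,
    permutations: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
    method: str = "raw",
) -> MantelResult:
    """Partial Mantel test of A vs B controlling for C.

    ``method='raw'`` permutes B and recomputes the partial statistic;
    ``method='residual'`` permutes the residuals of A on C against the
    residuals of B on C.
    """
    a, b, c = _aligned(A, B, C)
    n = a.shape[0]
    if n < 4:
        raise ValueError("partial Mantel test needs n >= 4")
    x, y, z = _upper(a), _upper(b), _upper(c)
    rac = _corr(x, z)
    r_obs = _partial_r(_corr(x, y), rac, _corr(y, z))
    rng = np.random.default_rng(seed)
    perm = np.empty(permutations)
    if method == "raw":
        for k in range(permutations):
            p = rng.permutation(n)
            yp = _upper(b[np.ix_(p, p)])
            perm[k] = _partial_r(_corr(x, yp), rac, _corr(yp, z))
    elif method == "residual":
        def resid(v: np.ndarray) -> np.ndarray:
            zc = z - z.mean()
            return (v - v.mean()) - (v @ zc / (zc @ zc)) * zc

        rx = resid(x)
        for k in range(permutations):
            p = rng.permutation(n)
            perm[k] = _corr(rx, resid(_upper(b[np.ix_(p, p)])))
    else:
        raise ValueError(f"unknown method {method!r}")
    return MantelResult(r=float(r_obs), p_value=_pvalue(r_obs, perm, alternative),
                        permutations=permutations, alternative=alternative,
                        partial_on="C")
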