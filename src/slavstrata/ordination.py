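"""Non-metric multidimensional scaling with Kruskal stress-1.

The embedding minimises Kruskal's stress-1,

    stress1 = sqrt( sum_{i<j} (dhat_ij - delta_ij)^2 / sum_{i<j} delta_ij^2 )

where ``delta`` are configuration (Euclidean) distances and ``dhat`` the
monotone-regression disparities of ``delta`` against the input
dissimilarities.  Ties in the dissimilarities follow Kruskal's primary
approach: within a tied block the disparities are free to follow the
configuration order.

Optimisation is SMACOF with isotonic regression; the first restart starts
from classical (Torgerson) scaling, further restarts from random Gaussian
configurations, and the lowest-stress configuration wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from slavstrata.popdata_io import DistanceMatrix

__all__ = ["MdsResult", "mds_embed", "stress1"]


@dataclass
class MdsResult:
    coordinates: pd.DataFrame  # index: labels; columns: dim1..dimk; mean-centred
    stress: float
    n_restarts: int
    converged: bool


def _disparities(dissim: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Monotone (primary-ties) regression of configuration distances on dissimilarities."""
    order = np.lexsort((delta, dissim))
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(np.arange(order.size), delta[order])
    dhat = np.empty_like(delta)
    dhat[order] = fitted
    return dhat


def stress1(D: DistanceMatrix, coordinates: pd.DataFrame | np.ndarray) -> float:
    """Kruskal stress-1 of a configuration for the dissimilarities in ``D``.

    ``coordinates`` may be a labelled DataFrame (reordered to match ``D``) or
    a bare array already in the order of ``D.labels``.
    """
    if isinstance(coordinates, pd.DataFrame):
        missing = set(D.labels) - set(coordinates.index)
        if missing:
            raise ValueError(f"configuration lacks labels {sorted(missing)}")
        X = coordinates.loc[D.labels].to_numpy(dtype=float)
    else:
        X = np.asarray(coordinates, dtype=float)
        if X.shape[0] != len(D.labels):
            raise ValueError("configuration size does not match distance matrix")
    delta = pdist(X)
    dissim = D.condensed()
    denom = float(delta @ delta)
    if denom == 0.0:
        raise ValueError("degenerate configuration: all points coincide")
    dhat = _disparities(dissim, delta)
    return float(np.sqrt(np.sum((dhat - delta) ** 2) / denom))


def _torgerson(d: np.ndarray, k: int) -> np.ndarray:
    """Classical scaling: eigendecomposition of the double-centred squared distances."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:k]
    return v[:, idx] * np.sqrt(np.clip(w[idx], 0.0, None))


def mds_embed(
    D: DistanceMatrix,
    k: int = 2,
    restarts: int = 8,
    seed: int | None = None,
    max_iter: int = 300,
    eps: float = 1e-9,
) -> MdsResult:
    """Best-of-``restarts`` non-metric MDS embedding of ``D`` into ``k`` dimensions.

    Deterministic given ``seed``; the reported ``stress`` is ``stress1``
    evaluated on the returned coordinates.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    d = D.d
    if np.all(d == 0):
        raise ValueError("degenerate distances: all-zero matrix")
    rng = np.random.default_rng(seed)
    n = d.shape[0]
    best: tuple[float, np.ndarray, int] | None = None
    for r in range(restarts):
        init = _torgerson(d, k) if r == 0 else rng.normal(size=(n, k)) * d.mean()
        X, _, n_iter = smacof(
            d,
            metric=False,
            n_components=k,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=eps,
            normalized_stress=True,
            return_n_iter=True,
        )
        s = stress1(D, X)
        if best is None or s < best[0]:
            best = (s, X, n_iter)
    s, X, n_iter = best
    X = X - X.mean(axis=0)
    coords = pd.DataFrame(X, index=list(D.labels), columns=[f"dim{i + 1}" for i in range(k)])
    return MdsResult(coordinates=coords, stress=s, n_restarts=restarts, converged=n_iter < max_iter)
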