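"""Genetic distances from haplogroup frequencies and great-circle geography.

Nei's standard genetic distance between two haplogroup frequency vectors
``p`` and ``q``:

    Jxy = sum_i p_i q_i,  Jx = sum_i p_i^2,  Jy = sum_i q_i^2
    I   = Jxy / sqrt(Jx * Jy)
    D   = -ln I

The plain plug-in estimator is used by default; an optional small-sample
bias correction of Jx and Jy is available.  Populations with disjoint
haplogroup support (Jxy = 0) would give D = +inf; by default the distance is
capped at a finite value with a warning so that downstream ordination and
matrix tests stay finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np

from slavstrata.popdata_io import (
    DistanceMatrix,
    GroupDefinition,
    HaplogroupFrequencyTable,
    PopulationMeta,
)

__all__ = [
    "nei_distance",
    "nei_distance_matrix",
    "GroupMeanDistance",
    "mean_group_distance",
    "haversine_matrix",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0
DEFAULT_DISJOINT_CAP = 10.0


def nei_distance(
    p: np.ndarray,
    q: np.ndarray,
    cap: float = DEFAULT_DISJOINT_CAP,
    strict: bool = False,
    unbias_n: tuple[int, int] | None = None,
) -> float:
    """Nei's standard genetic distance D = -ln(Jxy / sqrt(Jx Jy)).

    Parameters
    ----------
    p, q:
        Frequency vectors of equal length, each summing to 1.
    cap:
        Finite value returned (with a warning) when the vectors share no
        haplogroups; ignored in strict mode.
    strict:
        Raise instead of capping on disjoint support.
    unbias_n:
        Optional ``(n_p, n_q)`` sample sizes; when given, Jx and Jy use the
        unbiased homozygosity estimator ``(n*J - 1)/(n - 1)``.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("frequency vectors differ in length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("negative frequencies")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} sums to {v.sum():.6g}, not 1")
    jxy = float(p @ q)
    jx = float(p @ p)
    jy = float(q @ q)
    if unbias_n is not None:
        n_p, n_q = unbias_n
        if n_p > 1:
            jx = (n_p * jx - 1.0) / (n_p - 1.0)
        if n_q > 1:
            jy = (n_q * jy - 1.0) / (n_q - 1.0)
        jx, jy = max(jx, 1e-12), max(jy, 1e-12)
    if jxy <= 0.0:
        if strict:
            raise ValueError("no shared haplogroups: Jxy = 0, D_Nei undefined")
        warnings.warn(
            f"no shared haplogroups (Jxy = 0); returning cap value {cap}", stacklevel=2
        )
        return cap
    d = -np.log(jxy / np.sqrt(jx * jy))
    # identical vectors can land at -0.0 through rounding
    return float(max(d, 0.0))


def nei_distance_matrix(
    table: HaplogroupFrequencyTable,
    cap: float = DEFAULT_DISJOINT_CAP,
    strict: bool = False,
    unbias: bool = False,
) -> DistanceMatrix:
    """Pairwise Nei distance matrix over all populations of a table."""
    n = len(table.populations)
    if n < 2:
        raise ValueError("need at least 2 populations")
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        kw = {}
        if unbias:
            kw["unbias_n"] = (table.populations[i].n_samples, table.populations[j].n_samples)
        try:
            d[i, j] = d[j, i] = nei_distance(table.freq[i], table.freq[j], cap=cap, strict=strict, **kw)
        except ValueError as e:
            raise ValueError(
                f"Nei distance failed for {table.population_ids[i]} vs {table.population_ids[j]}: {e}"
            ) from e
    return DistanceMatrix(list(table.population_ids), d)


@dataclass(frozen=True)
class GroupMeanDistance:
    """Mean pairwise distance within a group or between two groups."""

    group_a: GroupDefinition
    group_b: GroupDefinition | None
    mean_d: float
    n_pairs: int


def mean_group_distance(
    D: DistanceMatrix, a: GroupDefinition, b: GroupDefinition | None = None
) -> GroupMeanDistance:
    """Mean over unordered within-group pairs (``b`` absent) or all cross pairs."""
    for g in (a,) if b is None else (a, b):
        missing = g.members - set(D.labels)
        if missing:
            raise ValueError(f"group {g.group_name!r}: labels not in matrix: {sorted(missing)}")
    ia = [D.index(l) for l in sorted(a.members)]
    if b is None:
        if len(ia) < 2:
            raise ValueError(f"group {a.group_name!r}: no within-group pairs (singleton group)")
        pairs = list(combinations(ia, 2))
    else:
        ib = [D.index(l) for l in sorted(b.members)]
        pairs = [(i, j) for i, j in product(ia, ib) if i != j]
        if not pairs:
            raise ValueError("no cross-group pairs")
    vals = [D.d[i, j] for i, j in pairs]
    return GroupMeanDistance(a, b, float(np.mean(vals)), len(pairs))


def haversine_matrix(meta: list[PopulationMeta]) -> DistanceMatrix:
    """Great-circle distance matrix in km (haversine, Earth radius 6371 km)."""
    lat = np.radians([m.latitude for m in meta])
    lon = np.radians([m.longitude for m in meta])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return DistanceMatrix([m.population_id for m in meta], d)
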