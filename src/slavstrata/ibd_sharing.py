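"""Group-level IBD-segment sharing: the ibd-statistic and resampling comparisons.

The ibd-statistic between two groups of individuals is the average number of
IBD segments per cross-group pair of individuals, tabulated by segment-length
class in cM.  Every cross pair contributes to the denominator whether or not
it shares segments, so the per-class values sum to the binning-free average
segment count per pair.

Group comparisons ask whether a focal group shares more with comparator c1
than with comparator c2: Delta = ibd(focal, c1) - ibd(focal, c2) summed over
the selected length classes.  The null reassigns the individuals of c1 and c2
to two pseudo-groups of the original sizes (individuals, not populations, are
the exchangeable units) and the two-sided p-value is (b + 1) / (m + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from slavstrata.popdata_io import GroupDefinition, IBDSegmentSet

__all__ = [
    "LengthClassBins",
    "IbdStatProfile",
    "SharingComparison",
    "ibd_statistic",
    "compare_sharing",
    "sharing_profile_table",
]

#: Ten length classes: [1,1.5), [1.5,2), ..., [8,10), [10, inf) cM.
DEFAULT_EDGES = (1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0)


@dataclass(frozen=True)
class LengthClassBins:
    """Increasing cM breakpoints; the last class is open-ended."""

    edges: tuple[float, ...] = DEFAULT_EDGES

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.size < 1 or np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing and non-empty")

    @property
    def n_classes(self) -> int:
        return len(self.edges)

    @property
    def labels(self) -> list[str]:
        out = [f"[{a:g},{b:g})" for a, b in zip(self.edges[:-1], self.edges[1:])]
        out.append(f"[{self.edges[-1]:g},inf)")
        return out

    def classify(self, lengths: np.ndarray) -> np.ndarray:
        """Class index per length; -1 for lengths below the first edge."""
        return np.searchsorted(np.asarray(self.edges), lengths, side="right") - 1


@dataclass
class IbdStatProfile:
    group_a: GroupDefinition
    group_b: GroupDefinition
    per_class: np.ndarray
    n_pairs: int
    bins: LengthClassBins

    @property
    def total(self) -> float:
        return float(self.per_class.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.per_class, index=self.bins.labels, name=self.group_b.group_name)


@dataclass
class SharingComparison:
    focal: GroupDefinition
    comparator_1: GroupDefinition
    comparator_2: GroupDefinition
    delta_total: float
    delta_per_class: np.ndarray
    p_value: float | None
    permutations: int
    bins: LengthClassBins


def _group_individuals(segments: IBDSegmentSet, g: GroupDefinition) -> list[str]:
    inds = segments.individuals_of(g.members)
    if not inds:
        raise ValueError(f"group {g.group_name!r} has no individuals in the segment set")
    return inds


def _check_disjoint(segments: IBDSegmentSet, a: GroupDefinition, b: GroupDefinition) -> None:
    shared = set(_group_individuals(segments, a)) & set(_group_individuals(segments, b))
    if shared:
        raise ValueError(
            f"groups {a.group_name!r} and {b.group_name!r} overlap at the individual level: "
            f"{sorted(shared)[:5]}"
        )


def _class_counts(
    segments: IBDSegmentSet, set_a: set[str], set_b: set[str], bins: LengthClassBins
) -> np.ndarray:
    counts = np.zeros(bins.n_classes)
    for s in segments.segments:
        cross = (s.id1 in set_a and s.id2 in set_b) or (s.id1 in set_b and s.id2 in set_a)
        if not cross:
            continue
        k = bins.classify(np.array([s.length_cM]))[0]
        if k >= 0:
            counts[k] += 1
    return counts


def ibd_statistic(
    segments: IBDSegmentSet,
    a: GroupDefinition,
    b: GroupDefinition,
    bins: LengthClassBins | None = None,
) -> IbdStatProfile:
    """Average number of shared IBD segments per cross-group pair, per length class."""
    bins = bins or LengthClassBins()
    _check_disjoint(segments, a, b)
    ia, ib = _group_individuals(segments, a), _group_individuals(segments, b)
    n_pairs = len(ia) * len(ib)
    counts = _class_counts(segments, set(ia), set(ib), bins)
    return IbdStatProfile(a, b, counts / n_pairs, n_pairs, bins)


def compare_sharing(
    segments: IBDSegmentSet,
    focal: GroupDefinition,
    c1: GroupDefinition,
    c2: GroupDefinition,
    bins: LengthClassBins | None = None,
    permutations: int = 999,
    seed: int | None = None,
    classes: Sequence[int] | None = None,
) -> SharingComparison:
    """Permutation comparison of ibd(focal, c1) against ibd(focal, c2).

    ``classes`` optionally restricts the totalled Delta to a subset of length
    classes (indices into the bin classes); the per-class Delta is always
    reported in full.  ``permutations = 0`` reports Delta without a p-value.
    """
    bins = bins or LengthClassBins()
    _check_disjoint(segments, focal, c1)
    _check_disjoint(segments, focal, c2)
    i_f = _group_individuals(segments, focal)
    i1 = _group_individuals(segments, c1)
    i2 = _group_individuals(segments, c2)
    if set(i1) & set(i2):
        raise ValueError("comparator groups overlap at the individual level")

    # per-individual-by-class counts of segments shared with the focal group
    pool = i1 + i2
    pos = {ind: k for k, ind in enumerate(pool)}
    fset = set(i_f)
    M = np.zeros((len(pool), bins.n_classes))
    for s in segments.segments:
        if s.id1 in fset and s.id2 in pos:
            other = s.id2
        elif s.id2 in fset and s.id1 in pos:
            other = s.id1
        else:
            continue
        k = bins.classify(np.array([s.length_cM]))[0]
        if k >= 0:
            M[pos[other], k] += 1

    n_f, n1, n2 = len(i_f), len(i1), len(i2)
    sel = np.arange(bins.n_classes) if classes is None else np.asarray(classes, dtype=int)

    def delta_from_assignment(in_c1: np.ndarray) -> tuple[float, np.ndarray]:
        prof1 = M[in_c1].sum(axis=0) / (n_f * n1)
        prof2 = M[~in_c1].sum(axis=0) / (n_f * n2)
        d = prof1 - prof2
        return float(d[sel].sum()), d

    obs_mask = np.zeros(len(pool), dtype=bool)
    obs_mask[:n1] = True
    d_obs, d_per_class = delta_from_assignment(obs_mask)

    p_value = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        b = 0
        for _ in range(permutations):
            mask = np.zeros(len(pool), dtype=bool)
            mask[rng.choice(len(pool), size=n1, replace=False)] = True
            d_perm, _ = delta_from_assignment(mask)
            if abs(d_perm) >= abs(d_obs) - 1e-12:
                b += 1
        p_value = (b + 1) / (permutations + 1)
    return SharingComparison(focal, c1, c2, d_obs, d_per_class, p_value, permutations, bins)


def sharing_profile_table(
    segments: IBDSegmentSet,
    groups: Sequence[GroupDefinition],
    focal: GroupDefinition,
    bins: LengthClassBins | None = None,
) -> pd.DataFrame:
    """Profiles of a focal group against each comparator: rows = groups, cols = classes."""
    bins = bins or LengthClassBins()
    rows = []
    for g in groups:
        prof = ibd_statistic(segments, focal, g, bins)
        s = prof.to_series()
        s["total"] = prof.total
        s["n_pairs"] = prof.n_pairs
        rows.append(s)
    return pd.DataFrame(rows)
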