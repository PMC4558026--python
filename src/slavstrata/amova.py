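"""Hierarchical analysis of molecular variance (AMOVA) on haplogroup counts.

Individuals are treated as haplogroup-labelled units with the molecular
distance delta_ij = 0 if two individuals carry the same haplogroup and 1
otherwise, which makes Phi_ST the haplogroup-frequency analogue of F_ST.
Sums of squared differences are partitioned over a two- or three-level
hierarchy (among groups / among populations within groups / within
populations) and converted to variance components with the standard
expected-mean-square coefficients for unequal sample sizes:

    sigma_c = MS_WP
    sigma_b = (MS_AP - sigma_c) / n'
    sigma_a = (MS_AG - sigma_c - n'' sigma_b) / n'''

    Phi_ST = (sigma_a + sigma_b) / sigma_T
    Phi_SC = sigma_b / (sigma_b + sigma_c)
    Phi_CT = sigma_a / sigma_T

With 0/1 distances every sum of squares reduces to counts:
sum_{i,j in S} delta^2_ij = n_S^2 - sum_h c_{S,h}^2 over ordered pairs.

Permutation p-values use (b + 1) / (m + 1).  Phi_ST permutes individuals
among all populations, Phi_SC permutes individuals among populations within
their group, and Phi_CT permutes whole populations among groups.  Negative
variance components are reported as estimated and also clamped to zero in a
secondary field.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from slavstrata.popdata_io import HaplogroupFrequencyTable, PopulationMeta

logger = logging.getLogger(__name__)

__all__ = ["AmovaHierarchy", "AmovaResult", "amova", "amova_per_group"]


@dataclass(frozen=True)
class AmovaHierarchy:
    """Ordered grouping maps (outermost stratum first) over population ids."""

    levels: tuple[str, ...]
    assignment: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for pid, labels in self.assignment.items():
            if len(labels) != len(self.levels):
                raise ValueError(f"population {pid!r}: expected {len(self.levels)} level labels")

    @classmethod
    def from_meta(
        cls,
        meta: Sequence[PopulationMeta],
        levels: tuple[str, ...] = ("linguistic_branch", "ethnic_group"),
    ) -> "AmovaHierarchy":
        return cls(
            levels=tuple(levels),
            assignment={m.population_id: tuple(getattr(m, lv) for lv in levels) for m in meta},
        )

    def level_map(self, level: str) -> dict[str, str]:
        i = self.levels.index(level)
        return {pid: labels[i] for pid, labels in self.assignment.items()}


@dataclass
class AmovaResult:
    """Variance components, Phi-statistics and permutation p-values.

    Component keys: ``among_groups`` (sigma_a, three-level only),
    ``among_pops`` (sigma_b), ``within_pops`` (sigma_c).  A stratum with a
    single unit is reported as not testable (NaN) rather than zero.
    """

    sigma: dict[str, float]
    sigma_clamped: dict[str, float]
    phi: dict[str, float]
    ss: dict[str, float]
    df: dict[str, int]
    testable: dict[str, bool]
    p_values: dict[str, float] = field(default_factory=dict)
    permutations: int = 0
    n_individuals: int = 0

    @property
    def sigma_total(self) -> float:
        return float(sum(v for v in self.sigma.values() if not math.isnan(v)))

    @property
    def phi_clamped(self) -> dict[str, float]:
        """Phi-statistics recomputed from the zero-clamped variance components.

        The raw ``phi`` follows the signed-estimate convention and can be
        slightly negative when units are more similar than random sampling
        predicts; this view maps such cases to 0.
        """
        sa = self.sigma_clamped.get("among_groups", float("nan"))
        sb = self.sigma_clamped.get("among_pops", float("nan"))
        sc = self.sigma_clamped.get("within_pops", float("nan"))
        out: dict[str, float] = {}
        if "among_groups" in self.sigma_clamped:
            tot = (0.0 if math.isnan(sa) else sa) + (0.0 if math.isnan(sb) else sb) + sc
            out["phi_ct"] = sa / tot if tot > 0 else 0.0
            out["phi_sc"] = sb / (sb + sc) if (sb + sc) > 0 else 0.0
            out["phi_st"] = (sa + sb) / tot if tot > 0 else 0.0
        else:
            tot = sb + sc
            out["phi_st"] = sb / tot if tot > 0 else 0.0
        return out

    @property
    def variance_fraction(self) -> dict[str, float]:
        t = self.sigma_total
        return {k: (v / t if t > 0 else float("nan")) for k, v in self.sigma.items()}


def _pairsum(counts: np.ndarray) -> float:
    """sum over ordered pairs within the pooled set of 0/1 mismatch distances."""
    n = counts.sum()
    return float(n * n - (counts.astype(float) ** 2).sum())


def _decompose(counts: np.ndarray, group_idx: np.ndarray | None) -> dict:
    """Raw AMOVA decomposition from a P x H count matrix.

    ``group_idx`` assigns each population row to a top-level group
    (``None`` -> two-level design).  Returns sums of squares, df, variance
    components and Phi-statistics; non-testable entries are NaN.
    """
    counts = np.asarray(counts, dtype=float)
    n_p = counts.sum(axis=1)
    if np.any(n_p == 0):
        raise ValueError("population with zero individuals")
    N = float(n_p.sum())
    P = counts.shape[0]

    ssd_total = _pairsum(counts.sum(axis=0)) / (2.0 * N)
    ssd_wp = float(sum(_pairsum(counts[p]) / (2.0 * n_p[p]) for p in range(P)))

    nan = float("nan")
    if group_idx is None:
        # two-level: among populations / within populations
        if P < 2:
            raise ValueError("two-level AMOVA needs >= 2 populations")
        ssd_ap = ssd_total - ssd_wp
        df_ap, df_wp = P - 1, int(N) - P
        ms_ap = ssd_ap / df_ap
        sigma_c = ssd_wp / df_wp if df_wp > 0 else nan
        ncoef = (N - float(n_p @ n_p) / N) / df_ap
        sigma_b = (ms_ap - sigma_c) / ncoef
        tot = sigma_b + sigma_c
        return {
            "ss": {"among_pops": ssd_ap, "within_pops": ssd_wp},
            "df": {"among_pops": df_ap, "within_pops": df_wp},
            "sigma": {"among_pops": sigma_b, "within_pops": sigma_c},
            "phi": {"phi_st": sigma_b / tot if tot != 0 else 0.0},
            "testable": {"among_pops": True, "within_pops": df_wp > 0},
        }

    group_idx = np.asarray(group_idx)
    G = int(group_idx.max()) + 1
    group_counts = np.zeros((G, counts.shape[1]))
    np.add.at(group_counts, group_idx, counts)
    n_g = group_counts.sum(axis=1)
    ssd_groups_within = float(sum(_pairsum(group_counts[g]) / (2.0 * n_g[g]) for g in range(G)))
    ssd_ag = ssd_total - ssd_groups_within
    ssd_ap = ssd_groups_within - ssd_wp

    df_ag, df_ap, df_wp = G - 1, P - G, int(N) - P
    sigma_c = ssd_wp / df_wp if df_wp > 0 else nan

    sum_np2_over_ng = float(sum((n_p[group_idx == g] ** 2).sum() / n_g[g] for g in range(G)))
    testable_b = df_ap > 0
    if testable_b and not math.isnan(sigma_c):
        n1 = (N - sum_np2_over_ng) / df_ap
        sigma_b = (ssd_ap / df_ap - sigma_c) / n1
    else:
        sigma_b = nan
    testable_a = df_ag > 0
    if testable_a and not (math.isnan(sigma_c) or math.isnan(sigma_b)):
        n2 = (sum_np2_over_ng - float(n_p @ n_p) / N) / df_ag
        n3 = (N - float(n_g @ n_g) / N) / df_ag
        sigma_a = (ssd_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    else:
        sigma_a = nan

    tot = (0.0 if math.isnan(sigma_a) else sigma_a) + (0.0 if math.isnan(sigma_b) else sigma_b) + sigma_c
    phi = {
        "phi_ct": sigma_a / tot if testable_a and tot != 0 else (nan if not testable_a else 0.0),
        "phi_sc": (
            sigma_b / (sigma_b + sigma_c)
            if testable_b and (sigma_b + sigma_c) != 0
            else (nan if not testable_b else 0.0)
        ),
        "phi_st": (
            ((0.0 if math.isnan(sigma_a) else sigma_a) + (0.0 if math.isnan(sigma_b) else sigma_b)) / tot
            if tot != 0
            else 0.0
        ),
    }
    return {
        "ss": {"among_groups": ssd_ag, "among_pops": ssd_ap, "within_pops": ssd_wp},
        "df": {"among_groups": df_ag, "among_pops": df_ap, "within_pops": df_wp},
        "sigma": {"among_groups": sigma_a, "among_pops": sigma_b, "within_pops": sigma_c},
        "phi": phi,
        "testable": {"among_groups": testable_a, "among_pops": testable_b, "within_pops": df_wp > 0},
    }


def _counts_from_individuals(hap: np.ndarray, pop: np.ndarray, n_pops: int, n_h: int) -> np.ndarray:
    counts = np.zeros((n_pops, n_h))
    np.add.at(counts, (pop, hap), 1.0)
    return counts


def _require_counts(table: HaplogroupFrequencyTable) -> np.ndarray:
    if table.counts is None:
        raise ValueError("AMOVA requires integer haplogroup counts, not frequencies alone")
    return np.asarray(table.counts, dtype=int)


def amova(
    table: HaplogroupFrequencyTable,
    groups: Mapping[str, str] | AmovaHierarchy | None = None,
    group_level: str | None = None,
    permutations: int = 0,
    seed: int | None = None,
) -> AmovaResult:
    """AMOVA over the populations of ``table``.

    ``groups`` maps each population id to a top-level group label (or is an
    :class:`AmovaHierarchy`, whose ``group_level`` — outermost by default —
    is used); ``None`` runs the two-level design (among / within
    populations).
    """
    counts = _require_counts(table)
    pids = table.population_ids
    if isinstance(groups, AmovaHierarchy):
        groups = groups.level_map(group_level or groups.levels[0])
    if groups is not None:
        missing = [p for p in pids if p not in groups]
        if missing:
            raise ValueError(f"populations without a group label: {missing}")
        labels = sorted({groups[p] for p in pids})
        gidx = np.array([labels.index(groups[p]) for p in pids])
        if len(labels) < 2:
            logger.warning("single group at the top level: among-group component not testable")
    else:
        gidx = None

    res = _decompose(counts, gidx)
    out = AmovaResult(
        sigma=res["sigma"],
        sigma_clamped={k: (max(v, 0.0) if not math.isnan(v) else v) for k, v in res["sigma"].items()},
        phi=res["phi"],
        ss=res["ss"],
        df=res["df"],
        testable=res["testable"],
        permutations=permutations,
        n_individuals=int(counts.sum()),
    )
    if permutations > 0:
        out.p_values = _permutation_pvalues(counts, gidx, res["phi"], permutations, seed)
    return out


def _phi_or_nan(counts: np.ndarray, gidx: np.ndarray | None, key: str) -> float:
    try:
        return _decompose(counts, gidx)["phi"][key]
    except (ValueError, ZeroDivisionError):
        return float("nan")


def _permutation_pvalues(
    counts: np.ndarray,
    gidx: np.ndarray | None,
    observed: dict[str, float],
    permutations: int,
    seed: int | None,
) -> dict[str, float]:
    rng = np.random.default_rng(seed)
    n_pops, n_h = counts.shape
    hap = np.repeat(
        np.tile(np.arange(n_h), n_pops), counts.astype(int).ravel()
    )
    pop = np.repeat(np.arange(n_pops), counts.astype(int).sum(axis=1))

    exceed = {k: 0 for k, v in observed.items() if not math.isnan(v)}
    for _ in range(permutations):
        if "phi_st" in exceed:
            perm_pop = rng.permutation(pop)
            c = _counts_from_individuals(hap, perm_pop, n_pops, n_h)
            key = "phi_st"
            if _phi_or_nan(c, gidx, key) >= observed[key] - 1e-12:
                exceed[key] += 1
        if gidx is not None and "phi_sc" in exceed:
            perm_pop = pop.copy()
            for g in np.unique(gidx):
                sel = np.isin(pop, np.where(gidx == g)[0])
                perm_pop[sel] = rng.permutation(pop[sel])
            c = _counts_from_individuals(hap, perm_pop, n_pops, n_h)
            if _phi_or_nan(c, gidx, "phi_sc") >= observed["phi_sc"] - 1e-12:
                exceed["phi_sc"] += 1
        if gidx is not None and "phi_ct" in exceed:
            perm_g = rng.permutation(gidx)
            if _phi_or_nan(counts, perm_g, "phi_ct") >= observed["phi_ct"] - 1e-12:
                exceed["phi_ct"] += 1
    return {k: (b + 1) / (permutations + 1) for k, b in exceed.items()}


def amova_per_group(
    table: HaplogroupFrequencyTable,
    hierarchy: AmovaHierarchy,
    level: str,
    permutations: int = 0,
    seed: int | None = None,
) -> tuple[list[tuple[str, AmovaResult]], float]:
    """One two-level AMOVA per unit of ``level`` plus the across-unit mean Phi_ST.

    Units with fewer than two populations are skipped (logged).
    """
    lmap = hierarchy.level_map(level)
    counts = _require_counts(table)
    pids = table.population_ids
    results: list[tuple[str, AmovaResult]] = []
    seen: list[str] = []
    for p in pids:
        if lmap[p] not in seen:
            seen.append(lmap[p])
    rng = np.random.default_rng(seed)
    for unit in seen:
        idx = [i for i, p in enumerate(pids) if lmap[p] == unit]
        if len(idx) < 2:
            logger.info("amova_per_group: unit %r has < 2 populations, skipped", unit)
            continue
        sub = HaplogroupFrequencyTable.from_counts(
            [table.populations[i] for i in idx], list(table.haplogroups), counts[idx]
        )
        results.append(
            (unit, amova(sub, permutations=permutations, seed=int(rng.integers(2**31 - 1))))
        )
    if not results:
        raise ValueError(f"no unit of level {level!r} has >= 2 populations")
    avg = float(np.mean([r.phi["phi_st"] for _, r in results]))
    return results, avg
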