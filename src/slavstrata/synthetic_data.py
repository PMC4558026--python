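"""Synthetic-data generators with known ground truth for every pipeline input.

Three generators emulate the study's input classes:

* **Haplogroup tables** — a hierarchical Dirichlet-multinomial model.  A
  global frequency vector is drawn once; branch, group and population
  frequencies are successive Dirichlet draws centred on their parent with
  concentrations ``tau_branch``, ``tau_group``, ``tau_pop`` (higher = closer
  to the parent, hence less differentiation at that level), and counts are
  multinomial per population.  Populations of a branch are placed in
  geographically contiguous blocks; an optional Gaussian-kernel-correlated
  logit perturbation of the frequencies (``spatial_rho`` in km) adds a
  tunable geography-genetics signal.
* **IBD segments** — a recombination-clock model.  For a pair of individuals
  whose groups share ancestry ``g`` generations back, the raw segment count
  is Poisson(``mu``) and lengths are Exponential(mean 100/(2g) cM); segments
  below the detection threshold ``min_cM`` are discarded (rejection), so the
  observed count is Poisson(mu * exp(-2 g min_cM / 100)) and the expected
  count in a length class [a, b) is ``mu (e^{-2ga/100} - e^{-2gb/100})``,
  exposed as :func:`expected_ibd_profile`.
* **Wordlists** — Poisson replacement of cognate classes along a known dated
  tree; every replacement draws a globally novel class, and with probability
  ``synonym_prob`` it is added as a synonym rather than replacing the cell.
  Under the constant clock the expected share of two lects separated by
  total time T is exp(-rate * T) per item; an ``accelerated`` clock with
  hazard growing linearly in absolute age (Starostin-style, survival
  exp(-lambda t^2) per lineage from depth t) is also available.

Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from slavstrata.amova import AmovaHierarchy
from slavstrata.ibd_sharing import LengthClassBins
from slavstrata.lexstat import DatedTree, TreeNode, WordlistMatrix
from slavstrata.popdata_io import (
    GroupDefinition,
    HaplogroupFrequencyTable,
    IbdSegment,
    IBDSegmentSet,
    PopulationMeta,
)

__all__ = [
    "HaploSimConfig",
    "IbdSimConfig",
    "WordlistSimConfig",
    "simulate_haplogroups",
    "simulate_ibd",
    "expected_ibd_profile",
    "simulate_wordlists",
    "balto_slavic_like_tree",
    "ibd_groups",
    "default_ibd_study_config",
    "write_study_inputs",
]


# ---------------------------------------------------------------------------
# haplogroup frequencies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HaploSimConfig:
    """Hierarchical Dirichlet-multinomial study design.

    Defaults emulate the study conditions: four linguistic branches (think
    East/West/South Slavic and East Baltic), three ethnic groups per branch,
    two local populations per group, ~15 haplogroups at appreciable
    frequency, and around a hundred sampled men per local population.  The
    concentrations are ordered ``tau_branch < tau_group < tau_pop`` so that
    differentiation decreases down the hierarchy, as observed for these
    populations: the defaults place the among-branch differentiation near
    Phi_CT ~ 0.06, among-ethnic-group near Phi_SC ~ 0.03 and among-local-
    population (within a language) near Phi_ST ~ 0.01.
    """

    n_branches: int = 4
    n_groups_per_branch: int = 3
    n_pops_per_group: int = 2
    n_haplogroups: int = 15
    tau_branch: float = 20.0
    tau_group: float = 30.0
    tau_pop: float = 150.0
    n_per_pop: int = 100
    spatial_rho: float = 0.0  # km; 0 disables the spatially correlated perturbation
    spatial_sd: float = 1.0  # logit-scale s.d. of the spatial field
    origin: tuple[float, float] = (50.0, 20.0)  # lat, lon of the study area
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_branches, self.n_groups_per_branch, self.n_pops_per_group,
               self.n_haplogroups, self.n_per_pop) < 1:
            raise ValueError("all counts must be >= 1")
        if min(self.tau_branch, self.tau_group, self.tau_pop) <= 0:
            raise ValueError("Dirichlet concentrations must be > 0")


def simulate_haplogroups(
    cfg: HaploSimConfig,
) -> tuple[HaplogroupFrequencyTable, AmovaHierarchy]:
    """Simulate a haplogroup count table with a known linguistic hierarchy."""
    rng = np.random.default_rng(cfg.seed)
    eps = 1e-6
    global_freq = rng.dirichlet(np.ones(cfg.n_haplogroups))
    haplogroups = [f"hg{h:02d}" for h in range(cfg.n_haplogroups)]

    metas: list[PopulationMeta] = []
    counts = []
    assignment: dict[str, tuple[str, str]] = {}
    lat0, lon0 = cfg.origin
    branch_freq = None
    for b in range(cfg.n_branches):
        # isolation by distance at the branch level: each branch drifts from
        # its geographic neighbour, not independently from the global pool
        parent = global_freq if branch_freq is None else branch_freq
        branch_freq = rng.dirichlet(cfg.tau_branch * parent + eps)
        branch_name = f"branch{b}"
        # contiguous geography: one latitude band per branch
        blat = lat0 + 6.0 * b
        for g in range(cfg.n_groups_per_branch):
            group_freq = rng.dirichlet(cfg.tau_group * branch_freq + eps)
            group_name = f"{branch_name}_grp{g}"
            glon = lon0 + 5.0 * g
            for p in range(cfg.n_pops_per_group):
                pop_freq = rng.dirichlet(cfg.tau_pop * group_freq + eps)
                pid = f"{group_name}_pop{p}"
                lat = blat + 1.2 * p + rng.normal(0, 0.2)
                lon = glon + rng.normal(0, 0.4)
                metas.append(
                    PopulationMeta(
                        population_id=pid,
                        ethnic_group=group_name,
                        linguistic_branch=branch_name,
                        language=group_name,
                        latitude=float(np.clip(lat, -89, 89)),
                        longitude=float(np.clip(lon, -179, 179)),
                        n_samples=cfg.n_per_pop,
                    )
                )
                counts.append(pop_freq)
                assignment[pid] = (branch_name, group_name)

    freqs = np.array(counts)
    if cfg.spatial_rho > 0:
        freqs = _spatial_perturb(freqs, metas, cfg.spatial_rho, cfg.spatial_sd, rng)
    count_mat = np.array([rng.multinomial(cfg.n_per_pop, f) for f in freqs])
    # a multinomial draw can zero out a population only if n_per_pop = 0, guarded above
    table = HaplogroupFrequencyTable.from_counts(metas, haplogroups, count_mat)
    hierarchy = AmovaHierarchy(levels=("linguistic_branch", "ethnic_group"), assignment=assignment)
    return table, hierarchy


def _spatial_perturb(
    freqs: np.ndarray,
    metas: list[PopulationMeta],
    rho_km: float,
    sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian-kernel-correlated logit perturbation of population frequencies."""
    from slavstrata.gendist import haversine_matrix

    geo = haversine_matrix(metas).d
    cov = sd**2 * np.exp(-((geo / rho_km) ** 2))
    cov += 1e-8 * np.eye(len(metas))
    chol = np.linalg.cholesky(cov)
    logit = np.log(np.clip(freqs, 1e-9, None))
    for h in range(freqs.shape[1]):
        logit[:, h] += chol @ rng.standard_normal(len(metas))
    out = np.exp(logit)
    return out / out.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# IBD segments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IbdSimConfig:
    """Recombination-clock IBD sharing design.

    ``depth`` gives generations to common ancestry per unordered group pair;
    pairs absent from it share nothing.  ``mu`` is the Poisson mean of raw
    (pre-threshold) segments per pair of individuals; ``min_cM`` emulates the
    detection threshold of segment callers.  Defaults mirror the study's
    scale: 25 individuals per group and a 1 cM threshold.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: {"A": 25, "B": 25})
    depth: dict[tuple[str, str], float] = field(default_factory=lambda: {("A", "B"): 30.0})
    mu: float = 2.0
    min_cM: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        if any(g <= 0 for g in self.depth.values()):
            raise ValueError("depths must be positive generations")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")


def expected_ibd_profile(
    g: float, mu: float, bins: LengthClassBins, min_cM: float = 1.0
) -> np.ndarray:
    """Closed-form expected segment count per pair in each length class.

    E[count in [a, b)] = mu * (e^{-2ga/100} - e^{-2gb/100}) for a >= min_cM;
    classes entirely below the detection threshold expect zero.
    """
    rate = 2.0 * g / 100.0
    edges = np.array(list(bins.edges) + [np.inf])
    lo = np.maximum(edges[:-1], min_cM)
    hi = edges[1:]
    out = mu * (np.exp(-rate * lo) - np.where(np.isinf(hi), 0.0, np.exp(-rate * hi)))
    return np.where(hi <= min_cM, 0.0, out)


def simulate_ibd(cfg: IbdSimConfig) -> IBDSegmentSet:
    """Simulate fastIBD-style pairwise segments between groups."""
    rng = np.random.default_rng(cfg.seed)
    individuals: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for gname, n in cfg.group_sizes.items():
        members[gname] = [f"{gname}_{k:03d}" for k in range(n)]
        for ind in members[gname]:
            individuals[ind] = gname

    segments: list[IbdSegment] = []
    for (ga, gb), depth in sorted(cfg.depth.items()):
        if ga not in members or gb not in members:
            raise ValueError(f"depth entry references unknown group: {(ga, gb)}")
        mean_len = 100.0 / (2.0 * depth)
        p_detect = np.exp(-cfg.min_cM / mean_len)
        if ga == gb:
            pairs = combinations(members[ga], 2)
        else:
            pairs = ((ia, ib) for ia in members[ga] for ib in members[gb])
        for ia, ib in pairs:
            k = rng.poisson(cfg.mu * p_detect)
            for _ in range(k):
                # rejection sampling above the threshold == shifted exponential
                length = cfg.min_cM + rng.exponential(mean_len)
                chrom = str(rng.integers(1, 23))
                start = float(rng.uniform(0.0, 150.0))
                segments.append(IbdSegment(ia, ib, chrom, start, start + length))
    return IBDSegmentSet(individuals=individuals, segments=segments)


def ibd_groups(cfg: IbdSimConfig) -> dict[str, GroupDefinition]:
    """Group definitions matching a simulated segment set (one population per group)."""
    return {g: GroupDefinition.of(g, [g]) for g in cfg.group_sizes}


# ---------------------------------------------------------------------------
# wordlists
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WordlistSimConfig:
    """Poisson cognate-replacement simulation on a known dated tree.

    ``rates`` is the per-item replacement rate per millennium (scalar or one
    per item); the Swadesh-list default is 110 items at rate 0.05, the
    canonical basic-vocabulary scale.  ``clock='constant'`` uses a
    homogeneous Poisson clock (expected share e^{-rate*T} over separation
    T); ``clock='accelerated'`` uses the Starostin-style hazard 2*lambda*t
    in absolute millennia before present (survival e^{-lambda t^2} per
    lineage from depth t).
    """

    true_tree: DatedTree = None  # type: ignore[assignment]
    n_items: int = 110
    rates: float | tuple[float, ...] = 0.05
    synonym_prob: float = 0.05
    clock: str = "constant"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_tree is None:
            object.__setattr__(self, "true_tree", balto_slavic_like_tree())
        r = np.atleast_1d(np.asarray(self.rates, dtype=float))
        if np.any(r <= 0):
            raise ValueError("rates must be > 0")
        if not 0.0 <= self.synonym_prob < 1.0:
            raise ValueError("synonym_prob must lie in [0, 1)")
        if self.clock not in ("constant", "accelerated"):
            raise ValueError(f"unknown clock {self.clock!r}")


def balto_slavic_like_tree() -> DatedTree:
    """A study-shaped true tree: a deep two-branch split at 3400 YBP, one
    branch splitting ternary-fashion near 1900 YBP into three sub-clades that
    diversify 1400-600 YBP (the shape of the Balto-Slavic consensus tree)."""
    def clade(date: float, names: list[str]) -> TreeNode:
        return TreeNode(date=date, children=[TreeNode(name=n) for n in names])

    west = TreeNode(date=1400.0, children=[
        clade(700.0, ["W1", "W2"]), TreeNode(name="W3")])
    east = TreeNode(date=1300.0, children=[
        clade(600.0, ["E1", "E2"]), TreeNode(name="E3")])
    south = TreeNode(date=1350.0, children=[
        clade(800.0, ["S1", "S2"]), TreeNode(name="S3")])
    inner = TreeNode(date=1900.0, children=[west, east, south])
    baltic = TreeNode(date=1300.0, children=[TreeNode(name="B1"), TreeNode(name="B2")])
    return DatedTree(TreeNode(date=3400.0, children=[inner, baltic]))


def simulate_wordlists(cfg: WordlistSimConfig) -> WordlistMatrix:
    """Simulate wordlists on ``cfg.true_tree``; cognate classes are globally novel."""
    rng = np.random.default_rng(cfg.seed)
    rates = np.broadcast_to(np.atleast_1d(np.asarray(cfg.rates, dtype=float)), (cfg.n_items,))
    counter = [0]

    def fresh() -> int:
        counter[0] += 1
        return counter[0]

    def branch_hazard(rate: float, parent_date: float, child_date: float) -> float:
        t1, t0 = parent_date / 1000.0, child_date / 1000.0
        if cfg.clock == "constant":
            return rate * (t1 - t0)
        return rate * (t1**2 - t0**2)  # integral of hazard 2*rate*t

    leaves = cfg.true_tree.root.leaves()
    leaf_states: dict[str, list[frozenset[int]]] = {}

    def evolve(node: TreeNode, states: list[frozenset[int]]) -> None:
        if node.is_leaf:
            leaf_states[node.name] = states
            return
        for ch in node.children:
            child_states = []
            for it in range(cfg.n_items):
                cell = states[it]
                n_repl = rng.poisson(branch_hazard(rates[it], node.date, ch.date))
                for _ in range(n_repl):
                    if rng.random() < cfg.synonym_prob:
                        cell = cell | {fresh()}
                    else:
                        cell = frozenset({fresh()})
                child_states.append(cell)
            evolve(ch, child_states)

    root_states = [frozenset({fresh()}) for _ in range(cfg.n_items)]
    evolve(cfg.true_tree.root, root_states)

    lects = [lf.name for lf in leaves]
    items = [f"item{i:03d}" for i in range(cfg.n_items)]
    cells = [[leaf_states[l][i] for l in lects] for i in range(cfg.n_items)]
    return WordlistMatrix(items=items, lects=lects, cells=cells)


# ---------------------------------------------------------------------------
# full synthetic study
# ---------------------------------------------------------------------------


def default_ibd_study_config(seed: int = 0, n_per_group: int = 25, mu: float = 2.0) -> IbdSimConfig:
    """Five-group sharing design shaped like the study's group comparisons.

    A focal East-West-Slav-like group (``EWS``) shares most recently with a
    north-east-European-like group (``NE``, 30 generations), equally with a
    South-Slav-like group (``SS``) and an inter-Slavic group (``Inter``, 45
    generations each), and most distantly with a Volga-like group (80
    generations).
    """
    names = ["EWS", "SS", "NE", "Inter", "Volga"]
    base = {
        ("EWS", "SS"): 45.0,
        ("EWS", "NE"): 30.0,
        ("EWS", "Inter"): 45.0,
        ("EWS", "Volga"): 80.0,
        ("SS", "NE"): 60.0,
        ("SS", "Inter"): 50.0,
        ("SS", "Volga"): 90.0,
        ("NE", "Inter"): 60.0,
        ("NE", "Volga"): 70.0,
        ("Inter", "Volga"): 70.0,
    }
    return IbdSimConfig(
        group_sizes={n: n_per_group for n in names}, depth=base, mu=mu, seed=seed
    )


def write_study_inputs(outdir, seed: int = 0) -> "Path":
    """Write a complete synthetic study (all input files plus a TOML config).

    Returns the path of the written ``study.toml``.  The generated inputs
    follow the study conditions encoded in the generator defaults; the
    linguistic distance matrix between populations is derived from the true
    hierarchy (closest within an ethnic group, farthest across branches).
    """
    from pathlib import Path

    from slavstrata.popdata_io import (
        DistanceMatrix,
        write_distance_matrix,
        write_group_definitions,
        write_haplogroup_table,
        write_ibd_segments,
    )
    from slavstrata.lexstat import write_wordlist_matrix

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    hcfg = HaploSimConfig(seed=seed, spatial_rho=1000.0, spatial_sd=0.8, tau_branch=25.0)
    table, hierarchy = simulate_haplogroups(hcfg)
    write_haplogroup_table(table, out / "haplogroups.tsv", out / "populations.tsv")

    # hierarchy-derived linguistic distances between populations
    pids = table.population_ids
    n = len(pids)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        bi, gi = hierarchy.assignment[pids[i]]
        bj, gj = hierarchy.assignment[pids[j]]
        d[i, j] = d[j, i] = 0.1 if gi == gj else (0.45 if bi == bj else 0.85)
    write_distance_matrix(DistanceMatrix(list(pids), d), out / "linguistic_distances.tsv")

    icfg = default_ibd_study_config(seed=seed)
    segs = simulate_ibd(icfg)
    write_ibd_segments(segs, out / "ibd_segments.tsv", out / "genetic_map.tsv")
    write_group_definitions(list(ibd_groups(icfg).values()), out / "ibd_groups.tsv")

    wcfg = WordlistSimConfig(seed=seed)
    w = simulate_wordlists(wcfg)
    write_wordlist_matrix(w, out / "wordlists.tsv")

    config = f"""# synthetic study configuration
[inputs]
haplogroup_table = "haplogroups.tsv"
population_meta = "populations.tsv"
linguistic_distances = "linguistic_distances.tsv"
ibd_segments = "ibd_segments.tsv"
genetic_map = "genetic_map.tsv"
ibd_groups = "ibd_groups.tsv"
wordlists = "wordlists.tsv"

[params]
seed = {seed}
permutations = 999
mds_dimensions = 2
mds_restarts = 8
lambda_glotto = 0.05
dating_law = "linear"
collapse_years = 300

[ibd]
focal = "EWS"
compare = [["SS", "Volga"], ["NE", "SS"], ["SS", "Inter"]]

[output]
dir = "results"
"""
    cfg_path = out / "study.toml"
    cfg_path.write_text(config, encoding="utf-8")
    return cfg_path
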