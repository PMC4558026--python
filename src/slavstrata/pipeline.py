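"""End-to-end study driver: one TOML config, six analysis stages, one manifest.

Stages: ``dist`` (Nei + geographic matrices), ``mds``, ``amova``, ``mantel``,
``ibd`` and ``lex``.  Each stage writes its results as TSV/Newick under the
output directory and records itself in ``manifest.json`` together with the
seeds and parameter values, so a rerun with the same config is bit-identical
for the deterministic stages.  Stages communicate only through the declared
files and the returned result bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from slavstrata import __version__
from slavstrata.amova import AmovaHierarchy, amova, amova_per_group
from slavstrata.gendist import haversine_matrix, nei_distance_matrix
from slavstrata.ibd_sharing import LengthClassBins, compare_sharing, sharing_profile_table
from slavstrata.lexstat import (
    collapse_consensus,
    lex_distance_matrix,
    read_wordlist_matrix,
    starling_nj,
    write_newick,
)
from slavstrata.matrix_tests import mantel, partial_mantel
from slavstrata.ordination import mds_embed
from slavstrata.popdata_io import (
    read_group_definitions,
    read_haplogroup_table,
    read_ibd_segments,
    write_distance_matrix,
)

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StageError", "load_config", "run_study"]

STAGES = ("dist", "mds", "amova", "mantel", "ibd", "lex")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class StudyConfig:
    haplogroup_table: Path
    population_meta: Path
    ibd_segments: Path
    genetic_map: Path
    ibd_groups: Path
    wordlists: Path
    output_dir: Path
    linguistic_distances: Path | None = None
    seed: int = 1
    permutations: int = 999
    mds_dimensions: int = 2
    mds_restarts: int = 8
    bin_edges: tuple[float, ...] = LengthClassBins().edges
    min_segment_cM: float = 1.0
    ibd_focal: str | None = None
    ibd_compare: list[tuple[str, str]] = field(default_factory=list)
    lambda_glotto: float = 0.05
    dating_law: str = "starostin"
    collapse_years: float = 300.0
    hierarchy_levels: tuple[str, str] = ("linguistic_branch", "ethnic_group")


def load_config(path: str | Path) -> StudyConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    base = Path(path).parent
    inputs = raw.get("inputs", {})
    params = raw.get("params", {})
    ibd = raw.get("ibd", {})

    def p(key: str) -> Path:
        if key not in inputs:
            raise ValueError(f"{path}: missing [inputs].{key}")
        return base / inputs[key]

    return StudyConfig(
        haplogroup_table=p("haplogroup_table"),
        population_meta=p("population_meta"),
        ibd_segments=p("ibd_segments"),
        genetic_map=p("genetic_map"),
        ibd_groups=p("ibd_groups"),
        wordlists=p("wordlists"),
        output_dir=base / raw.get("output", {}).get("dir", "results"),
        linguistic_distances=(base / inputs["linguistic_distances"])
        if "linguistic_distances" in inputs
        else None,
        seed=int(params.get("seed", 1)),
        permutations=int(params.get("permutations", 999)),
        mds_dimensions=int(params.get("mds_dimensions", 2)),
        mds_restarts=int(params.get("mds_restarts", 8)),
        bin_edges=tuple(params.get("bin_edges", LengthClassBins().edges)),
        min_segment_cM=float(params.get("min_segment_cM", 1.0)),
        ibd_focal=ibd.get("focal"),
        ibd_compare=[tuple(x) for x in ibd.get("compare", [])],
        lambda_glotto=float(params.get("lambda_glotto", 0.05)),
        dating_law=str(params.get("dating_law", "starostin")),
        collapse_years=float(params.get("collapse_years", 300.0)),
    )


def _require(cfg_path: Path, stage: str) -> Path:
    if not Path(cfg_path).exists():
        raise StageError(stage, f"input file not found: {cfg_path}")
    return Path(cfg_path)


def _param_hash(cfg: StudyConfig) -> str:
    blob = json.dumps(
        {k: str(v) for k, v in vars(cfg).items()}, sort_keys=True
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_study(cfg: StudyConfig) -> dict[str, Any]:
    """Run all six stages; returns the result bundle and writes the manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {}
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "param_hash": _param_hash(cfg),
        "stages": [],
    }

    # --- dist -------------------------------------------------------------
    table = read_haplogroup_table(
        _require(cfg.haplogroup_table, "dist"), _require(cfg.population_meta, "dist")
    )
    try:
        D = nei_distance_matrix(table)
        G = haversine_matrix(table.populations)
    except ValueError as e:
        raise StageError("dist", str(e)) from e
    write_distance_matrix(D, out / "nei_distances.tsv")
    write_distance_matrix(G, out / "geo_distances.tsv")
    results["dist"] = {"nei": D, "geo": G}
    manifest["stages"].append("dist")

    # --- mds --------------------------------------------------------------
    try:
        mres = mds_embed(D, k=cfg.mds_dimensions, restarts=cfg.mds_restarts, seed=cfg.seed)
    except ValueError as e:
        raise StageError("mds", str(e)) from e
    mres.coordinates.to_csv(out / "mds_coordinates.tsv", sep="\t", index_label="label")
    results["mds"] = mres
    logger.info("mds: stress = %.4f", mres.stress)
    manifest["stages"].append("mds")

    # --- amova ------------------------------------------------------------
    try:
        hierarchy = AmovaHierarchy.from_meta(table.populations, cfg.hierarchy_levels)
        ares = amova(table, hierarchy, permutations=cfg.permutations, seed=cfg.seed)
        per_group, avg_phi = amova_per_group(
            table, hierarchy, cfg.hierarchy_levels[-1], permutations=0, seed=cfg.seed
        )
    except ValueError as e:
        raise StageError("amova", str(e)) from e
    pd.DataFrame(
        {
            "component": list(ares.sigma),
            "sigma": list(ares.sigma.values()),
            "ss": list(ares.ss.values()),
            "df": list(ares.df.values()),
        }
    ).to_csv(out / "amova_components.tsv", sep="\t", index=False)
    results["amova"] = {"three_level": ares, "per_group": per_group, "avg_within_phi_st": avg_phi}
    manifest["stages"].append("amova")

    # --- mantel -----------------------------------------------------------
    try:
        m_geo = mantel(D, G, permutations=cfg.permutations, seed=cfg.seed)
        rows = [{"test": "nei~geo", "r": m_geo.r, "p": m_geo.p_value}]
        results["mantel"] = {"nei_geo": m_geo}
        if cfg.linguistic_distances is not None:
            from slavstrata.popdata_io import read_distance_matrix

            L = read_distance_matrix(_require(cfg.linguistic_distances, "mantel"))
            m_lex = mantel(D, L, permutations=cfg.permutations, seed=cfg.seed)
            pm_geo = partial_mantel(D, G, L, permutations=cfg.permutations, seed=cfg.seed)
            pm_lex = partial_mantel(D, L, G, permutations=cfg.permutations, seed=cfg.seed)
            rows += [
                {"test": "nei~lex", "r": m_lex.r, "p": m_lex.p_value},
                {"test": "nei~geo|lex", "r": pm_geo.r, "p": pm_geo.p_value},
                {"test": "nei~lex|geo", "r": pm_lex.r, "p": pm_lex.p_value},
            ]
            results["mantel"].update({"nei_lex": m_lex, "nei_geo_given_lex": pm_geo,
                                      "nei_lex_given_geo": pm_lex})
    except ValueError as e:
        raise StageError("mantel", str(e)) from e
    pd.DataFrame(rows).to_csv(out / "mantel.tsv", sep="\t", index=False)
    manifest["stages"].append("mantel")

    # --- ibd --------------------------------------------------------------
    segs = read_ibd_segments(
        _require(cfg.ibd_segments, "ibd"),
        _require(cfg.genetic_map, "ibd"),
        min_cM=cfg.min_segment_cM,
    )
    groups = {g.group_name: g for g in read_group_definitions(_require(cfg.ibd_groups, "ibd"))}
    bins = LengthClassBins(tuple(cfg.bin_edges))
    try:
        focal_name = cfg.ibd_focal or next(iter(groups))
        focal = groups[focal_name]
        comparators = [g for n, g in groups.items() if n != focal_name]
        prof = sharing_profile_table(segs, comparators, focal, bins)
        prof.to_csv(out / "ibd_profiles.tsv", sep="\t", index_label="comparator")
        comps = {}
        for c1, c2 in cfg.ibd_compare:
            comps[(c1, c2)] = compare_sharing(
                segs, focal, groups[c1], groups[c2], bins,
                permutations=cfg.permutations, seed=cfg.seed,
            )
        results["ibd"] = {"profiles": prof, "comparisons": comps, "focal": focal_name}
    except (KeyError, ValueError) as e:
        raise StageError("ibd", str(e)) from e
    manifest["stages"].append("ibd")

    # --- lex --------------------------------------------------------------
    w = read_wordlist_matrix(_require(cfg.wordlists, "lex"))
    try:
        lexD, share = lex_distance_matrix(w)
        tree = starling_nj(w, lambda_glotto=cfg.lambda_glotto, law=cfg.dating_law)
        consensus = collapse_consensus(tree, cfg.collapse_years)
    except ValueError as e:
        raise StageError("lex", str(e)) from e
    write_distance_matrix(lexD, out / "lex_distances.tsv")
    write_newick(tree, out / "lex_tree.nwk")
    write_newick(consensus, out / "lex_tree_consensus.nwk")
    results["lex"] = {"distances": lexD, "share": share, "tree": tree, "consensus": consensus}
    manifest["stages"].append("lex")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    results["manifest"] = manifest
    return results
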