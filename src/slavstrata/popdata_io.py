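"""Data model and tab-separated readers/writers for all pipeline inputs.

File dialects (all UTF-8, tab-separated, lines starting with ``#`` ignored):

* population metadata: columns ``population_id, ethnic_group,
  linguistic_branch, language, latitude, longitude, n_samples``;
* haplogroup table: header row of haplogroup labels, first column population
  id, cells either relative frequencies or integer counts (auto-detected);
* square distance matrix: first column and header carry identical labels;
* IBD segments: whitespace-separated ``id1 id2 chromosome start_marker
  end_marker score`` resolved against a PLINK-.map-like genetic map
  (``chromosome marker position_cM`` in the first three columns);
* group definitions: columns ``group_name, population_id``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationMeta",
    "HaplogroupFrequencyTable",
    "DistanceMatrix",
    "IBDSegmentSet",
    "GroupDefinition",
    "read_population_meta",
    "write_population_meta",
    "read_haplogroup_table",
    "write_haplogroup_table",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_ibd_segments",
    "write_ibd_segments",
    "read_group_definitions",
    "write_group_definitions",
]


@dataclass(frozen=True)
class PopulationMeta:
    """One sampled population with its linguistic affiliation and location."""

    population_id: str
    ethnic_group: str
    linguistic_branch: str
    language: str
    latitude: float
    longitude: float
    n_samples: int

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"{self.population_id}: latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"{self.population_id}: longitude {self.longitude} outside [-180, 180]")
        if self.n_samples < 1:
            raise ValueError(f"{self.population_id}: n_samples must be >= 1")


@dataclass
class HaplogroupFrequencyTable:
    """Populations x haplogroups relative-frequency matrix, optionally with counts.

    ``freq`` rows sum to 1; when integer ``counts`` are present the frequencies
    are the row-normalised counts.
    """

    populations: list[PopulationMeta]
    haplogroups: list[str]
    freq: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (len(self.populations), len(self.haplogroups)):
            raise ValueError("frequency matrix shape does not match populations x haplogroups")
        if np.any(self.freq < -1e-12) or np.any(self.freq > 1 + 1e-12):
            raise ValueError("frequencies must lie in [0, 1]")
        rowsums = self.freq.sum(axis=1)
        bad = np.where(np.abs(rowsums - 1.0) > 1e-9)[0]
        if bad.size:
            raise ValueError(
                f"frequency rows must sum to 1; row {bad[0]} "
                f"({self.populations[bad[0]].population_id}) sums to {rowsums[bad[0]]:.6g}"
            )
        ids = [p.population_id for p in self.populations]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate population_id in table")
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if self.counts.shape != self.freq.shape:
                raise ValueError("counts shape does not match freq shape")

    @classmethod
    def from_counts(
        cls, populations: list[PopulationMeta], haplogroups: list[str], counts: np.ndarray
    ) -> "HaplogroupFrequencyTable":
        counts = np.asarray(counts)
        rowsums = counts.sum(axis=1)
        zero = np.where(rowsums == 0)[0]
        if zero.size:
            raise ValueError(
                f"empty population: row {zero[0]} ({populations[zero[0]].population_id}) "
                "has zero total count"
            )
        freq = counts / rowsums[:, None]
        return cls(populations, haplogroups, freq, counts=counts)

    @property
    def population_ids(self) -> list[str]:
        return [p.population_id for p in self.populations]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freq, index=self.population_ids, columns=self.haplogroups)


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix is {self.d.shape}, expected ({n}, {n})")
        if np.any(self.d < -1e-12):
            raise ValueError("negative distances")
        if np.max(np.abs(self.d - self.d.T)) > 1e-9:
            raise ValueError("asymmetric distance matrix")
        if np.max(np.abs(np.diag(self.d))) > 1e-9:
            raise ValueError("non-zero diagonal")
        # exact symmetry / zero diagonal after validation
        self.d = (self.d + self.d.T) / 2.0
        np.fill_diagonal(self.d, 0.0)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Return the submatrix restricted to ``labels``, in that order."""
        idx = [self.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.d[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy ``squareform`` order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.d[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class IbdSegment:
    id1: str
    id2: str
    chromosome: str
    start_cM: float
    end_cM: float

    def __post_init__(self) -> None:
        if self.end_cM <= self.start_cM:
            raise ValueError(f"segment {self.id1}-{self.id2}: end {self.end_cM} <= start {self.start_cM}")
        if self.id1 == self.id2:
            raise ValueError(f"segment pairs an individual with itself: {self.id1}")

    @property
    def length_cM(self) -> float:
        return self.end_cM - self.start_cM


@dataclass
class IBDSegmentSet:
    """Pairwise IBD segments over registered individuals.

    ``individuals`` maps each individual id to the population it was sampled
    from; half-open genetic-map coordinates ``[start_cM, end_cM)``.
    """

    individuals: dict[str, str]
    segments: list[IbdSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.segments:
            for i in (s.id1, s.id2):
                if i not in self.individuals:
                    raise ValueError(f"segment references unregistered individual {i!r}")

    def individuals_of(self, population_ids: Iterable[str]) -> list[str]:
        wanted = set(population_ids)
        return [i for i, p in self.individuals.items() if p in wanted]

    def lengths(self) -> np.ndarray:
        return np.array([s.length_cM for s in self.segments])


@dataclass(frozen=True)
class GroupDefinition:
    """Named set of population ids used in group-level comparisons."""

    group_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.group_name!r} has no members")

    @classmethod
    def of(cls, group_name: str, members: Iterable[str]) -> "GroupDefinition":
        return cls(group_name, frozenset(members))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "population_id",
    "ethnic_group",
    "linguistic_branch",
    "language",
    "latitude",
    "longitude",
    "n_samples",
]


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kw)


def read_population_meta(path: str | Path) -> list[PopulationMeta]:
    df = _read_tsv(path)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    return [
        PopulationMeta(
            population_id=r.population_id,
            ethnic_group=r.ethnic_group,
            linguistic_branch=r.linguistic_branch,
            language=r.language,
            latitude=float(r.latitude),
            longitude=float(r.longitude),
            n_samples=int(r.n_samples),
        )
        for r in df.itertuples()
    ]


def write_population_meta(meta: Sequence[PopulationMeta], path: str | Path) -> None:
    pd.DataFrame([vars(m) for m in meta])[_META_COLUMNS].to_csv(path, sep="\t", index=False)


def _is_count_table(values: np.ndarray) -> bool:
    """Counts heuristic: all entries integral and rows not already normalised."""
    integral = np.allclose(values, np.round(values), atol=1e-9)
    normalised = np.allclose(values.sum(axis=1), 1.0, atol=1e-6)
    return integral and not normalised


def read_haplogroup_table(path: str | Path, meta_path: str | Path) -> HaplogroupFrequencyTable:
    """Read a populations x haplogroups table and join it with metadata.

    Cells may be relative frequencies or integer counts; a table whose entries
    are all integers and whose rows do not sum to one is treated as counts and
    renormalised.
    """
    meta = {m.population_id: m for m in read_population_meta(meta_path)}
    df = _read_tsv(path, index_col=0)
    values = df.to_numpy(dtype=float)
    haplogroups = [str(c) for c in df.columns]
    populations = []
    for rownum, pid in enumerate(df.index):
        if pid not in meta:
            raise ValueError(f"{path}: row {rownum + 1}: unknown population {pid!r} (not in metadata)")
        populations.append(meta[pid])
    zero = np.where(values.sum(axis=1) == 0)[0]
    if zero.size:
        raise ValueError(f"{path}: empty population in row {zero[0] + 1} ({df.index[zero[0]]!r})")
    if _is_count_table(values):
        return HaplogroupFrequencyTable.from_counts(populations, haplogroups, values.astype(int))
    # tolerate rounded frequency tables: renormalise rows
    freq = values / values.sum(axis=1, keepdims=True)
    return HaplogroupFrequencyTable(populations, haplogroups, freq)


def write_haplogroup_table(
    table: HaplogroupFrequencyTable, path: str | Path, meta_path: str | Path | None = None
) -> None:
    data = table.counts if table.counts is not None else table.freq
    pd.DataFrame(data, index=table.population_ids, columns=table.haplogroups).to_csv(
        path, sep="\t", index_label="population_id"
    )
    if meta_path is not None:
        write_population_meta(table.populations, meta_path)


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a square labelled TSV; asymmetries up to 1e-6 are averaged out."""
    df = _read_tsv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is {df.shape[0]}x{df.shape[1]}, not square")
    rows = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]
    if rows != cols:
        raise ValueError(f"{path}: row labels differ from column labels")
    d = df.to_numpy(dtype=float)
    if np.any(d < 0):
        raise ValueError(f"{path}: negative entries")
    asym = np.max(np.abs(d - d.T))
    if asym > 1e-6:
        i, j = np.unravel_index(np.argmax(np.abs(d - d.T)), d.shape)
        raise ValueError(
            f"{path}: asymmetric matrix: d[{rows[i]},{rows[j]}]={d[i, j]:.6g} "
            f"vs d[{rows[j]},{rows[i]}]={d[j, i]:.6g}"
        )
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(rows, d)


def write_distance_matrix(D: DistanceMatrix, path: str | Path) -> None:
    D.to_frame().to_csv(path, sep="\t", index_label="", float_format="%.12g")


def _read_genetic_map(map_path: str | Path) -> dict[tuple[str, str], float]:
    """PLINK-.map-like file: chromosome, marker name, cM position (cols 1-3)."""
    cm: dict[tuple[str, str], float] = {}
    with open(map_path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{map_path}: map line needs >= 3 columns: {line!r}")
            cm[(parts[0], parts[1])] = float(parts[2])
    return cm


def read_ibd_segments(
    path: str | Path,
    map_path: str | Path,
    min_cM: float = 1.0,
    individuals: dict[str, str] | None = None,
) -> IBDSegmentSet:
    """Read fastIBD-style pairwise segments, resolving markers through a map.

    Columns: id1, id2, chromosome, start_marker, end_marker[, score].
    Segments shorter than ``min_cM`` after map lookup are dropped (count
    logged).  When ``individuals`` is None the population of each individual
    is taken as the prefix of its id before the last underscore.
    """
    cm = _read_genetic_map(map_path)
    segments: list[IbdSegment] = []
    seen: dict[str, str] = {}
    dropped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected >= 5 columns")
            id1, id2, chrom, m1, m2 = parts[:5]
            for m in (m1, m2):
                if (chrom, m) not in cm:
                    raise ValueError(f"{path}:{lineno}: marker {m!r} on chromosome {chrom} absent from map")
            start, end = cm[(chrom, m1)], cm[(chrom, m2)]
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end position {end} cM not after start {start} cM")
            if end - start < min_cM:
                dropped += 1
                continue
            segments.append(IbdSegment(id1, id2, chrom, start, end))
            for i in (id1, id2):
                seen.setdefault(i, i.rsplit("_", 1)[0])
    if dropped:
        logger.info("read_ibd_segments: dropped %d segments shorter than %g cM", dropped, min_cM)
    if individuals is None:
        individuals = seen
    return IBDSegmentSet(individuals=individuals, segments=segments)


def write_ibd_segments(segs: IBDSegmentSet, path: str | Path, map_path: str | Path) -> None:
    """Write segments plus a companion map with one marker per endpoint."""
    with open(map_path, "w", encoding="utf-8") as mfh, open(path, "w", encoding="utf-8") as sfh:
        for k, s in enumerate(segs.segments):
            ma, mb = f"m{k}a", f"m{k}b"
            mfh.write(f"{s.chromosome}\t{ma}\t{s.start_cM:.6f}\n{s.chromosome}\t{mb}\t{s.end_cM:.6f}\n")
            sfh.write(f"{s.id1}\t{s.id2}\t{s.chromosome}\t{ma}\t{mb}\t1.0\n")


def read_group_definitions(path: str | Path) -> list[GroupDefinition]:
    df = _read_tsv(path)
    for col in ("group_name", "population_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return [
        GroupDefinition.of(name, sub["population_id"].tolist())
        for name, sub in df.groupby("group_name", sort=False)
    ]


def write_group_definitions(groups: Sequence[GroupDefinition], path: str | Path) -> None:
    rows = [
        {"group_name": g.group_name, "population_id": pid}
        for g in groups
        for pid in sorted(g.members)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
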