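import numpy as np
import pytest

from slavstrata.popdata_io import (
    DistanceMatrix,
    HaplogroupFrequencyTable,
    PopulationMeta,
)


def make_meta(pid, group="g", branch="b", lat=50.0, lon=20.0, n=10):
    return PopulationMeta(
        population_id=pid,
        ethnic_group=group,
        linguistic_branch=branch,
        language=group,
        latitude=lat,
        longitude=lon,
        n_samples=n,
    )


@pytest.fixture
def small_counts_table():
    """Two populations, two haplogroups, counts [[8,2],[2,8]]."""
    metas = [make_meta("p1"), make_meta("p2")]
    return HaplogroupFrequencyTable.from_counts(metas, ["A", "B"], np.array([[8, 2], [2, 8]]))


@pytest.fixture
def meta_tsv(tmp_path):
    path = tmp_path / "meta.tsv"
    path.write_text(
        "population_id\tethnic_group\tlinguistic_branch\tlanguage\tlatitude\tlongitude\tn_samples\n"
        "p1\tg1\tb1\tl1\t50.0\t20.0\t10\n"
        "p2\tg1\tb1\tl1\t51.0\t21.0\t10\n"
        "p3\tg2\tb2\tl2\t55.0\t30.0\t10\n"
    )
    return path


def write_square_matrix(path, labels, d):
    lines = ["\t" + "\t".join(labels)]
    for lab, row in zip(labels, np.asarray(d)):
        lines.append(lab + "\t" + "\t".join(f"{v:.12g}" for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def planar_distance_matrix():
    """Exact Euclidean distances of 5 planar points (perfectly 2-embeddable)."""
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.2, 1.3], [-0.5, 0.7]])
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix([f"P{i}" for i in range(5)], d)
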