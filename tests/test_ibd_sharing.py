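"""The ibd-statistic: per-pair averaging, binning conservation, comparisons."""

import numpy as np
import pytest

from slavstrata.ibd_sharing import (
    LengthClassBins,
    compare_sharing,
    ibd_statistic,
    sharing_profile_table,
)
from slavstrata.popdata_io import GroupDefinition, IbdSegment, IBDSegmentSet
from slavstrata.synthetic_data import IbdSimConfig, ibd_groups, simulate_ibd


def seg(i, j, length, chrom="1", start=10.0):
    return IbdSegment(i, j, chrom, start, start + length)


def make_set(individuals, segments):
    return IBDSegmentSet(individuals=individuals, segments=segments)


GA = GroupDefinition.of("a", ["popA"])
GB = GroupDefinition.of("b", ["popB"])


class TestIbdStatistic:
    def test_hand_counted_two_pair_example(self):
        segs = make_set(
            {"i1": "popA", "i2": "popA", "j1": "popB"},
            [seg("i1", "j1", 2.2), seg("i1", "j1", 4.5)],
        )
        prof = ibd_statistic(segs, GA, GB)
        labels = prof.bins.labels
        per = dict(zip(labels, prof.per_class))
        assert prof.n_pairs == 2
        assert per["[2,2.5)"] == pytest.approx(0.5)
        assert per["[4,5)"] == pytest.approx(0.5)
        assert prof.total == pytest.approx(1.0)
        assert sum(v for k, v in per.items() if k not in ("[2,2.5)", "[4,5)")) == 0.0

    def test_no_segments_gives_zero_profile(self):
        segs = make_set({"i1": "popA", "j1": "popB"}, [])
        prof = ibd_statistic(segs, GA, GB)
        assert np.all(prof.per_class == 0.0)

    def test_duplicating_individuals_leaves_profile_unchanged(self):
        segs = make_set(
            {"i1": "popA", "j1": "popB"},
            [seg("i1", "j1", 2.2), seg("i1", "j1", 4.5)],
        )
        dup = make_set(
            {"i1": "popA", "i1b": "popA", "j1": "popB"},
            [seg("i1", "j1", 2.2), seg("i1", "j1", 4.5),
             seg("i1b", "j1", 2.2), seg("i1b", "j1", 4.5)],
        )
        p1 = ibd_statistic(segs, GA, GB)
        p2 = ibd_statistic(dup, GA, GB)
        assert np.allclose(p1.per_class, p2.per_class)

    def test_overlapping_groups_rejected(self):
        segs = make_set({"i1": "popA", "j1": "popB"}, [])
        both = GroupDefinition.of("both", ["popA", "popB"])
        with pytest.raises(ValueError, match="overlap"):
            ibd_statistic(segs, GA, both)

    def test_conservation_under_binning(self):
        """Sum over classes equals the binning-free per-pair segment count."""
        cfg = IbdSimConfig(seed=3)
        segs = simulate_ibd(cfg)
        g = ibd_groups(cfg)
        for bins in (LengthClassBins(), LengthClassBins((1.0, 5.0)), LengthClassBins((1.0,))):
            prof = ibd_statistic(segs, g["A"], g["B"], bins)
            n_a = len(segs.individuals_of({"A"}))
            n_b = len(segs.individuals_of({"B"}))
            assert prof.total == pytest.approx(len(segs.segments) / (n_a * n_b))

    def test_doubling_segments_doubles_every_class(self):
        segs = make_set(
            {"i1": "popA", "j1": "popB"},
            [seg("i1", "j1", 2.2), seg("i1", "j1", 11.0)],
        )
        doubled = make_set(
            segs.individuals, segs.segments + [seg(s.id1, s.id2, s.length_cM) for s in segs.segments]
        )
        p1 = ibd_statistic(segs, GA, GB)
        p2 = ibd_statistic(doubled, GA, GB)
        assert np.allclose(p2.per_class, 2.0 * p1.per_class)

    def test_invariant_to_segment_ordering(self):
        s = [seg("i1", "j1", 2.2), seg("i1", "j1", 4.5), seg("i1", "j1", 11.0)]
        p1 = ibd_statistic(make_set({"i1": "popA", "j1": "popB"}, s), GA, GB)
        p2 = ibd_statistic(make_set({"i1": "popA", "j1": "popB"}, s[::-1]), GA, GB)
        assert np.allclose(p1.per_class, p2.per_class)


class TestCompareSharing:
    def test_dominance_when_c2_segments_are_subset(self):
        inds = {"f1": "popF", "c1a": "pop1", "c2a": "pop2"}
        segs = make_set(
            inds,
            [seg("f1", "c1a", 2.2), seg("f1", "c1a", 4.5), seg("f1", "c2a", 2.2)],
        )
        res = compare_sharing(
            make_set(inds, segs.segments),
            GroupDefinition.of("f", ["popF"]),
            GroupDefinition.of("c1", ["pop1"]),
            GroupDefinition.of("c2", ["pop2"]),
            permutations=0,
        )
        nonzero = res.delta_per_class[np.abs(res.delta_per_class) > 0]
        assert np.all(nonzero > 0)
        assert res.delta_total > 0
        assert res.p_value is None

    def test_antisymmetric_under_comparator_swap(self):
        cfg = IbdSimConfig(
            group_sizes={"F": 10, "X": 10, "Y": 10},
            depth={("F", "X"): 30.0, ("F", "Y"): 60.0},
            seed=1,
        )
        segs = simulate_ibd(cfg)
        g = ibd_groups(cfg)
        a = compare_sharing(segs, g["F"], g["X"], g["Y"], permutations=0)
        b = compare_sharing(segs, g["F"], g["Y"], g["X"], permutations=0)
        assert a.delta_total == pytest.approx(-b.delta_total)
        assert np.allclose(a.delta_per_class, -b.delta_per_class)

    def test_depth_30_vs_60_significant(self):
        cfg = IbdSimConfig(
            group_sizes={"F": 25, "X": 25, "Y": 25},
            depth={("F", "X"): 30.0, ("F", "Y"): 60.0},
            mu=2.0,
            seed=7,
        )
        segs = simulate_ibd(cfg)
        g = ibd_groups(cfg)
        res = compare_sharing(segs, g["F"], g["X"], g["Y"], permutations=499, seed=11)
        assert res.delta_total > 0
        assert res.p_value < 0.01

    def test_null_pvalue_roughly_uniform(self):
        """Statistically identical comparators: p should not pile up low."""
        rng = np.random.default_rng(99)
        pvals = []
        for k in range(40):
            cfg = IbdSimConfig(
                group_sizes={"F": 8, "X": 8, "Y": 8},
                depth={("F", "X"): 40.0, ("F", "Y"): 40.0},
                seed=int(rng.integers(2**31 - 1)),
            )
            segs = simulate_ibd(cfg)
            g = ibd_groups(cfg)
            res = compare_sharing(segs, g["F"], g["X"], g["Y"], permutations=99,
                                  seed=int(rng.integers(2**31 - 1)))
            pvals.append(res.p_value)
        assert 0.2 < np.mean(pvals) < 0.8
        assert np.mean(np.array(pvals) <= 0.05) < 0.2


class TestProfileTable:
    def test_single_comparator_matches_ibd_statistic(self):
        cfg = IbdSimConfig(seed=2)
        segs = simulate_ibd(cfg)
        g = ibd_groups(cfg)
        tab = sharing_profile_table(segs, [g["B"]], g["A"])
        prof = ibd_statistic(segs, g["A"], g["B"])
        assert np.allclose(tab.iloc[0][prof.bins.labels].to_numpy(dtype=float), prof.per_class)

    def test_row_order_follows_group_order(self):
        cfg = IbdSimConfig(
            group_sizes={"F": 5, "X": 5, "Y": 5},
            depth={("F", "X"): 30.0, ("F", "Y"): 60.0},
            seed=4,
        )
        segs = simulate_ibd(cfg)
        g = ibd_groups(cfg)
        t1 = sharing_profile_table(segs, [g["X"], g["Y"]], g["F"])
        t2 = sharing_profile_table(segs, [g["Y"], g["X"]], g["F"])
        assert list(t1.index) == ["X", "Y"] and list(t2.index) == ["Y", "X"]
        assert np.allclose(t1.loc["X"].to_numpy(dtype=float), t2.loc["X"].to_numpy(dtype=float))

    def test_profile_totals_monotone_in_depth(self):
        cfg = IbdSimConfig(
            group_sizes={"F": 20, "X": 20, "Y": 20, "Z": 20},
            depth={("F", "X"): 10.0, ("F", "Y"): 30.0, ("F", "Z"): 60.0},
            mu=2.0,
            seed=5,
        )
        segs = simulate_ibd(cfg)
        g = ibd_groups(cfg)
        tab = sharing_profile_table(segs, [g["X"], g["Y"], g["Z"]], g["F"])
        totals = tab["total"].to_numpy(dtype=float)
        assert totals[0] > totals[1] > totals[2]
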