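"""AMOVA against an individual-expanded brute-force oracle."""

import numpy as np
import pytest
from scipy.stats import kstest

from slavstrata.amova import AmovaHierarchy, amova, amova_per_group
from slavstrata.popdata_io import HaplogroupFrequencyTable
from tests.conftest import make_meta


def brute_force_two_level(counts):
    """Explicit pairwise-mismatch decomposition over expanded individuals."""
    haps, pops = [], []
    for p, row in enumerate(counts):
        for h, c in enumerate(row):
            haps.extend([h] * int(c))
            pops.extend([p] * int(c))
    haps, pops = np.array(haps), np.array(pops)
    N = len(haps)
    P = counts.shape[0]
    delta2 = (haps[:, None] != haps[None, :]).astype(float)
    ss_total = delta2.sum() / (2.0 * N)
    ss_wp = 0.0
    n_p = np.array([(pops == p).sum() for p in range(P)])
    for p in range(P):
        sel = pops == p
        ss_wp += delta2[np.ix_(sel, sel)].sum() / (2.0 * n_p[p])
    ss_ap = ss_total - ss_wp
    df_ap, df_wp = P - 1, N - P
    sigma_c = ss_wp / df_wp
    ncoef = (N - (n_p**2).sum() / N) / df_ap
    sigma_b = (ss_ap / df_ap - sigma_c) / ncoef
    return ss_ap, ss_wp, sigma_b, sigma_c


def table_from_counts(counts, groups=None):
    counts = np.asarray(counts)
    metas = []
    for i in range(counts.shape[0]):
        g = groups[i] if groups else "g"
        metas.append(make_meta(f"p{i}", group=g, branch=g, n=int(counts[i].sum())))
    return HaplogroupFrequencyTable.from_counts(
        metas, [f"h{j}" for j in range(counts.shape[1])], counts
    )


class TestTwoLevel:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_pops = rng.integers(2, 5)
        n_h = rng.integers(2, 4)
        counts = rng.integers(0, 6, size=(n_pops, n_h))
        counts[counts.sum(axis=1) == 0, 0] = 1  # no empty populations
        while counts.sum() > 30:
            counts = np.maximum(counts - 1, 0)
            counts[counts.sum(axis=1) == 0, 0] = 1
        ss_ap, ss_wp, sigma_b, sigma_c = brute_force_two_level(counts)
        res = amova(table_from_counts(counts))
        assert res.ss["among_pops"] == pytest.approx(ss_ap, abs=1e-9)
        assert res.ss["within_pops"] == pytest.approx(ss_wp, abs=1e-9)
        assert res.sigma["among_pops"] == pytest.approx(sigma_b, abs=1e-9)
        assert res.sigma["within_pops"] == pytest.approx(sigma_c, abs=1e-9)

    def test_identical_populations_give_zero_phi(self):
        # raw estimate is <= 0 for identical counts; clamped view is exactly 0
        res = amova(table_from_counts([[5, 5], [5, 5], [5, 5]]))
        assert res.sigma["among_pops"] <= 0
        assert res.sigma_clamped["among_pops"] == 0.0
        assert res.phi_clamped["phi_st"] == 0.0

    def test_hand_example_two_pops(self):
        # counts (10,0) and (5,5): oracle decomposition over 20 individuals
        ss_ap, ss_wp, sigma_b, sigma_c = brute_force_two_level(np.array([[10, 0], [5, 5]]))
        res = amova(table_from_counts([[10, 0], [5, 5]]))
        assert res.phi["phi_st"] == pytest.approx(sigma_b / (sigma_b + sigma_c), abs=1e-12)


class TestThreeLevel:
    def test_fixed_groups_give_phi_st_one(self):
        # 2 groups x 2 pops x 10 individuals; groups fixed for different hgs
        counts = np.array([[10, 0], [10, 0], [0, 10], [0, 10]])
        res = amova(table_from_counts(counts, groups=["g1", "g1", "g2", "g2"]),
                    groups={"p0": "g1", "p1": "g1", "p2": "g2", "p3": "g2"})
        assert res.phi["phi_st"] == pytest.approx(1.0, abs=1e-12)
        assert res.phi["phi_sc"] == pytest.approx(0.0, abs=1e-12)
        assert res.sigma["within_pops"] == pytest.approx(0.0, abs=1e-12)

    def test_no_differentiation_gives_all_zero(self):
        counts = np.array([[6, 4], [6, 4], [6, 4], [6, 4]])
        res = amova(table_from_counts(counts), groups={"p0": "x", "p1": "x", "p2": "y", "p3": "y"})
        for k in ("phi_ct", "phi_sc", "phi_st"):
            assert res.phi_clamped[k] == pytest.approx(0.0, abs=1e-12)
            assert res.phi[k] <= 1e-12  # raw estimate non-positive without structure

    def test_components_sum_to_total_variance(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 10, size=(6, 4))
        groups = {f"p{i}": ("g1" if i < 3 else "g2") for i in range(6)}
        res = amova(table_from_counts(counts), groups=groups)
        # total variance from the one-pass global decomposition
        N = counts.sum()
        ss_total = sum(res.ss.values())
        df_total = N - 1
        # sigma_T equals the sum of components only approximately equals
        # ss_total/df_total for unequal sizes; check additivity of SS instead
        haps = np.repeat(np.tile(np.arange(4), 6), counts.ravel())
        delta2 = (haps[:, None] != haps[None, :]).astype(float)
        assert ss_total == pytest.approx(delta2.sum() / (2.0 * N), abs=1e-9)

    def test_single_group_not_testable(self):
        counts = np.array([[5, 1], [2, 4]])
        res = amova(table_from_counts(counts), groups={"p0": "only", "p1": "only"})
        assert not res.testable["among_groups"]
        assert np.isnan(res.sigma["among_groups"])

    def test_permutation_p_detects_structure(self):
        counts = np.array([[20, 0], [18, 2], [1, 19], [0, 20]])
        groups = {"p0": "g1", "p1": "g1", "p2": "g2", "p3": "g2"}
        res = amova(table_from_counts(counts, groups=["g1", "g1", "g2", "g2"]),
                    groups=groups, permutations=99, seed=1)
        assert res.p_values["phi_st"] < 0.05


class TestPerGroup:
    def test_identical_local_pops_give_zero(self):
        counts = np.array([[5, 5], [5, 5], [9, 1], [1, 9]])
        groups = ["ga", "ga", "gb", "gb"]
        t = table_from_counts(counts, groups=groups)
        hierarchy = AmovaHierarchy.from_meta(t.populations, ("linguistic_branch", "ethnic_group"))
        results, avg = amova_per_group(t, hierarchy, "ethnic_group")
        d = dict(results)
        assert d["ga"].phi_clamped["phi_st"] == 0.0
        assert d["gb"].phi["phi_st"] > 0.3
        assert avg == pytest.approx(
            np.mean([d["ga"].phi["phi_st"], d["gb"].phi["phi_st"]])
        )

    def test_hand_example_matches_brute_force(self):
        counts = np.array([[10, 0], [5, 5]])
        _, _, sigma_b, sigma_c = brute_force_two_level(counts)
        t = table_from_counts(counts, groups=["g", "g"])
        hierarchy = AmovaHierarchy.from_meta(t.populations, ("linguistic_branch", "ethnic_group"))
        results, _ = amova_per_group(t, hierarchy, "ethnic_group")
        assert results[0][1].phi["phi_st"] == pytest.approx(
            sigma_b / (sigma_b + sigma_c), abs=1e-12
        )


class TestPermutationCalibration:
    def test_null_pvalues_uniform(self):
        """Under no structure the permutation p-value is ~Uniform(0,1)."""
        rng = np.random.default_rng(123)
        pvals = []
        for _ in range(200):
            counts = rng.multinomial(8, [0.5, 0.3, 0.2], size=4)
            counts[counts.sum(axis=1) == 0, 0] = 1
            res = amova(table_from_counts(counts), permutations=59,
                        seed=int(rng.integers(2**31 - 1)))
            pvals.append(res.p_values["phi_st"])
        # discrete p on 60 support points; KS against uniform with loose alpha
        stat = kstest(pvals, "uniform").statistic
        assert stat < 0.12
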