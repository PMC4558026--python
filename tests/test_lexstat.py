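"""Lexicostatistic distances, dating laws, tree building and Newick round trips."""

import numpy as np
import pytest

from slavstrata.lexstat import (
    DatedTree,
    TreeNode,
    WordlistMatrix,
    collapse_consensus,
    glotto_date,
    lex_distance_matrix,
    read_newick,
    read_wordlist_matrix,
    starling_nj,
    write_newick,
    write_wordlist_matrix,
)


def wl(items, lects, cells, weights=None):
    return WordlistMatrix(items=items, lects=lects,
                          cells=[[frozenset(c) for c in row] for row in cells],
                          weights=weights)


class TestLexDistance:
    def test_identical_wordlists_give_zero(self):
        w = wl(["i1", "i2"], ["A", "B"], [[{1}, {1}], [{2}, {2}]])
        D, c = lex_distance_matrix(w)
        assert D.d[0, 1] == 0.0
        assert c.iloc[0, 1] == 1.0

    def test_hand_counted_shares_with_synonyms_and_missing(self):
        # 10 items: 7 intersecting, 2 disjoint, 1 missing in lect B => c = 7/9
        cells = []
        for k in range(7):
            cells.append([{k}, {k, 100 + k}])  # synonym on B side still matches
        cells.append([{50}, {60}])
        cells.append([{51}, {61}])
        cells.append([{52}, set()])
        w = wl([f"i{k}" for k in range(10)], ["A", "B"], cells)
        D, c = lex_distance_matrix(w)
        assert c.iloc[0, 1] == pytest.approx(7 / 9)
        assert D.d[0, 1] == pytest.approx(2 / 9)

    def test_duplicate_synonym_never_changes_distance(self):
        base = [[{1}, {1}], [{2}, {3}], [{4}, {4, 5}]]
        w1 = wl(["a", "b", "c"], ["X", "Y"], base)
        base2 = [[{1}, {1}], [{2}, {3}], [{4, 4}, {4, 5}]]
        w2 = wl(["a", "b", "c"], ["X", "Y"], base2)
        assert lex_distance_matrix(w1)[0].d[0, 1] == lex_distance_matrix(w2)[0].d[0, 1]

    def test_weights_change_share(self):
        cells = [[{1}, {1}], [{2}, {3}]]
        w_flat = wl(["a", "b"], ["X", "Y"], cells)
        w_wt = wl(["a", "b"], ["X", "Y"], cells, weights=np.array([3.0, 1.0]))
        assert lex_distance_matrix(w_flat)[1].iloc[0, 1] == pytest.approx(0.5)
        assert lex_distance_matrix(w_wt)[1].iloc[0, 1] == pytest.approx(0.75)

    def test_no_compared_items_rejected(self):
        w = wl(["a", "b"], ["X", "Y"], [[{1}, set()], [set(), {2}]])
        with pytest.raises(ValueError, match="X.*Y"):
            lex_distance_matrix(w)

    def test_round_trip_through_tsv(self, tmp_path):
        w = wl(["a", "b"], ["X", "Y"], [[{1, 2}, {1}], [{3}, set()]])
        path = tmp_path / "w.tsv"
        write_wordlist_matrix(w, path)
        w2 = read_wordlist_matrix(path)
        assert w2.items == w.items and w2.lects == w.lects
        assert w2.cells == w.cells


class TestGlottoDate:
    def test_full_share_dates_to_zero(self):
        for law in ("starostin", "sqrt", "linear"):
            assert glotto_date(1.0, law=law) == 0.0

    def test_closed_form_starostin_value(self):
        # c = 0.75, lambda = 0.05: sqrt(0.287682/0.075) millennia ~ 1959 YBP
        t = glotto_date(0.75, 0.05, law="starostin")
        assert t == pytest.approx(np.sqrt(-np.log(0.75) / (2 * 0.05 * 0.75)) * 1000, rel=1e-12)
        assert t == pytest.approx(1959, abs=1.0)

    def test_laws_are_antitone_in_share(self):
        for law in ("starostin", "sqrt", "linear"):
            dates = [glotto_date(c, law=law) for c in (0.2, 0.4, 0.6, 0.8, 0.999)]
            assert all(a > b for a, b in zip(dates, dates[1:]))

    def test_invalid_share_rejected(self):
        for c in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                glotto_date(c)


class TestStarlingNj:
    def test_ultrametric_toy_topology_and_date_order(self):
        # A,B near-identical; C distant: ((A,B),C) with the AB node younger
        cells = []
        for k in range(20):
            ab = {k}
            c_val = {k} if k < 8 else {1000 + k}
            cells.append([ab, ab if k < 18 else {500 + k}, c_val])
        w = wl([f"i{k}" for k in range(20)], ["A", "B", "C"], cells)
        tree = starling_nj(w, law="linear", exclude_lects=())
        sets = tree.topology_sets()
        assert frozenset({"A", "B"}) in sets
        dates = tree.node_dates()
        assert dates[frozenset({"A", "B"})] < dates[frozenset({"A", "B", "C"})]

    def test_excluded_lect_dropped(self):
        cells = [[{k}, {k}, {k + 100}, {k + 200}] for k in range(10)]
        w = wl([f"i{k}" for k in range(10)], ["A", "B", "C", "Slovenian"], cells)
        tree = starling_nj(w, law="linear")
        assert "Slovenian" not in tree.leaf_names

    def test_parent_dates_monotone(self):
        from slavstrata.synthetic_data import WordlistSimConfig, simulate_wordlists

        w = simulate_wordlists(WordlistSimConfig(seed=5))
        tree = starling_nj(w, law="linear", exclude_lects=())
        for node in tree.root.walk():
            for ch in node.children:
                assert ch.date <= node.date + 1e-9


class TestCollapse:
    @staticmethod
    def chain_tree(gap):
        inner = TreeNode(date=2100.0 - gap, children=[
            TreeNode(name="B"), TreeNode(name="C")])
        root = TreeNode(date=2100.0, children=[TreeNode(name="A"), inner])
        return DatedTree(root)

    def test_small_gap_contracts_to_ternary(self):
        t = collapse_consensus(self.chain_tree(200.0))
        assert len(t.root.children) == 3
        assert t.root.date == 2100.0

    def test_gap_above_threshold_unchanged(self):
        t = collapse_consensus(self.chain_tree(301.0))
        assert len(t.root.children) == 2

    def test_boundary_gap_exactly_300_contracts(self):
        t = collapse_consensus(self.chain_tree(300.0))
        assert len(t.root.children) == 3

    def test_idempotent(self):
        base = self.chain_tree(250.0)
        once = collapse_consensus(base)
        twice = collapse_consensus(once)
        assert once.node_dates() == twice.node_dates()
        assert once.topology_sets() == twice.topology_sets()

    def test_does_not_touch_leaves(self):
        t = collapse_consensus(self.chain_tree(200.0))
        assert sorted(t.leaf_names) == ["A", "B", "C"]


class TestNewick:
    def test_cherry_serialisation(self):
        t = DatedTree(TreeNode(date=1000.0, children=[TreeNode(name="A"), TreeNode(name="B")]))
        assert write_newick(t).replace(" ", "") == "(A:1000,B:1000);"

    def test_multifurcation_preserved(self):
        t = DatedTree(TreeNode(date=500.0, children=[
            TreeNode(name="A"), TreeNode(name="B"), TreeNode(name="C")]))
        t2 = read_newick(write_newick(t))
        assert len(t2.root.children) == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_random_trees(self, seed, tmp_path):
        rng = np.random.default_rng(seed)

        def random_tree(names, depth):
            if len(names) == 1:
                return TreeNode(name=names[0])
            k = rng.integers(1, len(names))
            left = random_tree(names[:k], depth * rng.uniform(0.3, 0.9))
            right = random_tree(names[k:], depth * rng.uniform(0.3, 0.9))
            return TreeNode(date=depth, children=[left, right])

        n = int(rng.integers(3, 9))
        t = DatedTree(random_tree([f"L{i}" for i in range(n)], 3000.0))
        path = tmp_path / "t.nwk"
        write_newick(t, path)
        t2 = read_newick(path)
        assert t2.topology_sets() == t.topology_sets()
        d1, d2 = t.node_dates(), t2.node_dates()
        for k in d1:
            assert d2[k] == pytest.approx(d1[k], abs=0.5)
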