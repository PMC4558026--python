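"""Cognate-matrix lexicostatistics and glottochronological tree dating.

A wordlist matrix holds, for each Swadesh concept and each lect, the set of
cognate classes attested for that concept (synonyms allowed; empty set =
missing).  Two lects match on an item when their cognate-class sets
intersect.  With per-item stability weights w (default 1) the cognate share
of lects i, j over the items non-missing in both is

    c_ij = sum_{matched} w_item / sum_{compared} w_item,   d_ij = 1 - c_ij.

Node dates come from a glottochronological decay law.  The default is the
Starostin-school law with the share-dependent correction,

    t = sqrt( -ln c / (2 lambda c) )   [millennia],  lambda = 0.05 / ky^2,

alongside the uncorrected square-root law t = sqrt(-ln c / (2 lambda)) and a
constant-rate law t = -ln c / (2 lambda) (lambda per millennium) that
inverts a homogeneous Poisson replacement clock.

Tree building ("StarlingNJ" style): neighbor-joining on d, midpoint-rooted;
each internal node is dated from the mean cognate share between the leaf
sets of its child clusters, and dates are made monotone root-ward by a
running maximum.  Neighboring binary nodes closer than a threshold (default
300 years) can be collapsed into multifurcations for a consensus-style tree.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio.tree import nj

from slavstrata.popdata_io import DistanceMatrix

__all__ = [
    "WordlistMatrix",
    "TreeNode",
    "DatedTree",
    "read_wordlist_matrix",
    "write_wordlist_matrix",
    "lex_distance_matrix",
    "glotto_date",
    "starling_nj",
    "collapse_consensus",
    "write_newick",
    "read_newick",
]

DEFAULT_LAMBDA = 0.05
DEFAULT_EXCLUDED_LECTS = ("Slovenian",)


@dataclass
class WordlistMatrix:
    """Swadesh items x lects; each cell a (possibly empty) set of cognate classes."""

    items: list[str]
    lects: list[str]
    cells: list[list[frozenset[int]]]  # [item][lect]
    weights: np.ndarray | None = None  # per-item stability weight, > 0

    def __post_init__(self) -> None:
        if len(self.cells) != len(self.items) or any(len(r) != len(self.lects) for r in self.cells):
            raise ValueError("cells shape does not match items x lects")
        for j, lect in enumerate(self.lects):
            if all(not self.cells[i][j] for i in range(len(self.items))):
                raise ValueError(f"lect {lect!r} has no non-missing cells")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.items),) or np.any(self.weights <= 0):
                raise ValueError("weights must be positive, one per item")

    def drop_lects(self, names: Iterable[str]) -> "WordlistMatrix":
        drop = set(names)
        keep = [j for j, l in enumerate(self.lects) if l not in drop]
        return WordlistMatrix(
            items=list(self.items),
            lects=[self.lects[j] for j in keep],
            cells=[[row[j] for j in keep] for row in self.cells],
            weights=self.weights,
        )


def _parse_cell(text: str) -> frozenset[int]:
    text = text.strip()
    if not text or text == "?":
        return frozenset()
    return frozenset(int(t) for t in text.split(","))


def read_wordlist_matrix(path: str | Path, weights_path: str | Path | None = None) -> WordlistMatrix:
    """TSV dialect: rows = items, columns = lects, cell = comma-separated
    integer cognate-class ids, empty or ``?`` = missing."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str).fillna("")
    items = [str(i) for i in df.index]
    lects = [str(c) for c in df.columns]
    cells = [[_parse_cell(df.iat[i, j]) for j in range(len(lects))] for i in range(len(items))]
    weights = None
    if weights_path is not None:
        wdf = pd.read_csv(weights_path, sep="\t", comment="#", index_col=0)
        weights = wdf.iloc[:, 0].reindex(items).to_numpy(dtype=float)
        if np.any(~np.isfinite(weights)):
            raise ValueError(f"{weights_path}: missing weight for some items")
    return WordlistMatrix(items, lects, cells, weights)


def write_wordlist_matrix(w: WordlistMatrix, path: str | Path) -> None:
    data = [
        [",".join(str(c) for c in sorted(cell)) for cell in row]
        for row in w.cells
    ]
    pd.DataFrame(data, index=w.items, columns=w.lects).to_csv(path, sep="\t", index_label="item")


def cognate_share_matrix(w: WordlistMatrix) -> pd.DataFrame:
    """Weighted cognate-share matrix c_ij (synonym rule: sets intersect = match)."""
    n = len(w.lects)
    weights = w.weights if w.weights is not None else np.ones(len(w.items))
    c = np.ones((n, n))
    for i, j in combinations(range(n), 2):
        compared = matched = 0.0
        for it, row in enumerate(w.cells):
            a, b = row[i], row[j]
            if not a or not b:
                continue
            compared += weights[it]
            if a & b:
                matched += weights[it]
        if compared == 0:
            raise ValueError(f"lects {w.lects[i]!r} and {w.lects[j]!r} share no compared items")
        c[i, j] = c[j, i] = matched / compared
    return pd.DataFrame(c, index=w.lects, columns=w.lects)


def lex_distance_matrix(w: WordlistMatrix) -> tuple[DistanceMatrix, pd.DataFrame]:
    """Lexicostatistic distances d = 1 - c plus the cognate-share matrix."""
    if len(w.lects) < 2:
        raise ValueError("need at least 2 lects")
    c = cognate_share_matrix(w)
    d = 1.0 - c.to_numpy()
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(w.lects), d), c


def glotto_date(c: float, lambda_glotto: float = DEFAULT_LAMBDA, law: str = "starostin") -> float:
    """Date (years before present) of a split with cognate share ``c``.

    Laws: ``starostin`` t = sqrt(-ln c/(2 lambda c)); ``sqrt``
    t = sqrt(-ln c/(2 lambda)); ``linear`` t = -ln c/(2 lambda).
    Antitone in c; t(1) = 0.
    """
    if not 0.0 < c <= 1.0:
        raise ValueError(f"cognate share must lie in (0, 1], got {c}")
    neglog = -np.log(c)
    if law == "starostin":
        t = np.sqrt(neglog / (2.0 * lambda_glotto * c))
    elif law == "sqrt":
        t = np.sqrt(neglog / (2.0 * lambda_glotto))
    elif law == "linear":
        t = neglog / (2.0 * lambda_glotto)
    else:
        raise ValueError(f"unknown dating law {law!r}")
    return float(t * 1000.0)


# ---------------------------------------------------------------------------
# dated trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of a rooted dated tree; ``date`` in years before present."""

    name: str | None = None
    date: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for ch in self.children for lf in ch.leaves()]

    def walk(self) -> Iterable["TreeNode"]:
        yield self
        for ch in self.children:
            yield from ch.walk()


@dataclass
class DatedTree:
    """Rooted tree whose internal nodes carry dates in years before present."""

    root: TreeNode

    def __post_init__(self) -> None:
        for node in self.root.walk():
            for ch in node.children:
                if ch.date > node.date + 1e-9:
                    raise ValueError(
                        f"child date {ch.date} exceeds parent date {node.date}"
                    )

    @property
    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.root.leaves()]

    def node_dates(self) -> dict[frozenset[str], float]:
        """Map each internal node's leaf set to its date (for comparisons)."""
        return {
            frozenset(lf.name for lf in n.leaves()): n.date
            for n in self.root.walk()
            if not n.is_leaf
        }

    def topology_sets(self) -> set[frozenset[str]]:
        """Non-trivial clades (excluding leaves and the full set)."""
        all_leaves = frozenset(self.leaf_names)
        return {
            s for s in self.node_dates() if s != all_leaves
        }

    def copy(self) -> "DatedTree":
        def rec(n: TreeNode) -> TreeNode:
            return TreeNode(n.name, n.date, [rec(c) for c in n.children])

        return DatedTree(rec(self.root))


def _mean_cross_share(c: pd.DataFrame, clusters: Sequence[list[str]]) -> float:
    vals = []
    for a, b in combinations(range(len(clusters)), 2):
        for x in clusters[a]:
            for y in clusters[b]:
                vals.append(c.loc[x, y])
    return float(np.mean(vals))


def starling_nj(
    w: WordlistMatrix,
    lambda_glotto: float = DEFAULT_LAMBDA,
    law: str = "starostin",
    exclude_lects: Sequence[str] = DEFAULT_EXCLUDED_LECTS,
    min_share: float = 0.01,
) -> DatedTree:
    """Dated neighbor-joining tree from a wordlist matrix.

    Topology by NJ on the lexicostatistic distances (midpoint-rooted); each
    internal node dated from the mean cognate share between the leaf sets of
    its child clusters, monotonised root-ward.  Lects listed in
    ``exclude_lects`` (default: Slovenian, whose vocabulary mixes branches)
    are dropped before tree building when present.  A mean share of zero
    (no cognates at all between clusters) would date to infinity; shares are
    floored at ``min_share``.
    """
    present = [l for l in exclude_lects if l in w.lects]
    if present:
        w = w.drop_lects(present)
    if len(w.lects) < 3:
        raise ValueError("need at least 3 lects for a tree")
    D, c = lex_distance_matrix(w)
    sk = SkbioDistanceMatrix(D.d, ids=list(D.labels))
    unrooted = nj(sk)
    rooted = unrooted.root_at_midpoint()

    def convert(sknode) -> TreeNode:
        if sknode.is_tip():
            return TreeNode(name=str(sknode.name), date=0.0)
        return TreeNode(name=None, date=0.0, children=[convert(ch) for ch in sknode.children])

    root = convert(rooted)

    def date_rec(node: TreeNode) -> None:
        for ch in node.children:
            date_rec(ch)
        if node.is_leaf:
            return
        clusters = [[lf.name for lf in ch.leaves()] for ch in node.children]
        share = max(_mean_cross_share(c, clusters), min_share)
        node.date = glotto_date(share, lambda_glotto, law=law)
        # parent at least as old as its children (running maximum root-ward)
        node.date = max([node.date] + [ch.date for ch in node.children])

    date_rec(root)
    return DatedTree(root)


def collapse_consensus(t: DatedTree, threshold_years: float = 300.0) -> DatedTree:
    """Contract internal edges whose parent-child date gap is <= threshold.

    Produces multifurcations; the contracted node keeps the parent's date.
    Gaps are evaluated top-down on the partly collapsed tree, which makes the
    operation idempotent.
    """
    out = t.copy()

    def rec(node: TreeNode) -> None:
        changed = True
        while changed:
            changed = False
            new_children: list[TreeNode] = []
            for ch in node.children:
                if not ch.is_leaf and node.date - ch.date <= threshold_years:
                    new_children.extend(ch.children)
                    changed = True
                else:
                    new_children.append(ch)
            node.children = new_children
        for ch in node.children:
            rec(ch)

    rec(out.root)
    return out


def _to_dendropy(t: DatedTree) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def rec(node: TreeNode, dnode: dendropy.Node) -> None:
        for ch in node.children:
            dch = dnode.new_child(edge_length=node.date - ch.date)
            if ch.is_leaf:
                dch.taxon = taxa.new_taxon(ch.name)
            rec(ch, dch)

    rec(t.root, tree.seed_node)
    return tree


def write_newick(t: DatedTree, path: str | Path | None = None) -> str:
    """Newick string with branch lengths in years (parent date - child date)."""
    tree = _to_dendropy(t)
    s = tree.as_string(schema="newick", suppress_rooting=True, real_value_format_specifier="g")
    s = s.strip()
    if path is not None:
        Path(path).write_text(s + "\n", encoding="utf-8")
    return s


def read_newick(source: str | Path) -> DatedTree:
    """Read a Newick tree with branch lengths in years; leaves are at 0 YBP.

    Node dates are reconstructed from root-to-node path lengths, assuming the
    tree is ultrametric (as produced by :func:`write_newick`).
    """
    text = Path(source).read_text(encoding="utf-8") if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ) else str(source)
    tree = dendropy.Tree.get(file=io.StringIO(text), schema="newick")
    # root height = longest root-to-leaf path
    def depth(dnode) -> float:
        if dnode.is_leaf():
            return 0.0
        return max((ch.edge.length or 0.0) + depth(ch) for ch in dnode.child_nodes())

    height = depth(tree.seed_node)

    def convert(dnode, date: float) -> TreeNode:
        if dnode.is_leaf():
            return TreeNode(name=dnode.taxon.label if dnode.taxon else dnode.label, date=0.0)
        node = TreeNode(name=None, date=date)
        node.children = [
            convert(ch, date - (ch.edge.length or 0.0)) for ch in dnode.child_nodes()
        ]
        return node

    root = convert(tree.seed_node, height)
    return DatedTree(root)
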