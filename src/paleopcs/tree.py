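"""Dated phylogenies: Newick I/O, taxon merging, BLADJ dating, patristic distances.

Trees are rooted, with an optional age (Ma before present) on each node.
Branch lengths of a dated tree are parent age minus child age, so a tree with
all tips at age 0 is ultrametric.  Newick parsing and serialization are
delegated to :mod:`dendropy`; the tree is held in a light node structure that
the dating and editing operations manipulate directly.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd


class TreeError(ValueError):
    """Raised for structurally invalid trees or inconsistent age constraints."""


@dataclass
class Node:
    label: str | None = None
    age: float | None = None
    parent: "Node | None" = None
    children: list["Node"] = field(default_factory=list)
    # edge length from parent, kept when read from Newick; for a dated tree it
    # is recomputed as parent.age - age on write
    edge_length: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class Tree:
    """A rooted tree with optional node ages (Ma)."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ walks
    def preorder(self) -> Iterable[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterable[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.preorder() if n.is_leaf)

    def is_fully_dated(self) -> bool:
        return all(n.age is not None for n in self.preorder())

    def find_tip(self, label: str) -> Node:
        for n in self.leaves():
            if n.label == label:
                return n
        raise KeyError(f"tip {label!r} not in tree")

    def mrca(self, labels: Sequence[str]) -> Node:
        """Most recent common ancestor of the named tips."""
        want = set(labels)
        missing = want - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        # postorder accumulation of tip sets
        found: dict[int, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                s = {node.label} & want
            else:
                s = set()
                for c in node.children:
                    s |= found.pop(id(c))
            if s == want:
                return node
            found[id(node)] = s
        raise TreeError("MRCA search failed")  # pragma: no cover

    def copy(self) -> "Tree":
        def _copy(node: Node) -> Node:
            new = Node(label=node.label, age=node.age, edge_length=node.edge_length)
            for c in node.children:
                new.add_child(_copy(c))
            return new

        return Tree(_copy(self.root))

    def validate(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        # dated ancestors must not be younger than dated descendants; the
        # tolerance scales with tree height so round-tripped ages survive
        dated = [n.age for n in self.preorder() if n.age is not None]
        tol = 1e-9 * max(1.0, max(dated, default=0.0))
        for node in self.preorder():
            if node.age is None:
                continue
            anc = node.parent
            while anc is not None:
                if anc.age is not None and anc.age < node.age - tol:
                    raise TreeError(
                        f"age inversion: ancestor age {anc.age} < descendant age "
                        f"{node.age} ({node.label or 'internal'})"
                    )
                anc = anc.parent

    # --------------------------------------------------------------- dendropy
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Tree":
        def _conv(dnode) -> Node:
            node = Node(
                label=dnode.taxon.label if dnode.taxon else dnode.label,
                edge_length=dnode.edge.length,
            )
            for dchild in dnode.child_nodes():
                node.add_child(_conv(dchild))
            return node

        return cls(_conv(dtree.seed_node))

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)

        def _conv(node: Node, dnode) -> None:
            if node.is_leaf:
                dnode.taxon = taxa.require_taxon(label=node.label)
            elif node.label:
                dnode.label = node.label
            dnode.edge.length = node.edge_length
            for c in node.children:
                _conv(c, dnode.new_child())

        _conv(self.root, dtree.seed_node)
        return dtree

    # ------------------------------------------------------------------- ages
    def ages_from_edge_lengths(self) -> None:
        """Derive node ages assuming the tree is ultrametric with tips at 0.

        Raises :class:`TreeError` when root-to-tip path lengths disagree by
        more than 1e-6.
        """
        depth = {id(self.root): 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            if node.edge_length is None:
                raise TreeError("missing edge length; cannot derive ages")
            depth[id(node)] = depth[id(node.parent)] + node.edge_length
        tip_depths = [depth[id(n)] for n in self.leaves()]
        height = max(tip_depths)
        if max(tip_depths) - min(tip_depths) > 1e-6:
            raise TreeError("tree is not ultrametric; cannot derive ages from lengths")
        for node in self.preorder():
            node.age = height - depth[id(node)]

    def edge_lengths_from_ages(self) -> None:
        for node in self.preorder():
            if node is self.root:
                node.edge_length = None
                continue
            if node.age is None or node.parent.age is None:
                raise TreeError("undated node; cannot set edge lengths")
            node.edge_length = node.parent.age - node.age


# ---------------------------------------------------------------------- I/O


def read_tree(path_or_string: str | Path, retain_branch_lengths: bool = True) -> Tree:
    """Read a rooted Newick tree.

    Parameters
    ----------
    path_or_string
        File path, or a Newick string (detected by a terminating ';').
    retain_branch_lengths
        When True and lengths are present, keep them (and derive node ages if
        the tree is ultrametric).  When False, lengths are discarded and the
        result is an undated topology.

    Raises
    ------
    TreeError
        On duplicate tip labels or a basal polytomy (taken to mean an
        unrooted input).
    """
    text = str(path_or_string)
    if not text.strip().endswith(";"):
        text = Path(path_or_string).read_text()
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"malformed Newick input: {exc}") from exc
    tree = Tree.from_dendropy(dtree)
    if len(tree.root.children) > 2:
        raise TreeError(
            "root has more than two children; input looks unrooted — "
            "root the tree before analysis"
        )
    tree.validate()
    if retain_branch_lengths:
        has_lengths = all(
            n.edge_length is not None for n in tree.preorder() if n is not tree.root
        )
        if has_lengths:
            try:
                tree.ages_from_edge_lengths()
            except TreeError:
                pass  # non-ultrametric lengths are kept as-is, no ages
    else:
        for n in tree.preorder():
            n.edge_length = None
    return tree


def write_tree(tree: Tree, path: str | Path | None = None) -> str:
    """Serialize to Newick; dated trees get branch lengths from ages."""
    out = tree.copy()
    if out.is_fully_dated():
        out.edge_lengths_from_ages()
    dtree = out.to_dendropy()
    has_lengths = any(
        n.edge_length is not None for n in out.preorder() if n is not out.root
    )
    s = dtree.as_string(
        schema="newick",
        suppress_edge_lengths=not has_lengths,
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    ).strip()
    if path is not None:
        Path(path).write_text(s + "\n")
    return s


def read_node_ages(path: str | Path) -> dict[str, float]:
    """Read a node-age table CSV with columns ``clade_name,age_ma``."""
    df = pd.read_csv(path)
    return dict(zip(df["clade_name"].astype(str), df["age_ma"].astype(float)))


# ------------------------------------------------------------------- editing


def merge_taxa(
    tree: Tree,
    groups: Sequence[tuple[Sequence[str], str]],
    missing: str = "error",
) -> Tree:
    """Collapse groups of pollen-indistinguishable tips into single tips.

    Each group ``(members, name)`` is replaced by one tip attached at the
    members' most recent common ancestor, with the MRCA's age (zero-length
    stem), because the merged pollen type represents the whole clade.

    Parameters
    ----------
    missing
        ``"error"`` rejects groups with absent members; ``"skip"`` drops the
        absent members (a group left with one member simply renames it).
    """
    seen: set[str] = set()
    for members, _name in groups:
        overlap = seen & set(members)
        if overlap:
            raise ValueError(f"merge groups overlap: {sorted(overlap)}")
        seen |= set(members)

    out = tree.copy()
    for members, name in groups:
        tips = set(out.tip_labels)
        present = [m for m in members if m in tips]
        absent = [m for m in members if m not in tips]
        if absent and missing == "error":
            raise KeyError(f"merge group {name!r}: members absent from tree: {absent}")
        if not present:
            continue
        if len(present) == 1:
            out.find_tip(present[0]).label = name
            continue
        mrca = out.mrca(present)
        _remove_tips(out, present, protect=mrca)
        if mrca.is_leaf:
            mrca.label = name  # MRCA subtree contained only group members
        else:
            tip = Node(label=name, age=mrca.age, edge_length=0.0)
            mrca.add_child(tip)
        _suppress_unifurcations(out)
    out.validate()
    return out


def prune_clade(tree: Tree, clade_tips: Iterable[str]) -> Tree:
    """Remove the named tips (e.g. gymnosperms after dating); ages unchanged."""
    drop = set(clade_tips)
    out = tree.copy()
    tips = set(out.tip_labels)
    missing = drop - tips
    if missing:
        raise KeyError(f"tips not in tree: {sorted(missing)}")
    if len(tips - drop) < 2:
        raise TreeError("pruning would leave fewer than 2 tips")
    _remove_tips(out, drop, protect=None)
    _suppress_unifurcations(out)
    return out


def _remove_tips(tree: Tree, labels: Iterable[str], protect: Node | None) -> None:
    drop = set(labels)
    for label in drop:
        node = tree.find_tip(label)
        parent = node.parent
        parent.children.remove(node)
        # clean up internal nodes emptied by the removal
        while parent is not None and parent is not protect and not parent.children:
            gp = parent.parent
            if gp is None:
                raise TreeError("cannot remove all tips")
            gp.children.remove(parent)
            parent = gp


def _suppress_unifurcations(tree: Tree) -> None:
    for node in list(tree.postorder()):
        if node.is_leaf or len(node.children) != 1:
            continue
        child = node.children[0]
        if node.parent is None:
            # root with a single child: child becomes the new root
            child.parent = None
            child.edge_length = None
            tree.root = child
        else:
            if node.edge_length is not None and child.edge_length is not None:
                child.edge_length = node.edge_length + child.edge_length
            child.parent = node.parent
            idx = node.parent.children.index(node)
            node.parent.children[idx] = child


# --------------------------------------------------------------------- BLADJ


def bladj_date(
    tree: Tree,
    ages: Mapping[str, float],
    root_age: float | None = None,
    default_tip_age: float = 0.0,
) -> Tree:
    """Date every node by the BLADJ even-spacing rule.

    Ages are supplied for a subset of nodes, keyed by tip label or internal
    node label; the root age must be among them (or given via ``root_age``).
    Tips without an entry default to ``default_tip_age`` (extant taxa).
    Fixed nodes are then processed oldest first: each fixed node is walked up
    to its nearest dated ancestor and the undated nodes on that path are
    assigned evenly spaced ages between the two fixed ages.  Processing in
    descending age order guarantees that no assigned age inverts a dated
    ancestor/descendant pair, so branch lengths are never negative, and
    re-dating an already fully dated tree changes nothing.
    """
    out = tree.copy()
    labeled = {}
    for node in out.preorder():
        if node.label is not None:
            labeled[node.label] = node

    for name, age in ages.items():
        if name not in labeled:
            raise KeyError(f"aged node {name!r} not found in tree")
        labeled[name].age = float(age)
    if root_age is not None:
        out.root.age = float(root_age)
    if out.root.age is None:
        raise TreeError("root age is required for BLADJ dating")
    for leaf in out.leaves():
        if leaf.age is None:
            leaf.age = float(default_tip_age)
    out.validate()  # rejects inverted age constraints

    order = [n for n in out.preorder()]
    index = {id(n): i for i, n in enumerate(order)}
    fixed = sorted(
        (n for n in order if n.age is not None),
        key=lambda n: (-n.age, index[id(n)]),
    )
    dated = {id(n) for n in fixed}

    for node in fixed:
        # collect undated nodes on the path up to the nearest dated ancestor
        chain: list[Node] = []
        anc = node.parent
        while anc is not None and id(anc) not in dated:
            chain.append(anc)
            anc = anc.parent
        if not chain:
            continue
        if anc is None:  # pragma: no cover - root is always dated
            raise TreeError("no dated ancestor found")
        span = anc.age - node.age
        step = span / (len(chain) + 1)
        for k, u in enumerate(reversed(chain), start=1):
            # k edges below the dated ancestor
            u.age = anc.age - k * step
            dated.add(id(u))

    if not out.is_fully_dated():  # pragma: no cover - defensive
        raise TreeError("BLADJ left undated nodes")
    out.validate()
    # clamp sub-tolerance inversions (round-tripped ages can disagree with
    # supplied fixed ages at the ~1e-9 level) so no branch length is negative
    for node in out.preorder():
        if node.parent is not None and node.age > node.parent.age:
            node.age = node.parent.age
    out.edge_lengths_from_ages()
    return out


# --------------------------------------------------------------- distances


def cophenetic_distances(tree: Tree) -> pd.DataFrame:
    """Patristic distance matrix between tips of a fully dated tree.

    ``d(i, j)`` is the sum of branch lengths on the path between tips,
    equal to ``2 * age(MRCA) - age(i) - age(j)``.
    """
    if not tree.is_fully_dated():
        raise TreeError("cophenetic distances require a fully dated tree")
    leaves = tree.leaves()
    labels = [n.label for n in leaves]
    n = len(leaves)
    # for each node, the set of leaf indices below it (postorder)
    D = np.zeros((n, n))
    leaf_index = {id(node): i for i, node in enumerate(leaves)}
    below: dict[int, list[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = [leaf_index[id(node)]]
            continue
        kids = [below.pop(id(c)) for c in node.children]
        merged: list[int] = []
        # pairs whose MRCA is this node: tips in different child subtrees
        for a, b in itertools.combinations(kids, 2):
            for i in a:
                ai = leaves[i].age
                for j in b:
                    d = 2.0 * node.age - ai - leaves[j].age
                    D[i, j] = d
                    D[j, i] = d
        for k in kids:
            merged.extend(k)
        below[id(node)] = merged
    return pd.DataFrame(D, index=labels, columns=labels)
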