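"""Rooted time trees and tree utilities.

The package works with rooted trees whose nodes may carry ages in Ma
(tips with age > 0 are extinct/fossil samples, age 0 is the present) and
whose branches may carry relative or absolute rates.  A deliberately
small ``Node``/``Tree`` pair is used internally; Newick/NEXUS exchange
goes through dendropy so that dialect quirks are not our problem.
"""

from __future__ import annotations

import re
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "Node",
    "Tree",
    "read_tree",
    "write_tree",
    "bipartitions",
    "clades",
    "strict_consensus",
    "majority_rule_allcompat",
]


class Node:
    """A node of a rooted tree.

    ``age`` is the node's age in Ma (time before present), ``length`` the
    duration of the branch subtending the node, and ``rate`` an optional
    branch rate annotation.  ``length`` and ``age`` are kept independent:
    time trees use ages (lengths derived as parent.age - age); unrooted
    parsimony trees use lengths only.
    """

    __slots__ = ("label", "age", "length", "rate", "children", "parent")

    def __init__(self, label: str | None = None, age: float | None = None,
                 length: float | None = None, rate: float | None = None):
        self.label = label
        self.age = age
        self.length = length
        self.rate = rate
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Node({self.label!r}, age={self.age})"


class Tree:
    """A rooted tree over labelled leaves."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def find(self, label: str) -> Node:
        for n in self.postorder():
            if n.label == label:
                return n
        raise KeyError(label)

    # -- age/length bookkeeping -------------------------------------------
    def set_lengths_from_ages(self) -> None:
        for node in self.postorder():
            if node.parent is not None:
                node.length = node.parent.age - node.age

    def set_ages_from_lengths(self, tip_ages: dict[str, float] | None = None) -> None:
        """Assign ages from branch lengths, anchoring tips.

        With ``tip_ages`` omitted all tips are placed at age 0 (only valid
        for ultrametric trees); node ages are max over children of
        child age + child length.
        """
        for node in self.postorder():
            if node.is_leaf:
                node.age = 0.0 if tip_ages is None else tip_ages[node.label]
            else:
                node.age = max(c.age + (c.length or 0.0) for c in node.children)

    def total_branch_length(self) -> float:
        return sum(n.length for n in self.postorder() if n.parent is not None)

    def copy(self) -> "Tree":
        def rec(node: Node) -> Node:
            new = Node(node.label, node.age, node.length, node.rate)
            for c in node.children:
                new.add_child(rec(c))
            return new
        return Tree(rec(self.root))

    def __len__(self) -> int:
        return len(self.leaves())

    # -- Newick ------------------------------------------------------------
    def to_newick(self, lengths: bool = True, annotations: bool = False,
                  ages_as_lengths: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = _quote(node.label)
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    s += _quote(node.label)
            if annotations:
                parts = []
                if node.age is not None:
                    parts.append(f"age={node.age:.12g}")
                if node.rate is not None:
                    parts.append(f"rate={node.rate:.12g}")
                if parts:
                    s += "[&" + ",".join(parts) + "]"
            if ages_as_lengths and node.parent is not None and node.age is not None:
                s += f":{node.parent.age - node.age:.12g}"
            elif lengths and node.length is not None:
                s += f":{node.length:.12g}"
            return s
        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               suppress_internal_node_taxa=True,
                               extract_comment_metadata=False)
        return _from_dendropy(dt)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tree({len(self)} leaves)"


_QUOTE_NEEDED = re.compile(r"[\s()\[\]{}/\\,;:=*'\"`+<>-]")


def _quote(label: str | None) -> str:
    if label is None:
        return ""
    if _QUOTE_NEEDED.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


_ANNOT = re.compile(r"&?\s*(\w+)\s*=\s*([-+0-9.eE]+)")


def _from_dendropy(dt: dendropy.Tree) -> Tree:
    def rec(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for comment in dnode.comments or []:
            for key, val in _ANNOT.findall(comment):
                if key == "age":
                    node.age = float(val)
                elif key == "rate":
                    node.rate = float(val)
        for child in dnode.child_nodes():
            node.add_child(rec(child))
        return node
    return Tree(rec(dt.seed_node))


def read_tree(path) -> Tree:
    """Read the first tree from a Newick or NEXUS file (by extension)."""
    text = open(path).read()
    schema = "nexus" if text.lstrip().lower().startswith("#nexus") else "newick"
    dt = dendropy.Tree.get(data=text, schema=schema,
                           suppress_internal_node_taxa=True,
                           extract_comment_metadata=False)
    return _from_dendropy(dt)


def write_tree(tree: Tree, path, annotations: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(annotations=annotations) + "\n")


# ---------------------------------------------------------------------------
# splits and consensus
# ---------------------------------------------------------------------------

def clades(tree: Tree, reference: str | None = None,
           trivial: bool = False) -> set[frozenset]:
    """Return the tree's splits as leaf-label sets not containing ``reference``.

    Rooting all trees at the side of a common reference taxon turns unrooted
    split compatibility into nested-or-disjoint clade compatibility, which is
    what the consensus builders below exploit.  The reference defaults to the
    lexicographically smallest leaf label.
    """
    labels = frozenset(tree.leaf_labels())
    if reference is None:
        reference = min(labels)
    out: set[frozenset] = set()
    below: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        s = below[id(node)]
        if reference in s:
            s = labels - s
        if trivial or 1 < len(s) < len(labels) - 1 or (trivial and len(s) >= 1):
            if 1 < len(s) < len(labels):
                out.add(s)
    return out


def bipartitions(tree: Tree) -> set[frozenset]:
    """Non-trivial unrooted bipartitions, canonicalized (see :func:`clades`)."""
    return clades(tree)


def _compatible(clade: frozenset, accepted: Iterable[frozenset]) -> bool:
    for other in accepted:
        inter = clade & other
        if inter and inter != clade and inter != other:
            return False
    return True


def _build_from_clades(labels: Sequence[str], accepted: dict[frozenset, float],
                       reference: str) -> Tree:
    """Assemble a rooted tree from pairwise nested-or-disjoint clades.

    Each accepted clade becomes an internal node attached to its smallest
    strict superset (the root when none exists); each leaf attaches to the
    smallest clade containing it.  The reference taxon hangs off the root,
    which realises the convention that clades never contain it.
    """
    ordered = sorted(accepted, key=len, reverse=True)
    root = Node()
    tree_nodes = {clade: Node() for clade in ordered}
    for clade in ordered:
        supersets = [o for o in ordered if clade < o]
        parent = tree_nodes[min(supersets, key=len)] if supersets else root
        parent.add_child(tree_nodes[clade])
    for label in sorted(l for l in labels if l != reference):
        containing = [c for c in ordered if label in c]
        parent = tree_nodes[min(containing, key=len)] if containing else root
        parent.add_child(Node(label))
    root.add_child(Node(reference))
    return Tree(root)


def _split_frequencies(trees: Sequence[Tree],
                       weights: Sequence[float] | None,
                       reference: str) -> dict[frozenset, float]:
    if weights is None:
        weights = [1.0] * len(trees)
    total = float(sum(weights))
    freq: dict[frozenset, float] = {}
    for tree, w in zip(trees, weights):
        for clade in clades(tree, reference=reference):
            freq[clade] = freq.get(clade, 0.0) + w
    return {c: f / total for c, f in freq.items()}


def _check_leafsets(trees: Sequence[Tree]) -> list[str]:
    labels = sorted(trees[0].leaf_labels())
    for t in trees[1:]:
        if sorted(t.leaf_labels()) != labels:
            raise ValueError("consensus requires identical leaf sets; "
                             f"got {sorted(t.leaf_labels())} vs {labels}")
    return labels


def strict_consensus(trees: Sequence[Tree]) -> Tree:
    """Consensus containing only the splits present in every input tree."""
    labels = _check_leafsets(trees)
    reference = min(labels)
    freq = _split_frequencies(trees, None, reference)
    accepted = {c: f for c, f in freq.items() if f >= 1.0 - 1e-12}
    return _build_from_clades(labels, accepted, reference)


def majority_rule_allcompat(trees: Sequence[Tree],
                            weights: Sequence[float] | None = None
                            ) -> tuple[Tree, dict[frozenset, float]]:
    """Majority-rule consensus extended with compatible lower-frequency groups.

    Splits with frequency > 0.5 are always included (they are mutually
    compatible); the remaining splits are then added greedily in decreasing
    frequency order whenever compatible with the growing set.  Returns the
    consensus tree plus the frequency of every accepted split.
    """
    labels = _check_leafsets(trees)
    reference = min(labels)
    freq = _split_frequencies(trees, weights, reference)
    accepted: dict[frozenset, float] = {c: f for c, f in freq.items() if f > 0.5}
    rest = sorted((c for c in freq if c not in accepted),
                  key=lambda c: (-freq[c], sorted(c)))
    for clade in rest:
        if _compatible(clade, accepted):
            accepted[clade] = freq[clade]
    tree = _build_from_clades(labels, accepted, reference)
    return tree, accepted
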