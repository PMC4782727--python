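"""Generalized (Sankoff) parsimony with step matrices.

Characters are scored by dynamic programming over the tree with an
arbitrary symmetric step matrix per character, which is what makes the
two weighting schemes for ordered morphoclines (full-step vs half-step
transitions through polymorphic intermediates) a one-line difference.
Tree search is heuristic: random stepwise addition followed by
hill-climbing over NNI and SPR neighborhoods, with an exhaustive
enumerator for small instances used by the test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import CharacterMatrix, build_step_matrix
from .trees import Tree, Node, bipartitions, strict_consensus, majority_rule_allcompat

__all__ = [
    "ParsimonyResult",
    "sankoff_score",
    "heuristic_search",
    "exhaustive_search",
    "consistency_indices",
    "bootstrap_support",
    "strict_consensus",
    "majority_rule_allcompat",
    "enumerate_topologies",
    "root_on_outgroup",
]

_INF = 1e18


@dataclass
class ParsimonyResult:
    best_score: float
    mpt_set: list[Tree]
    indices: dict = field(default_factory=dict)


class _SankoffData:
    """Per-character step matrices and leaf cost vectors, precomputed."""

    def __init__(self, matrix: CharacterMatrix, scheme: str = "equal"):
        if not matrix.is_recoded:
            raise ValueError("recode the matrix before scoring")
        self.matrix = matrix
        self.scheme = scheme
        self.taxon_index = {t: i for i, t in enumerate(matrix.taxa)}
        self.steps = [build_step_matrix(m, scheme).cost for m in matrix.char_meta]
        self.leaf_costs: list[np.ndarray] = []  # per char: (n_taxa, k)
        for j, meta in enumerate(matrix.char_meta):
            k = meta.n_states
            lc = np.full((matrix.n_taxa, k), _INF)
            for i, cell in enumerate(matrix.recoded_column(j)):
                if cell is None:
                    lc[i, :] = 0.0
                elif isinstance(cell, frozenset):
                    lc[i, list(cell)] = 0.0
                else:
                    lc[i, cell] = 0.0
            self.leaf_costs.append(lc)

    def score(self, tree: Tree, per_character: bool = False):
        order = list(tree.postorder())
        for leaf in tree.leaves():
            if leaf.label not in self.taxon_index:
                missing = sorted(set(tree.leaf_labels()) - set(self.taxon_index))
                extra = sorted(set(self.taxon_index) - set(tree.leaf_labels()))
                raise ValueError(f"tree/matrix taxon mismatch: tree-only={missing}, "
                                 f"matrix-only={extra}")
        scores = np.zeros(len(self.steps))
        for j, (cost, lc) in enumerate(zip(self.steps, self.leaf_costs)):
            vecs: dict[int, np.ndarray] = {}
            for node in order:
                if node.is_leaf:
                    vecs[id(node)] = lc[self.taxon_index[node.label]]
                else:
                    acc = None
                    for child in node.children:
                        cv = np.min(cost + vecs[id(child)][None, :], axis=1)
                        acc = cv if acc is None else acc + cv
                    vecs[id(node)] = acc
            scores[j] = vecs[id(order[-1])].min() if order else 0.0
        return scores if per_character else float(scores.sum())


def sankoff_score(tree: Tree, matrix: CharacterMatrix, scheme: str = "equal",
                  per_character: bool = False):
    """Total minimum-cost steps of ``matrix`` on ``tree`` under ``scheme``."""
    return _SankoffData(matrix, scheme).score(tree, per_character=per_character)


# ---------------------------------------------------------------------------
# topology manipulation (unrooted trees stored with a trifurcating root)
# ---------------------------------------------------------------------------

def _star(labels) -> Tree:
    root = Node()
    for lab in labels:
        root.add_child(Node(lab))
    return Tree(root)


def _edges(tree: Tree) -> list[Node]:
    """Every non-root node identifies the edge to its parent."""
    return [n for n in tree.postorder() if n.parent is not None]


def _insert_on_edge(child: Node, new_leaf_label: str) -> Node:
    """Split the edge above ``child`` and attach a new leaf; returns it."""
    parent = child.parent
    parent.children.remove(child)
    mid = parent.add_child(Node())
    mid.add_child(child)
    return mid.add_child(Node(new_leaf_label))


def _detach(tree: Tree, node: Node) -> None:
    """Remove ``node``'s subtree, suppressing the resulting unary node."""
    parent = node.parent
    parent.children.remove(node)
    node.parent = None
    if len(parent.children) == 1 and parent.parent is not None:
        only = parent.children[0]
        grand = parent.parent
        grand.children[grand.children.index(parent)] = only
        only.parent = grand
    elif len(parent.children) == 2 and parent.parent is None:
        # keep the root trifurcating: merge one internal child into the root
        for c in list(parent.children):
            if not c.is_leaf:
                parent.children.remove(c)
                for gc in list(c.children):
                    parent.add_child(gc)
                break


def _subtree_nodes(node: Node) -> set[int]:
    out, stack = set(), [node]
    while stack:
        n = stack.pop()
        out.add(id(n))
        stack.extend(n.children)
    return out


def _copy_with_map(tree: Tree) -> tuple[Tree, dict[int, Node]]:
    mapping: dict[int, Node] = {}

    def rec(node: Node) -> Node:
        new = Node(node.label)
        mapping[id(node)] = new
        for c in node.children:
            new.add_child(rec(c))
        return new

    return Tree(rec(tree.root)), mapping


def spr_neighbors(tree: Tree):
    """Yield all subtree-prune-regraft neighbors of an unrooted tree."""
    originals = _edges(tree)
    for prune in originals:
        forbidden = _subtree_nodes(prune)
        for target in originals:
            if id(target) in forbidden or target is prune:
                continue
            if target.parent is prune.parent and prune.parent is not None:
                continue  # regraft onto a sibling edge reproduces the tree
            new_tree, mapping = _copy_with_map(tree)
            p, t = mapping[id(prune)], mapping[id(target)]
            _detach(new_tree, p)
            # the target edge may have been dissolved by unary suppression;
            # regrafting there would reproduce the original tree anyway
            if t.parent is None or t not in t.parent.children:
                continue
            parent = t.parent
            parent.children.remove(t)
            mid = parent.add_child(Node())
            mid.add_child(t)
            mid.add_child(p)
            yield new_tree


def nni_neighbors(tree: Tree):
    """Yield nearest-neighbor-interchange neighbors across internal edges."""
    for v in _edges(tree):
        if v.is_leaf:
            continue
        p = v.parent
        siblings = [c for c in p.children if c is not v]
        for a in v.children:
            for b in siblings:
                new_tree, mapping = _copy_with_map(tree)
                na, nb = mapping[id(a)], mapping[id(b)]
                pa, pb = na.parent, nb.parent
                pa.children[pa.children.index(na)] = nb
                pb.children[pb.children.index(nb)] = na
                na.parent, nb.parent = pb, pa
                yield new_tree


def enumerate_topologies(labels: list[str]):
    """All distinct unrooted binary topologies over ``labels`` (<= 12 taxa)."""
    labels = list(labels)
    if len(labels) > 12:
        raise ValueError("exhaustive enumeration limited to 12 taxa")
    if len(labels) < 3:
        yield _star(labels)
        return

    def rec(tree: Tree, remaining: list[str]):
        if not remaining:
            yield tree.copy()
            return
        label = remaining[0]
        for edge_child in list(_edges(tree)):
            new_tree, mapping = _copy_with_map(tree)
            _insert_on_edge(mapping[id(edge_child)], label)
            yield from rec(new_tree, remaining[1:])

    yield from rec(_star(labels[:3]), labels[3:])


def _topology_key(tree: Tree) -> frozenset:
    return frozenset(bipartitions(tree)) | frozenset([frozenset(tree.leaf_labels())])


def exhaustive_search(matrix: CharacterMatrix, scheme: str = "equal") -> ParsimonyResult:
    data = _SankoffData(matrix, scheme)
    best, best_trees, seen = None, [], set()
    for tree in enumerate_topologies(sorted(matrix.taxa)):
        s = data.score(tree)
        if best is None or s < best - 1e-9:
            best, best_trees, seen = s, [tree], {_topology_key(tree)}
        elif abs(s - best) <= 1e-9:
            key = _topology_key(tree)
            if key not in seen:
                seen.add(key)
                best_trees.append(tree)
    return ParsimonyResult(best, best_trees)


def heuristic_search(matrix: CharacterMatrix, scheme: str = "equal",
                     n_reps: int = 10, seed: int | None = None,
                     use_spr: bool = True,
                     compute_indices: bool = True) -> ParsimonyResult:
    """Random-addition + NNI/SPR hill-climbing parsimony search.

    Retains every distinct optimal topology encountered (deduplicated by
    unrooted bipartition set).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    data = _SankoffData(matrix, scheme)
    taxa = list(matrix.taxa)
    best: float | None = None
    mpts: list[Tree] = []
    seen: set[frozenset] = set()

    def consider(tree: Tree, score: float) -> None:
        nonlocal best, mpts, seen
        if best is None or score < best - 1e-9:
            best, mpts, seen = score, [tree], {_topology_key(tree)}
        elif abs(score - best) <= 1e-9:
            key = _topology_key(tree)
            if key not in seen:
                seen.add(key)
                mpts.append(tree)

    for _ in range(n_reps):
        order = [taxa[i] for i in rng.permutation(len(taxa))]
        tree = _star(order[:3])
        for label in order[3:]:
            candidates = []
            for edge_child in list(_edges(tree)):
                cand, mapping = _copy_with_map(tree)
                _insert_on_edge(mapping[id(edge_child)], label)
                candidates.append((data.score(cand), cand))
            tree = min(candidates, key=lambda x: x[0])[1]
        score = data.score(tree)
        improved = True
        while improved:
            improved = False
            neighborhoods = [nni_neighbors(tree)]
            if use_spr:
                neighborhoods.append(spr_neighbors(tree))
            for neigh in neighborhoods:
                for cand in neigh:
                    s = data.score(cand)
                    consider(cand, s)
                    if s < score - 1e-9:
                        tree, score, improved = cand, s, True
                        break
                if improved:
                    break
        consider(tree, score)
    result = ParsimonyResult(best, mpts)
    if compute_indices:
        result.indices = consistency_indices(matrix, mpts[0], scheme)
    return result


# ---------------------------------------------------------------------------
# ensemble fit indices
# ---------------------------------------------------------------------------

def _min_conceivable(data: _SankoffData, j: int) -> float:
    """Minimum steps for character j on any tree (Steiner cost of observed states)."""
    cost = data.steps[j]
    observed = sorted({c for c in data.matrix.recoded_column(j)
                       if isinstance(c, (int, np.integer))})
    if len(observed) < 2:
        return 0.0
    meta = data.matrix.char_meta[j]
    if meta.ordered:
        return float(cost[observed[0], observed[-1]])
    return float(len(observed) - 1)


def _max_conceivable(data: _SankoffData, j: int) -> float:
    """Maximum steps: score of character j on the star tree."""
    lc = data.leaf_costs[j]
    cost = data.steps[j]
    per_state = np.array([np.min(cost[s][None, :] + lc, axis=1).sum()
                          for s in range(cost.shape[0])])
    return float(per_state.min())


def consistency_indices(matrix: CharacterMatrix, tree: Tree,
                        scheme: str = "equal") -> dict:
    """Ensemble CI (excluding uninformative characters), RI, and RCI."""
    data = _SankoffData(matrix, scheme)
    s = data.score(tree, per_character=True)
    m = np.array([_min_conceivable(data, j) for j in range(matrix.n_char)])
    g = np.array([_max_conceivable(data, j) for j in range(matrix.n_char)])
    info = np.array([meta.informative for meta in matrix.char_meta], dtype=bool)
    out: dict[str, float | None] = {}
    si, mi = s[info].sum(), m[info].sum()
    out["CI_excl"] = float(mi / si) if si > 0 else None
    denom = g.sum() - m.sum()
    out["RI"] = float((g.sum() - s.sum()) / denom) if denom > 0 else None
    out["RCI"] = (out["RI"] * float(m.sum() / s.sum())
                  if out["RI"] is not None and s.sum() > 0 else None)
    out["tree_length"] = float(s.sum())
    return out


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(matrix: CharacterMatrix, scheme: str = "equal",
                      n_pseudoreplicates: int = 100, seed: int | None = None,
                      n_reps_per_replicate: int = 10) -> dict[frozenset, float]:
    """Nonparametric bootstrap clade support (percent of replicate MPTs).

    Characters are resampled with replacement; each pseudoreplicate gets a
    reduced-effort search (random addition + NNI only).  Within a replicate
    a clade counts once if it occurs in the strict consensus of that
    replicate's optimal trees.
    """
    from .matrix import recode_polymorphisms

    if n_pseudoreplicates < 1:
        raise ValueError("n_pseudoreplicates must be >= 1")
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_pseudoreplicates):
        cols = rng.integers(0, matrix.n_char, size=matrix.n_char)
        cells = [[row[j] for j in cols] for row in matrix.cells]
        flags = [matrix.ordered_flags[j] for j in cols]
        boot = recode_polymorphisms(CharacterMatrix(matrix.taxa, cells, flags))
        res = heuristic_search(boot, scheme=scheme, n_reps=n_reps_per_replicate,
                               seed=int(rng.integers(2**31)), use_spr=False,
                               compute_indices=False)
        consensus = strict_consensus(res.mpt_set) if len(res.mpt_set) > 1 else res.mpt_set[0]
        for clade in bipartitions(consensus):
            counts[clade] = counts.get(clade, 0) + 1
    return {c: 100.0 * n / n_pseudoreplicates for c, n in counts.items()}


def root_on_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Return a copy rooted on the edge leading to the outgroup leaf."""
    nodes = list(tree.postorder())
    adj: dict[int, list[int]] = {id(n): [] for n in nodes}
    byid = {id(n): n for n in nodes}
    for n in nodes:
        if n.parent is not None:
            adj[id(n)].append(id(n.parent))
            adj[id(n.parent)].append(id(n))
    leaf = next(n for n in nodes if n.label == outgroup)

    def build(src_id: int, avoid_id: int) -> Node:
        src = byid[src_id]
        neighbors = [o for o in adj[src_id] if o != avoid_id]
        if not neighbors:
            return Node(src.label)
        if len(neighbors) == 1 and src.label is None:
            return build(neighbors[0], src_id)  # suppress degree-2 old root
        new = Node(src.label)
        for other in neighbors:
            new.add_child(build(other, src_id))
        return new

    new_root = Node()
    new_root.add_child(Node(outgroup))
    new_root.add_child(build(adj[id(leaf)][0], id(leaf)))
    return Tree(new_root)
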