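"""Truth-annotated synthetic data: FBD trees, Mk characters, BM traits.

The generator is the package's test bench: it draws a time tree from a
forward birth-death process with Poisson fossil sampling along
lineages, evolves ordered/unordered morphological characters under the
Mk model with a relaxed clock and gamma rate variation, filters to
variable characters (emulating how morphological matrices are built),
injects adjacent-state polymorphic scorings, and wraps everything with
calibration windows, locality maps, Brownian-motion traits, and a truth
record, so that every downstream stage can be checked against known
parameter values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .matrix import (Cell, CharacterMatrix, CalibrationTable, STATE, POLY,
                     recode_polymorphisms)
from .mk import transition_matrices
from .trees import Node, Tree

__all__ = [
    "TruthRecord",
    "simulate_fbd_tree",
    "simulate_characters",
    "make_calibrations",
    "assign_localities",
    "simulate_bm_traits",
    "paperlike_dataset",
]


@dataclass
class TruthRecord:
    """Everything the generator knows; written alongside the fixtures."""

    seed: int
    params: dict = field(default_factory=dict)
    tip_ages: dict = field(default_factory=dict)
    branch_rates: dict = field(default_factory=dict)
    trait_params: dict = field(default_factory=dict)
    ancestral_traits: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {"seed": self.seed, "params": self.params,
                   "tip_ages": self.tip_ages,
                   "branch_rates": {"|".join(sorted(k)) if isinstance(k, frozenset)
                                    else k: v for k, v in self.branch_rates.items()},
                   "trait_params": self.trait_params,
                   "ancestral_traits": {"|".join(sorted(k)) if isinstance(k, frozenset)
                                        else k: v
                                        for k, v in self.ancestral_traits.items()}}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# FBD tree simulation
# ---------------------------------------------------------------------------

class _Lineage:
    __slots__ = ("parent", "birth", "end", "fate", "children", "fossils")

    def __init__(self, parent, birth):
        self.parent = parent
        self.birth = birth       # age (Ma) at which the lineage starts
        self.end = None          # age at which it ends
        self.fate = None         # 'birth' | 'death' | 'present'
        self.children = []
        self.fossils = []        # fossil-sampling ages along the lineage


def simulate_fbd_tree(lam: float, mu: float, psi: float, rho: float,
                      origin_age: float, seed: int, min_tips: int = 3,
                      max_tries: int = 2000) -> Tree:
    """Forward-simulate a sampled tree under the fossil-tip FBD process.

    Fossils are Poisson(psi) events along lineages; a sampled fossil
    truncates its lineage, so every fossil is a terminal tip by
    construction (fossil-tip semantics).  Extant survivors at the
    present are retained with probability rho; lineages leaving no
    samples are pruned and unary nodes suppressed.  Trees with fewer
    than ``min_tips`` samples are rejected and re-simulated.
    """
    if not (lam > mu >= 0):
        raise ValueError("need lambda > mu >= 0")
    if psi < 0 or not (0 < rho <= 1) or origin_age <= 0:
        raise ValueError("bad FBD simulation parameters")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        tree = _try_simulate(lam, mu, psi, rho, origin_age, rng, min_tips)
        if tree is not None:
            return tree
    raise RuntimeError(f"no acceptable tree in {max_tries} tries; "
                       "parameters may be too extreme")


def _try_simulate(lam, mu, psi, rho, origin_age, rng, min_tips):
    total = lam + mu + psi
    root_lineage = _Lineage(None, origin_age)
    active = [root_lineage]
    all_lineages = [root_lineage]
    while active:
        lin = active.pop()
        t = lin.birth
        while True:
            t -= rng.exponential(1.0 / total) if total > 0 else np.inf
            if t <= 0:
                lin.end, lin.fate = 0.0, "present"
                break
            u = rng.random() * total
            if u < lam:
                lin.end, lin.fate = t, "birth"
                for _ in range(2):
                    child = _Lineage(lin, t)
                    lin.children.append(child)
                    active.append(child)
                    all_lineages.append(child)
                break
            if u < lam + mu:
                lin.end, lin.fate = t, "death"
                break
            lin.end, lin.fate = t, "fossil"
            lin.fossils.append(t)
            break
        if len(all_lineages) > 100000:
            return None  # runaway clade; treat as a failed draw
    # sampling
    sampled_extant = {id(l) for l in all_lineages
                      if l.fate == "present" and rng.random() < rho}

    # prune to sampled tree
    counter = [0]

    def build(lin: _Lineage):
        if lin.fossils:
            counter[0] += 1
            return Node(label=f"F{counter[0]}", age=lin.fossils[0])
        if lin.fate == "present" and id(lin) in sampled_extant:
            counter[0] += 1
            return Node(label=f"E{counter[0]}", age=0.0)
        if lin.fate == "birth":
            kids = [build(c) for c in lin.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            node = Node(age=lin.end)
            for k in kids:
                node.add_child(k)
            return node
        return None

    root = build(root_lineage)
    if root is None or (root.is_leaf and min_tips > 1):
        return None
    tree = Tree(root)
    if len(tree.leaves()) < min_tips:
        return None
    tree.set_lengths_from_ages()
    return tree


# ---------------------------------------------------------------------------
# character simulation
# ---------------------------------------------------------------------------

def simulate_characters(tree: Tree, c: float, sigma2: float, n_char: int,
                        frac_ordered: float, k_distribution: dict[int, float],
                        alpha: float, polymorphism_rate: float,
                        seed: int) -> tuple[CharacterMatrix, dict]:
    """Evolve ``n_char`` variable characters on a time tree.

    Branch effective lengths follow the IGR law (gamma with mean c*t and
    variance sigma2*c*t; sigma2=0 is a strict clock); each character gets
    a gamma(alpha) rate multiplier (alpha=inf means none); constant
    characters are redrawn so the output emulates variable coding.
    Ordered-character tip states become adjacent polymorphisms with
    probability ``polymorphism_rate``.  Returns the recoded matrix and a
    dict of the realized branch effective lengths keyed by tip-set.
    """
    rng = np.random.default_rng(seed)
    nodes = list(tree.postorder())
    idx = {id(n): i for i, n in enumerate(nodes)}
    taxa = [n.label for n in nodes if n.is_leaf]
    # branch effective lengths
    v = np.zeros(len(nodes))
    below: dict[int, frozenset] = {}
    for i, n in enumerate(nodes):
        below[i] = (frozenset([n.label]) if n.is_leaf else
                    frozenset().union(*(below[idx[id(ch)]] for ch in n.children)))
        if n.parent is None:
            continue
        t = n.parent.age - n.age
        if t <= 0:
            raise ValueError("tree must have strictly positive branch durations")
        if sigma2 == 0:
            v[i] = c * t
        else:
            shape = c * t / sigma2
            v[i] = rng.gamma(shape, sigma2)
    ks = np.array(sorted(k_distribution))
    kp = np.array([k_distribution[k] for k in ks], dtype=float)
    kp = kp / kp.sum()
    cells: list[list[Cell]] = [[] for _ in taxa]
    flags: list[bool] = []
    taxon_pos = {lab: i for i, lab in enumerate(taxa)}
    made = 0
    while made < n_char:
        k = int(rng.choice(ks, p=kp))
        ordered = bool(rng.random() < frac_ordered)
        g = 1.0 if np.isinf(alpha) else rng.gamma(alpha, 1.0 / alpha)
        states = np.zeros(len(nodes), dtype=int)
        states[-1] = rng.integers(k)
        for i in reversed(range(len(nodes) - 1)):  # preorder below root
            p = idx[id(nodes[i].parent)]
            P = transition_matrices(k, ordered, np.array([v[i] * g]))[0]
            states[i] = rng.choice(k, p=P[states[p]] / P[states[p]].sum())
        tip_states = {n.label: states[i] for i, n in enumerate(nodes) if n.is_leaf}
        if len(set(tip_states.values())) < 2:
            continue
        for lab, s in tip_states.items():
            cell = Cell(STATE, (int(s),))
            if ordered and rng.random() < polymorphism_rate:
                if s + 1 < k and (s == 0 or rng.random() < 0.5):
                    cell = Cell(POLY, (int(s), int(s + 1)))
                elif s > 0:
                    cell = Cell(POLY, (int(s - 1), int(s)))
            cells[taxon_pos[lab]].append(cell)
        flags.append(ordered)
        made += 1
    matrix = recode_polymorphisms(CharacterMatrix(taxa, cells, flags))
    true_v = {below[i]: float(v[i]) for i in range(len(nodes) - 1)}
    return matrix, true_v


# ---------------------------------------------------------------------------
# calibrations, localities, traits
# ---------------------------------------------------------------------------

def make_calibrations(true_tip_ages: dict[str, float], window_width: float,
                      jitter: float, seed: int,
                      locality_map: dict[str, str] | None = None
                      ) -> CalibrationTable:
    """Uniform windows guaranteed to contain each fossil tip's true age.

    jitter=0 centers the window on the truth; jitter in (0, 1] shifts the
    center by up to jitter*width/2 while keeping the truth inside.
    Extant tips (age 0) are fixed at 0.
    """
    if window_width <= 0:
        raise ValueError("window width must be positive")
    rng = np.random.default_rng(seed)
    entries = {}
    for tip, age in true_tip_ages.items():
        loc = locality_map.get(tip) if locality_map else None
        if age <= 1e-9:
            entries[tip] = {"kind": "fixed", "fixed_age": 0.0, "locality": loc}
            continue
        offset = jitter * (window_width / 2.0) * rng.uniform(-1.0, 1.0)
        lo = max(0.0, age - window_width / 2.0 + offset)
        entries[tip] = {"kind": "uniform", "min_age": lo,
                        "max_age": lo + window_width, "locality": loc}
        assert lo - 1e-9 <= age <= lo + window_width + 1e-9
    return CalibrationTable(entries)


def assign_localities(true_tip_ages: dict[str, float], n_localities: int,
                      seed: int) -> dict[str, str]:
    """Group fossil tips of similar true age into named localities."""
    fossil = sorted((t for t, a in true_tip_ages.items() if a > 1e-9),
                    key=lambda t: true_tip_ages[t])
    n_localities = max(1, min(n_localities, len(fossil)))
    out: dict[str, str] = {}
    splits = np.array_split(np.arange(len(fossil)), n_localities)
    for li, chunk in enumerate(splits):
        for i in chunk:
            out[fossil[i]] = f"LOC{li + 1}"
    for tip, age in true_tip_ages.items():
        if age <= 1e-9:
            out[tip] = "RECENT"
    return out


def simulate_bm_traits(tree: Tree, alpha0: float, sigma2_bm: float,
                       lambda_scale: float, beta: float, seed: int
                       ) -> tuple[dict[str, float], dict[frozenset, float]]:
    """Exact multivariate-normal draw of tip and ancestral trait values."""
    from .traits import _TreeStructure
    if sigma2_bm < 0:
        raise ValueError("sigma2_bm must be non-negative")
    rng = np.random.default_rng(seed)
    st = _TreeStructure(tree)
    d = st.transformed_depth("lambda", lambda_scale)
    C = d[st.mrca].copy()
    np.fill_diagonal(C, d)
    mean = alpha0 + beta * st.transformed_depth("none", 1.0)
    if sigma2_bm == 0:
        x = mean
    else:
        vals, vecs = np.linalg.eigh(sigma2_bm * C)
        vals = np.clip(vals, 0.0, None)
        x = mean + vecs @ (np.sqrt(vals) * rng.standard_normal(st.n))
    below: dict[int, frozenset] = {}
    for i, node in enumerate(st.nodes):
        below[i] = (frozenset([node.label]) if st.is_leaf[i] else
                    frozenset().union(*(below[st.idx[id(c)]]
                                        for c in node.children)))
    tips = {st.labels[i]: float(x[i]) for i in st.leaf_order}
    ancestors = {below[i]: float(x[i]) for i in range(st.n) if not st.is_leaf[i]}
    return tips, ancestors


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def paperlike_dataset(seed: int, n_char: int = 118, target_tips: int = 40):
    """A fixture shaped like the study data: ~40 taxa (one extant),
    n_char variable characters (~65% ordered, 2-4 states), uniform
    calibration windows, localities, and BM traits; returns
    (matrix, tree, calibrations, locality_map, traits, truth)."""
    params = {"lam": 0.25, "mu": 0.18, "psi": 0.06, "rho": 0.02,
              "origin_age": 50.0, "c": 0.25, "sigma2": 0.05,
              "alpha": 1.0, "frac_ordered": 0.65,
              "polymorphism_rate": 0.03,
              "trait_alpha0": 1.0, "trait_sigma2": 0.05,
              "trait_lambda": 0.9, "trait_beta": 0.0}
    rng = np.random.default_rng(seed)
    tree = None
    for _ in range(400):
        cand = simulate_fbd_tree(params["lam"], params["mu"], params["psi"],
                                 params["rho"], params["origin_age"],
                                 int(rng.integers(2**31)), min_tips=8)
        if abs(len(cand.leaves()) - target_tips) <= max(6, target_tips // 3):
            tree = cand
            break
    if tree is None:
        raise RuntimeError("could not hit the target tree size")
    matrix, true_v = simulate_characters(
        tree, params["c"], params["sigma2"], n_char, params["frac_ordered"],
        {2: 0.5, 3: 0.3, 4: 0.2}, params["alpha"],
        params["polymorphism_rate"], int(rng.integers(2**31)))
    tip_ages = {n.label: float(n.age) for n in tree.leaves()}
    locality_map = assign_localities(tip_ages, max(3, target_tips // 5),
                                     int(rng.integers(2**31)))
    calibrations = make_calibrations(tip_ages, window_width=12.0, jitter=0.5,
                                     seed=int(rng.integers(2**31)),
                                     locality_map=locality_map)
    traits, ancestors = simulate_bm_traits(tree, params["trait_alpha0"],
                                           params["trait_sigma2"],
                                           params["trait_lambda"],
                                           params["trait_beta"],
                                           int(rng.integers(2**31)))
    truth = TruthRecord(seed=seed, params=params, tip_ages=tip_ages,
                        branch_rates=true_v,
                        trait_params={k: v for k, v in params.items()
                                      if k.startswith("trait_")},
                        ancestral_traits=ancestors)
    return matrix, tree, calibrations, locality_map, traits, truth
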