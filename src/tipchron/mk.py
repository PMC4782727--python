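"""Mk likelihood for morphological characters.

The Mk model is a k-state continuous-time Markov chain with uniform
stationary distribution; unordered characters allow any state-to-state
change, ordered characters only steps between adjacent positions on the
recoded morphocline.  Rate matrices are normalized to one expected
change per unit branch length so branch lengths are in expected-changes
units.  Among-character rate variation uses the discrete-gamma mixture
(equal-probability categories, category means), and the "variable"
ascertainment correction conditions each character's likelihood on
being non-constant, which is how morphological matrices are collected.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .matrix import CharacterMatrix
from .trees import Tree

__all__ = [
    "MkModel",
    "RateMatrix",
    "rate_matrix",
    "discrete_gamma",
    "TopologyIndex",
    "MkLikelihood",
    "pruning_loglik",
]


@dataclass
class MkModel:
    """Shared Mk settings: gamma shape, category count, ascertainment coding."""

    gamma_shape: float = 1.0
    n_gamma_categories: int = 4
    coding: str = "variable"  # or "all"

    def __post_init__(self):
        if self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.coding not in ("variable", "all"):
            raise ValueError(f"unknown coding {self.coding!r}")


@dataclass
class RateMatrix:
    Q: np.ndarray
    pi: np.ndarray


def rate_matrix(k: int, ordered: bool) -> RateMatrix:
    """Mean-rate-1 normalized Mk rate matrix with uniform stationarity."""
    if k < 2:
        raise ValueError("need at least 2 states")
    if ordered:
        beta = k / (2.0 * (k - 1))
        Q = np.zeros((k, k))
        for i in range(k - 1):
            Q[i, i + 1] = Q[i + 1, i] = beta
    else:
        Q = np.full((k, k), 1.0 / (k - 1))
        np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return RateMatrix(Q, np.full(k, 1.0 / k))


@lru_cache(maxsize=64)
def _eigen(k: int, ordered: bool):
    Q = rate_matrix(k, ordered).Q
    w, U = np.linalg.eigh(Q)  # symmetric under uniform pi
    return w, U


def transition_matrices(k: int, ordered: bool, lengths: np.ndarray) -> np.ndarray:
    """P(t) for each t in ``lengths`` via the cached spectral decomposition."""
    w, U = _eigen(k, ordered)
    t = np.asarray(lengths, dtype=float)
    ew = np.exp(np.multiply.outer(t, w))  # (..., k)
    P = (U * ew[..., None, :]) @ U.T
    return np.maximum(P, 0.0, out=P)


@lru_cache(maxsize=1024)
def _discrete_gamma_cached(alpha: float, ncat: int) -> np.ndarray:
    probs = np.arange(1, ncat) / ncat
    bounds = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([gammainc(alpha + 1, alpha * bounds), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1, alpha * bounds)])
    out = ncat * (upper - lower)
    out.setflags(write=False)
    return out


def discrete_gamma(alpha: float, ncat: int) -> np.ndarray:
    """Equal-probability discrete-gamma category rates (category means)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if ncat < 1:
        raise ValueError("ncat must be >= 1")
    if ncat == 1:
        return np.ones(1)
    return _discrete_gamma_cached(float(alpha), int(ncat))


class TopologyIndex:
    """Array view of a fixed topology: postorder node list + children."""

    def __init__(self, tree: Tree):
        self.nodes = list(tree.postorder())
        self.id2idx = {id(n): i for i, n in enumerate(self.nodes)}
        self.n_nodes = len(self.nodes)
        self.root = self.n_nodes - 1
        self.children = [[self.id2idx[id(c)] for c in n.children]
                         for n in self.nodes]
        self.parent = np.full(self.n_nodes, -1)
        for i, kids in enumerate(self.children):
            for c in kids:
                self.parent[c] = i
        self.is_leaf = np.array([n.is_leaf for n in self.nodes])
        self.leaf_label = {i: n.label for i, n in enumerate(self.nodes) if n.is_leaf}

    def branch_durations(self, ages: np.ndarray) -> np.ndarray:
        """Parent age minus node age per node (root entry is 0)."""
        t = np.zeros(self.n_nodes)
        mask = self.parent >= 0
        t[mask] = ages[self.parent[mask]] - ages[np.where(mask)[0]]
        return t


class MkLikelihood:
    """Pruning likelihood of a recoded matrix on a fixed topology.

    Characters are grouped by (state count, ordered) so transition
    matrices are shared within a group; evaluation takes a vector of
    effective branch lengths indexed like ``TopologyIndex.nodes``.
    Per-character log-scaling keeps deep trees stable.
    """

    def __init__(self, matrix: CharacterMatrix, topology: Tree | TopologyIndex,
                 model: MkModel | None = None):
        if not matrix.is_recoded:
            raise ValueError("recode the matrix before computing likelihoods")
        self.matrix = matrix
        self.model = model or MkModel()
        self.top = topology if isinstance(topology, TopologyIndex) else TopologyIndex(topology)
        labels = {self.top.leaf_label[i] for i in self.top.leaf_label}
        if labels != set(matrix.taxa):
            raise ValueError("tree leaves do not match matrix taxa: "
                             f"{sorted(labels ^ set(matrix.taxa))}")
        taxon_row = {t: i for i, t in enumerate(matrix.taxa)}
        groups: dict[tuple[int, bool], list[int]] = {}
        for j, meta in enumerate(matrix.char_meta):
            if meta.n_states < 2:
                continue  # constant-state-space characters carry no signal
            groups.setdefault((meta.n_states, meta.ordered), []).append(j)
        self.groups = []
        for (k, ordered), chars in sorted(groups.items()):
            tips = {}
            for i, lab in self.top.leaf_label.items():
                row = taxon_row[lab]
                L = np.zeros((len(chars), k))
                for cj, j in enumerate(chars):
                    cell = matrix.recoded[row][j]
                    if cell is None:
                        L[cj, :] = 1.0
                    elif isinstance(cell, frozenset):
                        L[cj, list(cell)] = 1.0
                    else:
                        L[cj, cell] = 1.0
                tips[i] = L
            self.groups.append({"k": k, "ordered": ordered, "chars": chars,
                                "tips": tips})
        self.n_char_scored = sum(len(g["chars"]) for g in self.groups)

    # -- core pruning -----------------------------------------------------
    def _group_site_logliks(self, group: dict, v: np.ndarray,
                            rates: np.ndarray, extra_const: bool):
        """Per-character site log-likelihoods for one (k, ordered) group.

        With ``extra_const`` the k all-constant patterns are appended as
        pseudo-characters so the ascertainment term reuses the same pass.
        """
        k, top = group["k"], self.top
        ncat = len(rates)
        nchar = len(group["chars"]) + (k if extra_const else 0)
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros(nchar)
        Ps: dict[int, np.ndarray] = {}
        for i in range(top.n_nodes - 1):
            Ps[i] = transition_matrices(k, group["ordered"], v[i] * rates)
        for i in range(top.n_nodes):
            if top.is_leaf[i]:
                L = group["tips"][i]
                if extra_const:
                    L = np.vstack([L, np.eye(k)])
                partial[i] = np.broadcast_to(L, (ncat,) + L.shape)
            else:
                acc = np.ones((ncat, nchar, k))
                for c in top.children[i]:
                    acc = acc * np.einsum("cij,cnj->cni", Ps[c], partial[c])
                    del partial[c]
                scale = acc.max(axis=(0, 2))
                scale[scale <= 0] = 1.0
                logscale += np.log(scale)
                partial[i] = acc / scale[None, :, None]
        site = partial[top.root].sum(axis=2).mean(axis=0) / k  # uniform pi
        return np.log(np.clip(site, 1e-300, None)) + logscale, site, logscale

    def loglik(self, v: np.ndarray, gamma_shape: float | None = None,
               per_character: bool = False):
        """Total (or per-character) log-likelihood at effective lengths ``v``.

        ``v[i]`` is the expected number of changes per character on the
        branch above postorder node i; the root entry is ignored.
        """
        v = np.asarray(v, dtype=float)
        if np.any(v[:-1] < 0):
            raise ValueError("negative effective branch length")
        alpha = self.model.gamma_shape if gamma_shape is None else gamma_shape
        rates = discrete_gamma(alpha, self.model.n_gamma_categories)
        correct = self.model.coding == "variable"
        out = np.zeros(self.n_char_scored)
        pos = 0
        for group in self.groups:
            n = len(group["chars"])
            logL, site, logscale = self._group_site_logliks(group, v, rates, correct)
            if correct:
                const_log = logL[n:]
                p_const = np.exp(const_log).sum()
                if p_const >= 1.0 - 1e-12:
                    raise FloatingPointError(
                        "variable-coding correction undefined: constant-pattern "
                        f"probability {p_const:.6g} >= 1 (degenerate tree)")
                out[pos:pos + n] = logL[:n] - np.log1p(-p_const)
            else:
                out[pos:pos + n] = logL[:n]
            pos += n
        return out if per_character else float(out.sum())

    def constant_pattern_probability(self, v: np.ndarray,
                                     gamma_shape: float | None = None) -> dict:
        """Per-group total probability of an all-constant pattern."""
        alpha = self.model.gamma_shape if gamma_shape is None else gamma_shape
        rates = discrete_gamma(alpha, self.model.n_gamma_categories)
        out = {}
        for group in self.groups:
            n = len(group["chars"])
            logL, _, _ = self._group_site_logliks(group, np.asarray(v, float),
                                                  rates, True)
            out[(group["k"], group["ordered"])] = float(np.exp(logL[n:]).sum())
        return out


class PruningCache:
    """Incremental re-evaluation of the pruning likelihood.

    MCMC moves usually touch one effective branch length, which only
    invalidates the partial likelihoods on the path from that branch to
    the root.  The cache keeps per-node partials (with the constant
    patterns appended when variable coding is on) and recomputes just the
    dirty path, with accept/reject bookkeeping.
    """

    def __init__(self, lik: MkLikelihood):
        self.lik = lik
        self.top = lik.top
        self.correct = lik.model.coding == "variable"
        self.ncat = lik.model.n_gamma_categories
        self._P: list[dict[int, np.ndarray]] = [dict() for _ in lik.groups]
        self._partial: list[dict[int, np.ndarray]] = [dict() for _ in lik.groups]
        self._scalelog: list[dict[int, np.ndarray]] = [dict() for _ in lik.groups]
        self._backup: list[tuple] | None = None
        self._loglik: float | None = None
        self._tips: list[dict[int, np.ndarray]] = []
        for g in lik.groups:
            k, n = g["k"], len(g["chars"])
            tips = {}
            for i, L in g["tips"].items():
                full = np.vstack([L, np.eye(k)]) if self.correct else L
                tips[i] = np.broadcast_to(full, (self.ncat,) + full.shape)
            self._tips.append(tips)

    def _recompute_node(self, gi: int, group: dict, i: int, v: np.ndarray,
                        rates: np.ndarray, dirty_P: set[int]) -> None:
        top = self.top
        k = group["k"]
        acc = None
        for c in top.children[i]:
            if c in dirty_P or c not in self._P[gi]:
                self._P[gi][c] = transition_matrices(k, group["ordered"],
                                                     v[c] * rates)
            child = (self._tips[gi][c] if top.is_leaf[c]
                     else self._partial[gi][c])
            term = child @ self._P[gi][c].transpose(0, 2, 1)
            acc = term if acc is None else acc * term
        scale = acc.max(axis=(0, 2))
        scale[scale <= 0] = 1.0
        old = self._scalelog[gi].get(i)
        if old is not None:
            self._scalesum[gi] = self._scalesum[gi] - old
        new_log = np.log(scale)
        self._partial[gi][i] = acc / scale[None, :, None]
        self._scalelog[gi][i] = new_log
        self._scalesum[gi] = self._scalesum[gi] + new_log

    def _root_loglik(self) -> float:
        total = 0.0
        for gi, group in enumerate(self.lik.groups):
            k, n = group["k"], len(group["chars"])
            site = self._partial[gi][self.top.root].sum(axis=2).mean(axis=0) / k
            logL = np.log(np.maximum(site, 1e-300)) + self._scalesum[gi]
            if self.correct:
                p_const = np.exp(logL[n:]).sum()
                if p_const >= 1.0 - 1e-12:
                    raise FloatingPointError("constant-pattern probability >= 1")
                total += float(logL[:n].sum() - n * np.log1p(-p_const))
            else:
                total += float(logL[:n].sum())
        return total

    def full(self, v: np.ndarray, gamma_shape: float) -> float:
        rates = discrete_gamma(gamma_shape, self.ncat)
        self._scalesum = []
        for gi, group in enumerate(self.lik.groups):
            nchar = len(group["chars"]) + (group["k"] if self.correct else 0)
            self._P[gi].clear()
            self._partial[gi].clear()
            self._scalelog[gi].clear()
            self._scalesum.append(np.zeros(nchar))
            for i in range(self.top.n_nodes):
                if not self.top.is_leaf[i]:
                    self._recompute_node(gi, group, i, v, rates,
                                         set(self.top.children[i]))
        self._backup = None
        self._loglik = self._root_loglik()
        return self._loglik

    def propose(self, v: np.ndarray, gamma_shape: float,
                changed: list[int]) -> float:
        """Re-evaluate after changing v on ``changed`` branches (node ids).

        ``full`` must have been called once first; call ``accept`` or
        ``reject`` before the next proposal.
        """
        rates = discrete_gamma(gamma_shape, self.ncat)
        dirty_P = set(changed)
        seen: set[int] = set()
        for i in changed:  # ancestors of the branch above node i
            a = int(self.top.parent[i])
            while a >= 0 and a not in seen:
                seen.add(a)
                a = int(self.top.parent[a])
        dirty_nodes = sorted(seen)  # postorder index order = children first
        backup = []
        for gi, group in enumerate(self.lik.groups):
            backup.append(("scalesum", gi, self._scalesum[gi]))
            for i in dirty_nodes:
                backup.append(("node", gi, i, self._partial[gi][i],
                               self._scalelog[gi][i]))
            for c in dirty_P:
                backup.append(("P", gi, c, self._P[gi][c]))
            for i in dirty_nodes:
                self._recompute_node(gi, group, i, v, rates, dirty_P)
        self._backup = backup
        new = self._root_loglik()
        self._pending_loglik = new
        return new

    def accept(self) -> None:
        self._backup = None
        self._loglik = self._pending_loglik

    def reject(self) -> None:
        if self._backup is None:
            return
        for entry in self._backup:
            if entry[0] == "scalesum":
                self._scalesum[entry[1]] = entry[2]
            elif entry[0] == "node":
                _, gi, i, partial, scalelog = entry
                self._partial[gi][i] = partial
                self._scalelog[gi][i] = scalelog
            else:
                _, gi, c, P = entry
                self._P[gi][c] = P
        self._backup = None


def pruning_loglik(tree: Tree, matrix: CharacterMatrix,
                   model: MkModel | None = None,
                   per_character: bool = False):
    """Likelihood of ``matrix`` on ``tree`` with ``node.length`` as
    effective branch lengths (expected changes per character)."""
    lik = MkLikelihood(matrix, tree, model)
    v = np.array([n.length if n.length is not None else 0.0
                  for n in lik.top.nodes])
    return lik.loglik(v, per_character=per_character)
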