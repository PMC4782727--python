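"""Metropolis-coupled MCMC over time trees, tip ages, and clock parameters.

One "generation" here is a full sweep: every fossil tip age, every
internal node age, every branch effective length, and each scalar
parameter receives one Metropolis-Hastings proposal, and coupled chains
attempt one state swap.  The target in tip-dating mode is

    Mkv likelihood x FBD tree prior x IGR branch-length prior x hyperpriors,

with topology fixed by default (node-age moves only); time-tree NNI
moves can be enabled.  Non-clock mode drops the time machinery and puts
independent exponential priors on branch effective lengths.  The
likelihood and the tree prior can each be switched off, which turns the
sampler into a prior sampler — the standard correctness check that the
proposal ratios are right.

The posterior pieces are maintained incrementally: a branch-length move
touches one IGR term and a partial pruning update; an age move touches
the FBD density and the adjacent IGR terms; only the gamma-shape move
pays for a full likelihood re-evaluation.  Prior terms that are
constant in the state (calibration-window widths) are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .matrix import CharacterMatrix, CalibrationTable
from .mk import MkLikelihood, MkModel, PruningCache, TopologyIndex
from .priors import FBDParams, PriorSet, fbd_log_density_times
from .trees import Tree, Node

__all__ = [
    "ChainConfig",
    "TreeSample",
    "MCMCOutput",
    "PosteriorSummary",
    "run_mcmc",
    "summarize",
    "diagnostics",
    "hpd_interval",
    "effective_sample_size",
    "potential_scale_reduction",
    "asdsf",
]

_FOSSIL_TOL = 1e-9


@dataclass
class ChainConfig:
    """Sampler settings (scaled-down defaults; the classic large-run values
    are accepted via the same fields)."""

    n_generations: int = 2000
    n_runs: int = 2
    n_chains: int = 2
    temp: float = 0.1
    sample_frequency: int = 2
    burn_in: float = 0.25
    mode: str = "tipdating"           # or "nonclock"
    likelihood: bool = True
    tree_prior: bool = True
    topology_moves: bool = False
    fossil_removal: bool = False
    n_gamma_categories: int = 4

    def heat(self, i: int) -> float:
        return 1.0 / (1.0 + self.temp * i)


@dataclass
class TreeSample:
    """One posterior draw, reduced to what summaries need."""

    clade_ages: dict[frozenset, float]     # internal clades -> node age
    tip_ages: dict[str, float]
    branch_ratio: dict[frozenset, float]   # clade/tip key -> v_b/(c*t_b)
    root_age: float


@dataclass
class MCMCOutput:
    traces: list[pd.DataFrame]
    tree_samples: list[list[TreeSample]]
    config: ChainConfig
    topology: Tree


# ---------------------------------------------------------------------------
# chain
# ---------------------------------------------------------------------------

class _Chain:
    """One (possibly heated) chain with incrementally maintained target.

    Components: ``lnL`` (pruning cache), ``fbd`` (tree prior),
    ``igr`` (per-branch clock prior terms, or exponential terms in
    non-clock mode), ``lnp_params`` (scalar-parameter hyperpriors).
    """

    def __init__(self, top: TopologyIndex, lik: MkLikelihood | None,
                 calibrations: CalibrationTable, priors: PriorSet,
                 config: ChainConfig, rng: np.random.Generator, beta: float):
        self.top = top
        self.calibrations = calibrations
        self.priors = priors
        self.config = config
        self.rng = rng
        self.beta = beta
        self.lik = lik
        self.cache = PruningCache(lik) if (lik and config.likelihood) else None
        self._index_tips()
        self._init_state()
        self._recompute_all()
        if not np.isfinite(self.log_posterior):
            raise RuntimeError("initial state has zero posterior density")

    def _index_tips(self) -> None:
        top, cal = self.top, self.calibrations
        self.tip_lo = np.zeros(top.n_nodes)
        self.tip_hi = np.zeros(top.n_nodes)
        self.movable_tips = []
        self.fossil_tips = []
        for i, lab in top.leaf_label.items():
            if lab in cal:
                lo, hi = cal.bounds(lab)
            else:
                lo = hi = 0.0
            self.tip_lo[i], self.tip_hi[i] = lo, hi
            if hi > lo:
                self.movable_tips.append(i)
            if hi > _FOSSIL_TOL:
                self.fossil_tips.append(i)
        self.internal = [i for i in range(top.n_nodes) if not top.is_leaf[i]]

    # -- state ------------------------------------------------------------
    def _init_state(self) -> None:
        top, rng = self.top, self.rng
        self.children = [list(c) for c in top.children]
        self.parent = top.parent.copy()
        ages = np.zeros(top.n_nodes)
        for i in self.fossil_tips + self.movable_tips:
            lo, hi = self.tip_lo[i], self.tip_hi[i]
            ages[i] = lo if hi == lo else rng.uniform(lo, hi)
        for i, lab in top.leaf_label.items():
            if self.tip_hi[i] == self.tip_lo[i]:
                ages[i] = self.tip_lo[i]
        min_allowed = np.zeros(top.n_nodes)
        for i in range(top.n_nodes):
            min_allowed[i] = (ages[i] if top.is_leaf[i] else
                              max(min_allowed[c] for c in top.children[i]))
        root_lo = max(self.priors.root_min, min_allowed[top.root] + 1e-6)
        if root_lo >= self.priors.root_max:
            raise RuntimeError(
                "no valid initial state: oldest tip constraint "
                f"{min_allowed[top.root]:.3f} Ma conflicts with the root age "
                f"window ({self.priors.root_min}, {self.priors.root_max})")
        ages[top.root] = rng.uniform(root_lo, self.priors.root_max)
        for i in reversed(range(top.n_nodes)):  # preorder below the root
            if top.is_leaf[i] or i == top.root:
                continue
            hi, lo = ages[self.parent[i]], min_allowed[i]
            ages[i] = rng.uniform(lo + 0.4 * (hi - lo), hi) if hi > lo else lo
        self.ages = ages
        self.d = 1.0 / self.priors.speciation_rate
        self.r = 0.5
        self.s = 0.5
        self.c = max(self.priors.clock_mean, 1e-3)
        self.sigma2 = 1.0 / self.priors.igrvar_rate
        self.alpha = 1.0
        self.t = self._durations()
        if self.config.mode == "tipdating":
            self.v = np.where(self.t > 0, self.c * self.t, 0.0)
        else:
            self.v = rng.exponential(1.0 / self.priors.nonclock_brlen_rate,
                                     size=top.n_nodes)
        self.v[top.root] = 0.0

    def _durations(self) -> np.ndarray:
        t = np.zeros(self.top.n_nodes)
        mask = self.parent >= 0
        idx = np.where(mask)[0]
        t[idx] = self.ages[self.parent[idx]] - self.ages[idx]
        return t

    # -- density pieces ---------------------------------------------------
    def _igr_term(self, idx) -> np.ndarray:
        """Per-branch log prior of v given t (IGR) or Exp (non-clock)."""
        idx = np.atleast_1d(idx)
        v = self.v[idx]
        if self.config.mode == "nonclock":
            lam = self.priors.nonclock_brlen_rate
            out = np.where(v >= 0, math.log(lam) - lam * v, -np.inf)
            return out
        t = self.t[idx]
        if np.any(t <= 0):
            return np.full(len(idx), -np.inf)
        a = self.c * t / self.sigma2
        # Gamma(shape a, rate 1/sigma2) log pdf at v
        with np.errstate(divide="ignore", invalid="ignore"):
            out = ((a - 1.0) * np.log(v) - v / self.sigma2
                   - a * math.log(self.sigma2) - gammaln(a))
        out = np.where(v > 0, out, np.where(v == 0, -np.inf, -np.inf))
        return out

    def _fbd(self) -> float:
        if not self.config.tree_prior or self.config.mode == "nonclock":
            return 0.0
        fossil = [self.ages[i] for i in self.fossil_tips
                  if self.ages[i] > _FOSSIL_TOL]
        n_extant = sum(1 for i in self.top.leaf_label
                       if self.ages[i] <= _FOSSIL_TOL)
        internal = self.ages[self.internal]
        try:
            return fbd_log_density_times(
                internal, fossil, n_extant, self.ages[self.top.root],
                FBDParams(self.d, self.r, self.s, self.priors.rho,
                          removal=self.config.fossil_removal))
        except ValueError:
            return -np.inf

    def _params_log_prior(self) -> float:
        p = self.priors
        if self.alpha <= 0:
            return -np.inf
        logp = -self.alpha  # Exp(1) on the gamma shape
        if self.config.mode == "nonclock":
            return logp
        if self.d <= 0 or self.sigma2 <= 0:
            return -np.inf
        if not (0 <= self.r < 1) or not (0 <= self.s < 1):
            return -np.inf
        if not (p.root_min <= self.ages[self.top.root] <= p.root_max):
            return -np.inf
        logp += math.log(p.speciation_rate) - p.speciation_rate * self.d
        logp += p.clock_log_density(self.c)
        logp += math.log(p.igrvar_rate) - p.igrvar_rate * self.sigma2
        return logp

    def _recompute_all(self) -> None:
        self.t = self._durations()
        self.igr = np.zeros(self.top.n_nodes)
        nonroot = [i for i in range(self.top.n_nodes) if i != self.top.root]
        self.igr[nonroot] = self._igr_term(nonroot)
        self.igr_sum = float(self.igr[nonroot].sum())
        self.fbd = self._fbd()
        self.lnp_params = self._params_log_prior()
        self.lnL = (self.cache.full(self.v, self.alpha)
                    if self.cache is not None else 0.0)

    @property
    def log_posterior(self) -> float:
        return self.lnL + self.fbd + self.igr_sum + self.lnp_params

    def _accept(self, delta: float, log_hastings: float) -> bool:
        if not np.isfinite(delta):
            return False
        return math.log(self.rng.random()) < self.beta * delta + log_hastings

    # -- age moves --------------------------------------------------------
    def _age_move(self, i: int, new_age: float, affected: list[int]) -> None:
        """Generic accept/reject for a single-node age change; ``affected``
        lists the branches whose durations change (i and its children)."""
        old_age = self.ages[i]
        old_t = self.t[affected].copy()
        old_terms = self.igr[affected].copy()
        self.ages[i] = new_age
        for b in affected:
            p = self.parent[b]
            self.t[b] = self.ages[p] - self.ages[b] if p >= 0 else 0.0
        if np.any(self.t[affected] <= 0):
            new_terms = np.full(len(affected), -np.inf)
        else:
            new_terms = self._igr_term(affected)
        d_igr = new_terms.sum() - old_terms.sum()
        new_fbd = self._fbd() if np.isfinite(d_igr) else -np.inf
        new_params = self._params_log_prior() if i == self.top.root \
            else self.lnp_params
        delta = d_igr + (new_fbd - self.fbd) + (new_params - self.lnp_params)
        if self._accept(delta, 0.0):
            self.igr[affected] = new_terms
            self.igr_sum += float(d_igr)
            self.fbd = new_fbd
            self.lnp_params = new_params
        else:
            self.ages[i] = old_age
            self.t[affected] = old_t
            self.igr[affected] = old_terms

    def _joint_age_move(self, i: int, new_age: float,
                        affected: list[int]) -> None:
        """Slide a node age while rescaling the adjacent effective lengths
        to preserve their rates (the Jacobian enters the Hastings term);
        this moves along the age/length ridge the plain moves fight."""
        old_age = self.ages[i]
        old_t = self.t[affected].copy()
        old_v = self.v[affected].copy()
        old_terms = self.igr[affected].copy()
        self.ages[i] = new_age
        new_t = np.empty(len(affected))
        for j, b in enumerate(affected):
            p = self.parent[b]
            new_t[j] = self.ages[p] - self.ages[b] if p >= 0 else 0.0
        if np.any(new_t <= 0) or np.any(old_t <= 0):
            self.ages[i] = old_age
            return
        factor = new_t / old_t
        self.t[affected] = new_t
        self.v[affected] = old_v * factor
        new_terms = self._igr_term(affected)
        d_igr = new_terms.sum() - old_terms.sum()
        new_fbd = self._fbd()
        new_params = self._params_log_prior() if i == self.top.root \
            else self.lnp_params
        lnL_new = self.lnL
        if self.cache is not None:
            lnL_new = self.cache.propose(self.v, self.alpha, list(affected))
        delta = (d_igr + (new_fbd - self.fbd) + (new_params - self.lnp_params)
                 + (lnL_new - self.lnL))
        if self._accept(delta, float(np.log(factor).sum())):
            self.igr[affected] = new_terms
            self.igr_sum += float(d_igr)
            self.fbd = new_fbd
            self.lnp_params = new_params
            if self.cache is not None:
                self.lnL = lnL_new
                self.cache.accept()
        else:
            self.ages[i] = old_age
            self.t[affected] = old_t
            self.v[affected] = old_v
            self.igr[affected] = old_terms
            if self.cache is not None:
                self.cache.reject()

    def _sweep_ages(self) -> None:
        rng = self.rng
        for i in self.movable_tips:
            lo, hi = self.tip_lo[i], self.tip_hi[i]
            prop = self.ages[i] + rng.normal(0.0, (hi - lo) / 6.0)
            if lo <= prop <= hi and prop < self.ages[self.parent[i]]:
                self._age_move(i, prop, [i])
            prop = self.ages[i] + rng.normal(0.0, (hi - lo) / 4.0)
            if lo <= prop <= hi and prop < self.ages[self.parent[i]]:
                self._joint_age_move(i, prop, [i])
        for i in self.internal:
            lo = max(self.ages[c] for c in self.children[i])
            hi = (self.priors.root_max if i == self.top.root
                  else self.ages[self.parent[i]])
            if hi <= lo:
                continue
            affected = [i] + list(self.children[i]) if i != self.top.root \
                else list(self.children[i])
            self._age_move(i, rng.uniform(lo, hi), affected)
            lo = max(self.ages[c] for c in self.children[i])
            hi = (self.priors.root_max if i == self.top.root
                  else self.ages[self.parent[i]])
            prop = self.ages[i] + rng.normal(0.0, 0.25 * (hi - lo))
            if lo < prop < hi:
                self._joint_age_move(i, prop, affected)

    # -- branch-length moves ----------------------------------------------
    def _sweep_lengths(self) -> None:
        rng = self.rng
        for i in range(self.top.n_nodes):
            if i == self.top.root:
                continue
            m = math.exp(0.8 * (rng.random() - 0.5))
            old_v = self.v[i]
            old_term = self.igr[i]
            self.v[i] = old_v * m
            new_term = float(self._igr_term(i)[0])
            lnL_new = self.lnL
            if self.cache is not None and np.isfinite(new_term):
                lnL_new = self.cache.propose(self.v, self.alpha, [i])
            delta = (new_term - old_term) + (lnL_new - self.lnL)
            if self._accept(delta, math.log(m)):
                self.igr[i] = new_term
                self.igr_sum += new_term - old_term
                if self.cache is not None:
                    self.lnL = lnL_new
                    self.cache.accept()
            else:
                self.v[i] = old_v
                if self.cache is not None:
                    self.cache.reject()

    # -- scalar parameter moves -------------------------------------------
    def _try_param(self, name: str, new_val: float, log_hastings: float,
                   igr_depends: bool = False, fbd_depends: bool = False,
                   lik_depends: bool = False) -> None:
        old_val = getattr(self, name)
        setattr(self, name, new_val)
        new_params = self._params_log_prior()
        if not np.isfinite(new_params):
            setattr(self, name, old_val)
            return
        nonroot = [i for i in range(self.top.n_nodes) if i != self.top.root]
        new_terms, new_sum = None, self.igr_sum
        if igr_depends:
            new_terms = self._igr_term(nonroot)
            new_sum = float(new_terms.sum())
        new_fbd = self._fbd() if fbd_depends else self.fbd
        lnL_new = self.lnL
        if lik_depends and self.cache is not None:
            lnL_new = self.cache.full(self.v, self.alpha)
        delta = ((new_params - self.lnp_params) + (new_sum - self.igr_sum)
                 + (new_fbd - self.fbd) + (lnL_new - self.lnL))
        if self._accept(delta, log_hastings):
            self.lnp_params = new_params
            if new_terms is not None:
                self.igr[nonroot] = new_terms
                self.igr_sum = new_sum
            self.fbd = new_fbd
            self.lnL = lnL_new
        else:
            setattr(self, name, old_val)
            if lik_depends and self.cache is not None:
                self.cache.full(self.v, self.alpha)

    def _sweep_params(self) -> None:
        rng = self.rng

        def mult(scale):
            m = math.exp(scale * (rng.random() - 0.5))
            return m, math.log(m)

        if self.config.mode == "tipdating":
            m, lh = mult(1.0)
            self._try_param("d", self.d * m, lh, fbd_depends=True)
            m, lh = mult(0.6)
            self._try_param("c", self.c * m, lh, igr_depends=True)
            m, lh = mult(1.2)
            self._try_param("sigma2", self.sigma2 * m, lh, igr_depends=True)
            self._try_param("r", self.r + rng.normal(0.0, 0.1), 0.0,
                            fbd_depends=True)
            self._try_param("s", self.s + rng.normal(0.0, 0.1), 0.0,
                            fbd_depends=True)
        if self.cache is not None:
            m, lh = mult(0.8)
            self._try_param("alpha", self.alpha * m, lh, lik_depends=True)

    # -- topology move ----------------------------------------------------
    def _move_nni(self) -> None:
        """Time-tree NNI: swap a child of an internal node with the node's
        sibling, keeping all ages; rejected when ages would conflict."""
        rng = self.rng
        candidates = [i for i in self.internal
                      if i != self.top.root and self.parent[i] >= 0]
        if not candidates:
            return
        vn = int(rng.choice(candidates))
        p = int(self.parent[vn])
        sibs = [c for c in self.children[p] if c != vn]
        a = int(rng.choice(self.children[vn]))
        b = int(rng.choice(sibs))
        if self.ages[b] >= self.ages[vn]:
            return

        def do_swap(x, y, px, py):
            self.children[px].remove(x)
            self.children[py].remove(y)
            self.children[px].append(y)
            self.children[py].append(x)
            self.parent[x], self.parent[y] = py, px

        do_swap(a, b, vn, p)
        old = (self.t.copy(), self.igr.copy(), self.igr_sum, self.lnL)
        self.t = self._durations()
        nonroot = [i for i in range(self.top.n_nodes) if i != self.top.root]
        self.igr[nonroot] = self._igr_term(nonroot)
        new_sum = float(self.igr[nonroot].sum())
        lnL_new = self.lnL
        if self.cache is not None:
            lnL_new = self._loglik_for_current_children()
        delta = (new_sum - old[2]) + (lnL_new - old[3])
        if self._accept(delta, 0.0):
            self.igr_sum = new_sum
            self.lnL = lnL_new
            self._commit_topology()
        else:
            do_swap(b, a, vn, p)
            self.t, self.igr, self.igr_sum, self.lnL = old

    def _loglik_for_current_children(self) -> float:
        top = _topology_from_children(self.top, self.children)
        lik = MkLikelihood(self.lik.matrix, top, self.lik.model)
        cache = PruningCache(lik)
        return cache.full(self.v[top.remap_from_old], self.alpha)

    def _commit_topology(self) -> None:
        top = _topology_from_children(self.top, self.children)
        remap = top.remap_from_old
        self.ages = self.ages[remap]
        self.v = self.v[remap]
        self.top = top
        if self.lik is not None:
            self.lik = MkLikelihood(self.lik.matrix, top, self.lik.model)
            self.cache = PruningCache(self.lik)
            self.cache.full(self.v, self.alpha)
        self._index_tips()
        self.children = [list(c) for c in top.children]
        self.parent = top.parent.copy()
        self.t = self._durations()
        nonroot = [i for i in range(self.top.n_nodes) if i != self.top.root]
        self.igr = np.zeros(self.top.n_nodes)
        self.igr[nonroot] = self._igr_term(nonroot)
        self.igr_sum = float(self.igr[nonroot].sum())

    def sweep(self) -> None:
        if self.config.mode == "tipdating":
            self._sweep_ages()
        self._sweep_lengths()
        self._sweep_params()
        if self.config.topology_moves:
            self._move_nni()


def _topology_from_children(top: TopologyIndex, children) -> TopologyIndex:
    """New TopologyIndex from mutated children lists, carrying a
    ``remap_from_old`` array (new index -> value taken from old index)."""
    old_of_node: dict[int, int] = {}

    def build(i: int) -> Node:
        n = Node(top.leaf_label.get(i))
        old_of_node[id(n)] = i
        for c in children[i]:
            n.add_child(build(c))
        return n

    tree = Tree(build(top.root))
    new_top = TopologyIndex(tree)
    remap = np.zeros(new_top.n_nodes, dtype=int)
    for new_i, node in enumerate(new_top.nodes):
        remap[new_i] = old_of_node[id(node)]
    new_top.remap_from_old = remap
    return new_top


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_mcmc(matrix: CharacterMatrix | None, topology: Tree,
             calibrations: CalibrationTable, priors: PriorSet,
             config: ChainConfig, seed: int) -> MCMCOutput:
    """Run ``config.n_runs`` independent MC3 runs; returns traces and
    cold-chain tree samples.

    ``matrix`` may be None for prior-only sampling (equivalent to
    ``config.likelihood = False``).
    """
    if config.n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    outputs_traces, outputs_trees = [], []
    for run in range(config.n_runs):
        rng = np.random.default_rng((seed + 1000003 * run) % 2**31)
        top = TopologyIndex(topology)
        lik = None
        if matrix is not None and config.likelihood:
            model = MkModel(n_gamma_categories=config.n_gamma_categories)
            lik = MkLikelihood(matrix, top, model)
        chains = []
        for ci in range(config.n_chains):
            tries = 0
            while True:
                try:
                    chains.append(_Chain(top, lik, calibrations, priors,
                                         config, rng, config.heat(ci)))
                    break
                except RuntimeError:
                    tries += 1
                    if tries >= 20:
                        raise
        rows, samples = [], []
        for gen in range(1, config.n_generations + 1):
            for chain in chains:
                chain.sweep()
            if len(chains) > 1:
                i = int(rng.integers(0, len(chains) - 1))
                a, b = chains[i], chains[i + 1]
                delta = (a.beta - b.beta) * (b.log_posterior - a.log_posterior)
                if math.log(rng.random()) < delta:
                    a.beta, b.beta = b.beta, a.beta
                    chains[i], chains[i + 1] = b, a
            if gen % config.sample_frequency == 0:
                cold = chains[0]
                _assert_valid(cold)
                rows.append(_trace_row(cold, gen))
                samples.append(_tree_sample(cold))
        outputs_traces.append(pd.DataFrame(rows))
        outputs_trees.append(samples)
    return MCMCOutput(outputs_traces, outputs_trees, config, topology)


def _assert_valid(chain: _Chain) -> None:
    top = chain.top
    for i in range(top.n_nodes):
        p = chain.parent[i]
        if p >= 0 and chain.config.mode == "tipdating":
            assert chain.ages[p] > chain.ages[i], "parent age <= child age"
    for i, lab in top.leaf_label.items():
        if lab in chain.calibrations:
            lo, hi = chain.calibrations.bounds(lab)
            assert lo - 1e-9 <= chain.ages[i] <= hi + 1e-9, "tip outside window"


def _trace_row(chain: _Chain, gen: int) -> dict:
    top = chain.top
    row = {"gen": gen, "lnL": chain.lnL, "lnP": chain.log_posterior,
           "d": chain.d, "r": chain.r, "s": chain.s, "clock_rate": chain.c,
           "sigma2": chain.sigma2, "alpha": chain.alpha,
           "root_age": chain.ages[top.root],
           "tree_length_v": float(chain.v.sum())}
    for i in chain.movable_tips:
        row[f"age_{top.leaf_label[i]}"] = chain.ages[i]
    return row


def _tree_sample(chain: _Chain) -> TreeSample:
    top = chain.top
    below: dict[int, frozenset] = {}
    order, stack = [], [top.root]
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(chain.children[i])
    clade_ages, ratios, tips = {}, {}, {}
    for i in order[::-1]:
        if top.is_leaf[i]:
            below[i] = frozenset([top.leaf_label[i]])
            tips[top.leaf_label[i]] = chain.ages[i]
        else:
            below[i] = frozenset().union(*(below[c] for c in chain.children[i]))
            clade_ages[below[i]] = chain.ages[i]
        p = chain.parent[i]
        if p >= 0:
            t = chain.ages[p] - chain.ages[i]
            if t > 0 and chain.c > 0:
                ratios[below[i]] = chain.v[i] / (chain.c * t)
    return TreeSample(clade_ages, tips, ratios, chain.ages[top.root])


# ---------------------------------------------------------------------------
# summaries and diagnostics
# ---------------------------------------------------------------------------

def hpd_interval(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    k = max(1, int(math.ceil(prob * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[:n - k]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k])


def effective_sample_size(trace) -> float:
    import arviz as az
    x = np.asarray(trace, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    return float(az.ess(az.convert_to_dataset(x)).x.values)


def potential_scale_reduction(traces) -> float:
    import arviz as az
    x = np.asarray(traces, dtype=float)
    return float(az.rhat(az.convert_to_dataset(x)).x.values)


def asdsf(tree_samples_by_run: list[list[TreeSample]],
          min_freq: float = 0.1) -> float:
    """Average s.d. of split frequencies across runs (splits with
    frequency >= min_freq in at least one run)."""
    freqs: list[dict[frozenset, float]] = []
    for run in tree_samples_by_run:
        counts: dict[frozenset, int] = {}
        for sample in run:
            for clade in sample.clade_ages:
                counts[clade] = counts.get(clade, 0) + 1
        freqs.append({c: n / len(run) for c, n in counts.items()})
    clades = {c for f in freqs for c, v in f.items() if v >= min_freq}
    if not clades:
        return 0.0
    sds = []
    for c in clades:
        vals = np.array([f.get(c, 0.0) for f in freqs])
        sds.append(vals.std(ddof=0))
    return float(np.mean(sds))


def diagnostics(output: MCMCOutput, burn_in: float | None = None) -> pd.DataFrame:
    """Per-parameter ESS and PSRF (pooled post-burn-in runs), plus ASDSF
    stored in ``.attrs['asdsf']``."""
    cfg = output.config
    b = cfg.burn_in if burn_in is None else burn_in
    traces = []
    for tr in output.traces:
        n = len(tr)
        traces.append(tr.iloc[int(b * n):])
    params = [c for c in traces[0].columns if c != "gen"]
    rows = []
    for p in params:
        stacked = np.array([t[p].to_numpy() for t in traces])
        if np.allclose(stacked.std(), 0.0):
            ess = float("nan")
            psrf = 1.0 if len(traces) > 1 else float("nan")
        else:
            ess = effective_sample_size(stacked)
            psrf = (potential_scale_reduction(stacked)
                    if len(traces) > 1 else float("nan"))
        rows.append({"parameter": p, "mean": stacked.mean(),
                     "median": float(np.median(stacked)),
                     "ess": ess, "psrf": psrf})
    df = pd.DataFrame(rows).set_index("parameter")
    trees = [run[int(b * len(run)):] for run in output.tree_samples]
    df.attrs["asdsf"] = asdsf(trees) if len(trees) > 1 else float("nan")
    return df


@dataclass
class PosteriorSummary:
    consensus: Tree
    clade_pp: dict[frozenset, float]
    clade_median_age: dict[frozenset, float]
    branch_median_ratio: dict[frozenset, float]
    tip_ages: pd.DataFrame           # mean, hpd_lo, hpd_hi per tip
    parameters: pd.DataFrame
    asdsf: float
    median_clock_rate: float


def summarize(output: MCMCOutput, burn_in: float | None = None) -> PosteriorSummary:
    """Allcompat consensus with median node ages, branch rate ratios,
    per-tip age means and 95% HPDs, and parameter diagnostics."""
    cfg = output.config
    b = cfg.burn_in if burn_in is None else burn_in
    samples: list[TreeSample] = []
    for run in output.tree_samples:
        samples.extend(run[int(b * len(run)):])
    if not samples:
        raise ValueError("no post-burn-in samples")
    labels = sorted(samples[0].tip_ages)
    # rooted clade frequencies over sampled time trees
    freq: dict[frozenset, int] = {}
    ages_by_clade: dict[frozenset, list[float]] = {}
    ratios_by_key: dict[frozenset, list[float]] = {}
    for s in samples:
        for clade, age in s.clade_ages.items():
            if 1 < len(clade) < len(labels):
                freq[clade] = freq.get(clade, 0) + 1
            ages_by_clade.setdefault(clade, []).append(age)
        for key, ratio in s.branch_ratio.items():
            ratios_by_key.setdefault(key, []).append(ratio)
    n = len(samples)
    accepted: dict[frozenset, float] = {c: k / n for c, k in freq.items()
                                        if k / n > 0.5}
    rest = sorted((c for c in freq if c not in accepted),
                  key=lambda c: (-freq[c], sorted(c)))
    from .trees import _compatible
    for clade in rest:
        if _compatible(clade, accepted):
            accepted[clade] = freq[clade] / n
    consensus = _build_rooted_from_clades(labels, accepted)
    clade_median = {c: float(np.median(v)) for c, v in ages_by_clade.items()}
    ratio_median = {k: float(np.median(v)) for k, v in ratios_by_key.items()}
    tip_mean = {lab: float(np.mean([s.tip_ages[lab] for s in samples]))
                for lab in labels}
    below: dict[int, frozenset] = {}
    for node in consensus.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
            node.age = tip_mean[node.label]
        else:
            below[id(node)] = frozenset().union(
                *(below[id(c)] for c in node.children))
        key = below[id(node)]
        if not node.is_leaf and key in clade_median:
            node.age = clade_median[key]
        if key in ratio_median:
            node.rate = ratio_median[key]
    root_ages = [s.root_age for s in samples]
    consensus.root.age = float(np.median(root_ages))
    _enforce_monotone_ages(consensus)
    rows = []
    for lab in labels:
        vals = np.array([s.tip_ages[lab] for s in samples])
        lo, hi = hpd_interval(vals)
        rows.append({"tip": lab, "mean": vals.mean(), "hpd_lo": lo, "hpd_hi": hi})
    tips = pd.DataFrame(rows).set_index("tip")
    params = diagnostics(output, burn_in=b)
    median_c = float(params.loc["clock_rate", "median"]) \
        if "clock_rate" in params.index else float("nan")
    return PosteriorSummary(consensus, dict(accepted), clade_median,
                            ratio_median, tips, params,
                            params.attrs.get("asdsf", float("nan")), median_c)


def _build_rooted_from_clades(labels: list[str],
                              accepted: dict[frozenset, float]) -> Tree:
    """Rooted tree from pairwise nested-or-disjoint clades over ``labels``."""
    ordered = sorted(accepted, key=len, reverse=True)
    root = Node()
    tree_nodes = {clade: Node() for clade in ordered}
    for clade in ordered:
        supersets = [o for o in ordered if clade < o]
        parent = tree_nodes[min(supersets, key=len)] if supersets else root
        parent.add_child(tree_nodes[clade])
    for label in labels:
        containing = [c for c in ordered if label in c]
        parent = tree_nodes[min(containing, key=len)] if containing else root
        parent.add_child(Node(label))
    return Tree(root)


def _enforce_monotone_ages(tree: Tree) -> None:
    """Consensus annotation can mix medians from different samples; nudge
    parents to be at least as old as their children for display."""
    for node in tree.postorder():
        if node.is_leaf or node.age is None:
            continue
        for c in node.children:
            if c.age is not None and c.age > node.age:
                node.age = c.age
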