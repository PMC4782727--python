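"""Bayesian ancestral reconstruction of a continuous trait on a time tree.

The trait (here ln first-lower-molar area) evolves by Brownian motion:
under the random-walk model tip values are multivariate normal with
mean alpha0 and covariance sigma2 * C, where C_ij is the elapsed time
from the root to the most recent common ancestor of tips i and j; the
directional model adds a trend beta per Ma of root-to-tip time.  Tree
transforms rescale C: Pagel's lambda multiplies internal-node depths
(hence off-diagonal covariances), delta raises node depths to a power,
kappa raises individual branch durations to a power.  Fossil tips at
their own ages make the tree non-ultrametric, which is what renders the
directional trend identifiable.  Inference is MH-MCMC over the model
parameters with ancestral states drawn from their exact conditional
multivariate normal at each sampled generation; marginal likelihoods
use the harmonic-mean estimator over post-burn-in samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .mcmc import hpd_interval
from .trees import Tree

__all__ = [
    "BMModel",
    "TraitModel",
    "TraitResults",
    "transform_depths",
    "tip_covariance",
    "bm_loglik",
    "compare_models",
]

TRANSFORMS = ("none", "lambda", "delta", "kappa")


@dataclass
class BMModel:
    kind: str = "random_walk"        # or "directional"
    sigma2: float = 1.0              # trait variance per Ma
    alpha0: float = 0.0              # root state
    beta: float = 0.0                # trend per Ma (directional only)
    transform: str = "none"
    transform_value: float = 1.0

    def __post_init__(self):
        if self.kind not in ("random_walk", "directional"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        _check_transform(self.transform, self.transform_value)


def _check_transform(transform: str, value: float) -> None:
    if transform == "lambda" and not (0.0 <= value <= 1.0):
        raise ValueError("lambda scale must be in [0, 1]")
    if transform in ("delta", "kappa") and value <= 0:
        raise ValueError(f"{transform} must be positive")


class _TreeStructure:
    """Precomputed node order, depths, and MRCA index matrices."""

    def __init__(self, tree: Tree):
        self.nodes = list(tree.postorder())
        self.idx = {id(n): i for i, n in enumerate(self.nodes)}
        self.n = len(self.nodes)
        root_age = tree.root.age
        if root_age is None:
            raise ValueError("tree needs node ages")
        self.depth = np.array([root_age - n.age for n in self.nodes])
        self.branch = np.array([0.0 if n.parent is None
                                else n.parent.age - n.age
                                for n in self.nodes])
        self.parent = np.array([-1 if n.parent is None else self.idx[id(n.parent)]
                                for n in self.nodes])
        self.is_leaf = np.array([n.is_leaf for n in self.nodes])
        self.labels = [n.label for n in self.nodes]
        self.leaf_order = [i for i in range(self.n) if self.is_leaf[i]]
        # ancestor chains
        anc = []
        for i in range(self.n):
            chain, j = [], i
            while j >= 0:
                chain.append(j)
                j = self.parent[j]
            anc.append(set(chain))
        self.mrca = np.zeros((self.n, self.n), dtype=int)
        for i in range(self.n):
            for j in range(i, self.n):
                common = anc[i] & anc[j]
                m = max(common, key=lambda x: self.depth[x])
                self.mrca[i, j] = self.mrca[j, i] = m

    def transformed_depth(self, transform: str, value: float) -> np.ndarray:
        _check_transform(transform, value)
        if transform == "none":
            return self.depth.copy()
        if transform == "lambda":
            d = self.depth.copy()
            d[~self.is_leaf] *= value
            return d
        if transform == "delta":
            return self.depth ** value
        # kappa: per-branch durations raised to a power, accumulated
        d = np.zeros(self.n)
        for i in reversed(range(self.n)):  # preorder
            p = self.parent[i]
            if p >= 0:
                d[i] = d[p] + max(self.branch[i], 0.0) ** value
        return d


def transform_depths(tree: Tree, transform: str, value: float) -> dict[str, np.ndarray]:
    """Node depths (time from root) after a tree transform; exposes the
    covariance inputs for inspection and testing."""
    ts = _TreeStructure(tree)
    d = ts.transformed_depth(transform, value)
    return {"depth": d, "is_leaf": ts.is_leaf, "labels": ts.labels,
            "mrca": ts.mrca}


def tip_covariance(tree: Tree, transform: str = "none",
                   value: float = 1.0) -> tuple[np.ndarray, list[str]]:
    """BM covariance (per unit sigma2) among tips, with tip labels."""
    ts = _TreeStructure(tree)
    d = ts.transformed_depth(transform, value)
    leaves = ts.leaf_order
    C = d[ts.mrca[np.ix_(leaves, leaves)]]
    np.fill_diagonal(C, d[leaves])
    return C, [ts.labels[i] for i in leaves]


def bm_loglik(tree: Tree, traits: dict[str, float], model: BMModel) -> float:
    """Multivariate-normal log likelihood of tip traits under ``model``."""
    C, labels = tip_covariance(tree, model.transform, model.transform_value)
    missing = sorted(set(labels) - set(traits))
    if missing:
        raise ValueError(f"tips without trait values: {missing}")
    x = np.array([traits[l] for l in labels])
    ts = _TreeStructure(tree)
    d = ts.transformed_depth(model.transform, model.transform_value)
    tip_depth = d[ts.leaf_order]
    mean = model.alpha0 + (model.beta * tip_depth
                           if model.kind == "directional" else 0.0)
    return _mvn_loglik(x, np.broadcast_to(mean, x.shape), model.sigma2 * C)


def _mvn_loglik(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    n = len(x)
    try:
        factor = cho_factor(cov, lower=True)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("singular BM covariance")
    resid = x - mean
    alpha = cho_solve(factor, resid)
    logdet = 2.0 * np.log(np.diag(factor[0])).sum()
    return float(-0.5 * (n * math.log(2 * math.pi) + logdet + resid @ alpha))


# ---------------------------------------------------------------------------
# model objects
# ---------------------------------------------------------------------------

@dataclass
class _TraitPriors:
    """Wide, deliberately weakly-informative priors (documented caveat)."""

    alpha0_range: tuple[float, float] = (-100.0, 100.0)
    beta_range: tuple[float, float] = (-100.0, 100.0)
    ln_sigma2_range: tuple[float, float] = (-20.0, 20.0)
    shape_range: tuple[float, float] = (0.01, 3.0)  # delta/kappa


class TraitModel:
    """Continuous-trait BM model bound to a time tree and tip data.

    statsmodels-style: construct from data, call :meth:`fit` to run the
    MCMC and obtain a :class:`TraitResults`.
    """

    def __init__(self, tree: Tree, traits: dict[str, float],
                 kind: str = "random_walk", transform: str = "none",
                 priors: _TraitPriors | None = None):
        if kind not in ("random_walk", "directional"):
            raise ValueError(f"unknown model kind {kind!r}")
        if transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {transform!r}")
        self.tree = tree
        self.kind = kind
        self.transform = transform
        self.priors = priors or _TraitPriors()
        self.struct = _TreeStructure(tree)
        labels = [self.struct.labels[i] for i in self.struct.leaf_order]
        missing = sorted(set(labels) - set(traits))
        if missing:
            raise ValueError(f"tips without trait values: {missing}")
        self.tip_labels = labels
        self.x = np.array([float(traits[l]) for l in labels])
        self.traits = dict(traits)

    @classmethod
    def from_files(cls, tree_path, traits_path, **kwargs) -> "TraitModel":
        from .matrix import read_traits
        from .trees import read_tree
        return cls(read_tree(tree_path), read_traits(traits_path), **kwargs)

    # -- likelihood over parameter vector ---------------------------------
    def _unpack(self, theta: np.ndarray):
        alpha0, ln_s2 = theta[0], theta[1]
        pos = 2
        beta = 0.0
        if self.kind == "directional":
            beta = theta[pos]
            pos += 1
        tval = 1.0
        if self.transform != "none":
            tval = theta[pos]
        return alpha0, math.exp(ln_s2), beta, tval

    def _log_prior(self, theta: np.ndarray) -> float:
        p = self.priors
        alpha0, ln_s2 = theta[0], theta[1]
        if not (p.alpha0_range[0] <= alpha0 <= p.alpha0_range[1]):
            return -np.inf
        if not (p.ln_sigma2_range[0] <= ln_s2 <= p.ln_sigma2_range[1]):
            return -np.inf
        pos = 2
        if self.kind == "directional":
            if not (p.beta_range[0] <= theta[pos] <= p.beta_range[1]):
                return -np.inf
            pos += 1
        if self.transform == "lambda":
            if not (0.0 <= theta[pos] <= 1.0):
                return -np.inf
        elif self.transform in ("delta", "kappa"):
            if not (p.shape_range[0] <= theta[pos] <= p.shape_range[1]):
                return -np.inf
        return 0.0

    def _loglik(self, theta: np.ndarray) -> float:
        alpha0, s2, beta, tval = self._unpack(theta)
        d = self.struct.transformed_depth(self.transform, tval)
        leaves = self.struct.leaf_order
        C = d[self.struct.mrca[np.ix_(leaves, leaves)]]
        np.fill_diagonal(C, d[leaves])
        mean = alpha0 + (beta * d[leaves] if self.kind == "directional" else 0.0)
        try:
            return _mvn_loglik(self.x, np.broadcast_to(mean, self.x.shape),
                               s2 * C)
        except np.linalg.LinAlgError:
            return -np.inf

    def _ancestral_conditional(self, theta: np.ndarray,
                               rng: np.random.Generator) -> np.ndarray:
        """One draw of all internal-node states given tips and parameters."""
        alpha0, s2, beta, tval = self._unpack(theta)
        st = self.struct
        d = st.transformed_depth(self.transform, tval)
        leaves = st.leaf_order
        internal = [i for i in range(st.n) if not st.is_leaf[i]]
        Cff = d[st.mrca[np.ix_(leaves, leaves)]].copy()
        np.fill_diagonal(Cff, d[leaves])
        Caf = d[st.mrca[np.ix_(internal, leaves)]]
        Caa = d[st.mrca[np.ix_(internal, internal)]].copy()
        np.fill_diagonal(Caa, d[internal])
        mean_f = alpha0 + (beta * d[leaves] if self.kind == "directional" else 0.0)
        mean_a = alpha0 + (beta * d[internal] if self.kind == "directional" else 0.0)
        factor = cho_factor(s2 * Cff, lower=True)
        w = cho_solve(factor, self.x - mean_f)
        cond_mean = mean_a + (s2 * Caf) @ w
        cond_cov = s2 * Caa - (s2 * Caf) @ cho_solve(factor, (s2 * Caf).T)
        cond_cov = 0.5 * (cond_cov + cond_cov.T)
        jitter = 1e-10 * max(1.0, np.trace(cond_cov) / len(internal))
        vals, vecs = np.linalg.eigh(cond_cov + jitter * np.eye(len(internal)))
        vals = np.clip(vals, 0.0, None)
        z = rng.standard_normal(len(internal))
        return cond_mean + vecs @ (np.sqrt(vals) * z)

    def _initial_theta(self) -> np.ndarray:
        p = self.priors
        theta = [float(np.clip(self.x.mean(), *p.alpha0_range)),
                 float(np.clip(
                     math.log(max(self.x.var()
                                  / max(self.struct.depth.max(), 1e-6), 1e-6)),
                     *p.ln_sigma2_range))]
        if self.kind == "directional":
            theta.append(float(np.clip(0.0, *p.beta_range)))
        if self.transform == "lambda":
            theta.append(0.5)
        elif self.transform != "none":
            theta.append(float(np.clip(1.0, *p.shape_range)))
        return np.array(theta)

    def fit(self, n_generations: int = 6000, burn_in: float = 0.25,
            sample_frequency: int = 5, seed: int = 0,
            sample_ancestral: bool = True) -> "TraitResults":
        rng = np.random.default_rng(seed)
        theta = self._initial_theta()
        lnL = self._loglik(theta)
        lnPrior = self._log_prior(theta)
        scales = np.full(len(theta), 0.15)
        scales[0] = max(self.x.std() / 4.0, 0.05)   # alpha0
        scales[1] = 0.4                              # ln sigma2
        if self.kind == "directional":
            scales[2] = max(self.x.std()
                            / max(self.struct.depth.max(), 1.0) / 2.0, 0.002)
        if self.transform != "none":
            scales[-1] = 0.12
        names = ["alpha0", "ln_sigma2"]
        if self.kind == "directional":
            names.append("beta")
        if self.transform != "none":
            names.append(self.transform)
        rows, anc_draws, lnl_samples = [], [], []
        for gen in range(1, n_generations + 1):
            for j in range(len(theta)):
                prop = theta.copy()
                prop[j] += rng.normal(0.0, scales[j])
                lp = self._log_prior(prop)
                if not np.isfinite(lp):
                    continue
                ll = self._loglik(prop)
                if math.log(rng.random()) < (ll + lp) - (lnL + lnPrior):
                    theta, lnL, lnPrior = prop, ll, lp
            if gen % sample_frequency == 0:
                row = dict(zip(names, theta))
                row["lnL"] = lnL
                rows.append(row)
                lnl_samples.append(lnL)
                if sample_ancestral:
                    anc_draws.append(self._ancestral_conditional(theta, rng))
        trace = pd.DataFrame(rows)
        cut = int(burn_in * len(trace))
        return TraitResults(self, trace, np.array(anc_draws), cut)


class TraitResults:
    """Posterior summaries of a fitted continuous-trait BM model."""

    def __init__(self, model: TraitModel, trace: pd.DataFrame,
                 ancestral_draws: np.ndarray, burn_cut: int):
        self.model = model
        self.trace = trace
        self._anc = ancestral_draws
        self._cut = burn_cut
        st = model.struct
        self.internal_indices = [i for i in range(st.n) if not st.is_leaf[i]]
        below: dict[int, frozenset] = {}
        for i, node in enumerate(st.nodes):
            if st.is_leaf[i]:
                below[i] = frozenset([node.label])
            else:
                below[i] = frozenset().union(
                    *(below[st.idx[id(c)]] for c in node.children))
        self.clades = {i: below[i] for i in self.internal_indices}

    @property
    def posterior(self) -> pd.DataFrame:
        return self.trace.iloc[self._cut:]

    @property
    def log_marginal_likelihood(self) -> float:
        """Harmonic-mean estimator from post-burn-in sampled likelihoods."""
        lnl = self.posterior["lnL"].to_numpy()
        m = lnl.max()
        return float(m - math.log(np.mean(np.exp(-(lnl - m)))))

    @property
    def ancestral(self) -> pd.DataFrame:
        """Per internal node: mean and 95% HPD on the ln scale and
        exponentiated (mm^2) scale; root is the last row."""
        draws = self._anc[self._cut:]
        rows = []
        st = self.model.struct
        for col, i in enumerate(self.internal_indices):
            vals = draws[:, col]
            lo, hi = hpd_interval(vals)
            rows.append({
                "node": f"node{i}",
                "age": st.nodes[i].age,
                "n_tips": len(self.clades[i]),
                "mean_ln": float(vals.mean()),
                "hpd_lo_ln": lo, "hpd_hi_ln": hi,
                "mean_exp": float(math.exp(vals.mean())),
                "hpd_lo_exp": float(math.exp(lo)),
                "hpd_hi_exp": float(math.exp(hi)),
                "is_root": i == st.n - 1,
            })
        return pd.DataFrame(rows).set_index("node")

    @property
    def root_estimate(self) -> dict:
        df = self.ancestral
        row = df[df["is_root"]].iloc[0]
        return {"mean_ln": row["mean_ln"], "mean_exp": row["mean_exp"],
                "hpd_ln": (row["hpd_lo_ln"], row["hpd_hi_ln"])}

    def summary(self) -> str:
        post = self.posterior
        lines = [f"Trait BM model: {self.model.kind}, "
                 f"transform={self.model.transform}",
                 f"post-burn-in samples: {len(post)}",
                 f"harmonic-mean log marginal likelihood: "
                 f"{self.log_marginal_likelihood:.3f}", ""]
        for col in post.columns:
            if col == "lnL":
                continue
            vals = post[col].to_numpy()
            lo, hi = hpd_interval(vals)
            lines.append(f"  {col:<10s} mean {vals.mean():9.4f}   "
                         f"95% HPD [{lo:9.4f}, {hi:9.4f}]")
        root = self.root_estimate
        lines.append("")
        lines.append(f"  root state  mean {root['mean_ln']:.4f} (ln scale), "
                     f"{root['mean_exp']:.3f} after exponentiation")
        return "\n".join(lines)

    def plot_through_time(self, path=None, other: "TraitResults | None" = None):
        """Size-through-time scatter of reconstructed node states; with a
        second fitted model the per-node disagreement is shaded."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        df = self.ancestral
        fig, ax = plt.subplots(figsize=(5, 6))
        ax.scatter(df["mean_ln"], df["age"], s=18, label=self.model.kind)
        if other is not None:
            df2 = other.ancestral
            ax.scatter(df2["mean_ln"], df2["age"], s=18, marker="s",
                       label=other.model.kind)
            for node in df.index.intersection(df2.index):
                ax.plot([df.loc[node, "mean_ln"], df2.loc[node, "mean_ln"]],
                        [df.loc[node, "age"]] * 2, color="0.6", lw=2, alpha=0.6)
        st = self.model.struct
        tip_ages = [st.nodes[i].age for i in st.leaf_order]
        ax.scatter(self.model.x, tip_ages, s=12, color="k", marker="x",
                   label="tips")
        ax.invert_yaxis()
        ax.set_xlabel("trait (ln scale)")
        ax.set_ylabel("age (Ma)")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def compare_models(results: list[TraitResults]) -> pd.DataFrame:
    """Rank fitted models by harmonic-mean marginal likelihood.

    Reports 2*(delta log ML) against the best model ("log Bayes factor"
    on the conventional 2 ln BF scale: <2 weak, 2-6 positive, 6-10 strong,
    >10 very strong).  Models must share data and tree.
    """
    if len(results) < 2:
        raise ValueError("need at least two fitted models")
    ref = results[0].model
    for r in results[1:]:
        if r.model.tree is not ref.tree or r.model.traits != ref.traits:
            raise ValueError("models were fitted to different data")
    rows = []
    for r in results:
        rows.append({"kind": r.model.kind, "transform": r.model.transform,
                     "log_marginal": r.log_marginal_likelihood})
    df = pd.DataFrame(rows).sort_values("log_marginal", ascending=False)
    best = df["log_marginal"].iloc[0]
    df["two_ln_bf_vs_best"] = 2.0 * (best - df["log_marginal"])

    def band(x):
        if x < 2:
            return "weak"
        if x < 6:
            return "positive"
        if x < 10:
            return "strong"
        return "very strong"

    df["evidence"] = df["two_ln_bf_vs_best"].map(band)
    return df.reset_index(drop=True)
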