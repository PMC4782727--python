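"""Self-validation experiments on synthetic data with known truth.

Each function runs a complete generate-infer-measure experiment at a
stated problem size and returns the measured quantity.  They are the
package's calibration evidence (coverage of credible intervals,
agreement of heuristic search with exhaustive enumeration, prior
recovery by the sampler) and are exercised both by the test suite and
by the reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .matrix import CalibrationTable, recode_polymorphisms
from .mcmc import ChainConfig, run_mcmc, summarize
from .priors import PriorSet
from .simulate import (make_calibrations, simulate_bm_traits,
                       simulate_characters, simulate_fbd_tree)
from .traits import TraitModel
from .trees import Tree

__all__ = [
    "tip_age_coverage",
    "prior_only_ks",
    "parsimony_vs_exhaustive",
    "bm_root_coverage",
    "lambda_recovery",
    "td2_precision_gain",
]

# Study-shaped synthetic regime: moderate diversification with fossil
# sampling over a ~25 Ma window, clock and clock-variance at the scale the
# hyperpriors expect, 10-Ma calibration windows around the true tip ages.
FBD_SIM = dict(lam=0.25, mu=0.15, psi=0.08, rho=0.4, origin_age=25.0)
CHAR_SIM = dict(c=0.25, sigma2=0.05, frac_ordered=0.6,
                k_distribution={2: 0.6, 3: 0.4}, alpha=1.0,
                polymorphism_rate=0.02)


def _study_tree(rng, n_tips=(16, 24), min_tips=14):
    seed = int(rng.integers(2**31))
    while True:
        tree = simulate_fbd_tree(**FBD_SIM, seed=seed, min_tips=min_tips)
        if n_tips[0] <= len(tree.leaves()) <= n_tips[1] and any(
                l.age > 1e-9 for l in tree.leaves()):
            return tree
        seed += 1


def tip_age_coverage(n_replicates: int = 20, seed: int = 0,
                     n_char: int = 200, sweeps: int = 450) -> dict:
    """Fraction of fossil tips whose true age falls in the posterior
    95% HPD, pooled over replicate synthetic datasets (~20 taxa each)."""
    rng = np.random.default_rng(seed)
    covered = total = 0
    for _ in range(n_replicates):
        tree = _study_tree(rng)
        matrix, _ = simulate_characters(tree, n_char=n_char,
                                        seed=int(rng.integers(2**31)),
                                        **CHAR_SIM)
        tip_ages = {l.label: l.age for l in tree.leaves()}
        cal = make_calibrations(tip_ages, window_width=10.0, jitter=0.5,
                                seed=int(rng.integers(2**31)))
        priors = PriorSet(root_min=tree.root.age * 0.75,
                          root_max=tree.root.age * 1.8, rho=FBD_SIM["rho"])
        config = ChainConfig(n_generations=sweeps, n_runs=1, n_chains=1,
                             sample_frequency=4, fossil_removal=True)
        out = run_mcmc(matrix, tree, cal, priors, config,
                       seed=int(rng.integers(2**31)))
        summary = summarize(out)
        for leaf in tree.leaves():
            if leaf.age <= 1e-9:
                continue
            row = summary.tip_ages.loc[leaf.label]
            covered += (row["hpd_lo"] - 1e-9 <= leaf.age
                        <= row["hpd_hi"] + 1e-9)
            total += 1
    return {"coverage": covered / total, "n_tips": total,
            "n_replicates": n_replicates}


def prior_only_ks(seed: int = 0, sweeps: int = 12000) -> dict:
    """Sample the joint prior with the full move set (including chain
    swaps) on a two-fossil cherry and KS-test each marginal against its
    analytic form; thinned to roughly independent draws."""
    topo = Tree.from_newick("(A,B);")
    cal = CalibrationTable({
        "A": {"kind": "uniform", "min_age": 10.0, "max_age": 20.0,
              "locality": None},
        "B": {"kind": "uniform", "min_age": 5.0, "max_age": 15.0,
              "locality": None}})
    priors = PriorSet(root_min=40.0, root_max=50.0)
    config = ChainConfig(n_generations=sweeps, n_runs=1, n_chains=2,
                         sample_frequency=4, likelihood=False,
                         tree_prior=False)
    out = run_mcmc(None, topo, cal, priors, config, seed=seed)
    tr = out.traces[0]
    tr = tr.iloc[int(0.25 * len(tr)):].iloc[::10]
    a = -priors.clock_mean / priors.clock_sd
    pvals = {
        "d": stats.kstest(tr["d"], "expon",
                          args=(0, 1 / priors.speciation_rate)).pvalue,
        "sigma2": stats.kstest(tr["sigma2"], "expon",
                               args=(0, 1 / priors.igrvar_rate)).pvalue,
        "clock_rate": stats.kstest(tr["clock_rate"], "truncnorm",
                                   args=(a, np.inf, priors.clock_mean,
                                         priors.clock_sd)).pvalue,
        "age_A": stats.kstest(tr["age_A"], "uniform", args=(10, 10)).pvalue,
        "age_B": stats.kstest(tr["age_B"], "uniform", args=(5, 10)).pvalue,
        "root_age": stats.kstest(tr["root_age"], "uniform",
                                 args=(40, 10)).pvalue,
    }
    return {k: float(v) for k, v in pvals.items()}


def parsimony_vs_exhaustive(n_instances: int = 20, seed: int = 0,
                            n_taxa: int = 6, n_char: int = 20) -> dict:
    """Heuristic search vs exhaustive enumeration on small instances:
    the heuristic never beats the true optimum and should find it in
    (nearly) every instance."""
    from .parsimony import exhaustive_search, heuristic_search
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_instances):
        m = _random_small_matrix(rng, n_taxa, n_char)
        ex = exhaustive_search(m)
        res = heuristic_search(m, n_reps=5, seed=int(rng.integers(2**31)),
                               compute_indices=False)
        if res.best_score < ex.best_score - 1e-9:
            raise AssertionError("heuristic returned an impossible score "
                                 "below the exhaustive optimum")
        hits += abs(res.best_score - ex.best_score) < 1e-9
    return {"agreement": hits / n_instances, "n_instances": n_instances}


def _random_small_matrix(rng, n_taxa, n_char):
    from .matrix import Cell, CharacterMatrix, STATE, POLY
    taxa = [f"T{i}" for i in range(n_taxa)]
    cells = [[] for _ in taxa]
    flags = []
    for _ in range(n_char):
        k = int(rng.integers(2, 4))
        ordered = bool(rng.random() < 0.5)
        flags.append(ordered)
        for i in range(n_taxa):
            u = rng.random()
            if u < 0.05:
                cells[i].append(Cell("missing"))
            elif u < 0.12 and k >= 2:
                s = int(rng.integers(0, k - 1))
                cells[i].append(Cell(POLY, (s, s + 1)))
            else:
                cells[i].append(Cell(STATE, (int(rng.integers(k)),)))
    return recode_polymorphisms(CharacterMatrix(taxa, cells, flags))


def bm_root_coverage(n_replicates: int = 20, seed: int = 0,
                     n_tips: tuple[int, int] = (25, 40),
                     generations: int = 3000) -> dict:
    """Root-state recovery for the BM trait model: fraction of replicates
    whose 95% HPD for alpha0 covers the simulating value.  Trees are
    study-sized (~25-40 tips) so the lambda transform is identifiable
    enough for the alpha0 interval to be honestly calibrated."""
    rng = np.random.default_rng(seed)
    truth_alpha0 = 1.0
    hits = 0
    from .mcmc import hpd_interval
    for _ in range(n_replicates):
        tree = _study_tree(rng, n_tips=n_tips, min_tips=16)
        tips, _ = simulate_bm_traits(tree, alpha0=truth_alpha0, sigma2_bm=0.08,
                                     lambda_scale=0.8, beta=0.0,
                                     seed=int(rng.integers(2**31)))
        model = TraitModel(tree, tips, kind="random_walk", transform="lambda")
        res = model.fit(n_generations=generations, seed=int(rng.integers(2**31)),
                        sample_ancestral=False, sample_frequency=2)
        lo, hi = hpd_interval(res.posterior["alpha0"].to_numpy())
        hits += lo - 1e-12 <= truth_alpha0 <= hi + 1e-12
    return {"coverage": hits / n_replicates, "n_replicates": n_replicates}


def lambda_recovery(n_replicates: int = 20, seed: int = 0,
                    n_tips: tuple[int, int] = (25, 40),
                    generations: int = 2000) -> dict:
    """Phylogenetic-signal recovery: data simulated at lambda = 1 vs
    lambda = 0 (star) should push the posterior lambda estimate to the
    correct side of 0.5."""
    rng = np.random.default_rng(seed)
    correct = 0
    for rep in range(n_replicates):
        truth = 1.0 if rep % 2 == 0 else 0.0
        tree = _study_tree(rng, n_tips=n_tips, min_tips=16)
        tips, _ = simulate_bm_traits(tree, alpha0=0.5, sigma2_bm=0.12,
                                     lambda_scale=truth, beta=0.0,
                                     seed=int(rng.integers(2**31)))
        model = TraitModel(tree, tips, kind="random_walk", transform="lambda")
        res = model.fit(n_generations=generations,
                        seed=int(rng.integers(2**31)),
                        sample_ancestral=False, sample_frequency=4)
        lam_hat = float(res.posterior["lambda"].mean())
        correct += (lam_hat > 0.5) == (truth > 0.5)
    return {"recovery": correct / n_replicates, "n_replicates": n_replicates}


def td2_precision_gain(seed: int = 0, sweeps: int = 400) -> dict:
    """One TD1 -> locality averaging -> TD2 pass on a synthetic dataset:
    fraction of internal clades whose posterior age s.d. shrinks when tip
    ages are fixed to locality means."""
    from .biochron import locality_average
    from .simulate import assign_localities
    rng = np.random.default_rng(seed)
    tree = _study_tree(rng)
    matrix, _ = simulate_characters(tree, n_char=150,
                                    seed=int(rng.integers(2**31)), **CHAR_SIM)
    tip_ages = {l.label: l.age for l in tree.leaves()}
    localities = assign_localities(tip_ages, 5, int(rng.integers(2**31)))
    cal = make_calibrations(tip_ages, window_width=10.0, jitter=0.5,
                            seed=int(rng.integers(2**31)),
                            locality_map=localities)
    priors = PriorSet(root_min=tree.root.age * 0.75,
                      root_max=tree.root.age * 1.8, rho=FBD_SIM["rho"])
    config = ChainConfig(n_generations=sweeps, n_runs=1, n_chains=1,
                         sample_frequency=4, fossil_removal=True)
    out1 = run_mcmc(matrix, tree, cal, priors, config,
                    seed=int(rng.integers(2**31)))
    s1 = summarize(out1)
    means = {t: float(s1.tip_ages.loc[t, "mean"]) for t in s1.tip_ages.index
             if s1.tip_ages.loc[t, "mean"] > 1e-9}
    fixed = locality_average(means, localities)
    for leaf in tree.leaves():
        if leaf.label not in fixed:
            fixed.entries[leaf.label] = {"kind": "fixed", "fixed_age": 0.0,
                                         "locality": localities.get(leaf.label)}
    out2 = run_mcmc(matrix, tree, fixed, priors, config,
                    seed=int(rng.integers(2**31)))
    samples1 = [s for run in out1.tree_samples
                for s in run[int(0.25 * len(run)):]]
    samples2 = [s for run in out2.tree_samples
                for s in run[int(0.25 * len(run)):]]

    def clade_sds(samples):
        by_clade: dict[frozenset, list[float]] = {}
        for s in samples:
            for clade, age in s.clade_ages.items():
                by_clade.setdefault(clade, []).append(age)
        return {c: float(np.std(v)) for c, v in by_clade.items()
                if len(v) >= 0.9 * len(samples)}

    sd1, sd2 = clade_sds(samples1), clade_sds(samples2)
    shared = sorted(set(sd1) & set(sd2), key=sorted)
    shrunk = sum(sd2[c] <= sd1[c] for c in shared)
    return {"fraction_shrunk": shrunk / len(shared), "n_clades": len(shared)}
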