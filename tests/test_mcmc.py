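"""Sampler correctness: prior recovery, diagnostics, HPDs, summaries."""

import numpy as np
import pandas as pd
import pytest

from tipchron.matrix import CalibrationTable
from tipchron.mcmc import (ChainConfig, MCMCOutput, TreeSample, asdsf,
                           diagnostics, effective_sample_size, hpd_interval,
                           potential_scale_reduction, run_mcmc, summarize)
from tipchron.priors import PriorSet
from tipchron.trees import Tree


@pytest.fixture(scope="module")
def prior_run():
    """Prior-only MC3 run (swaps enabled) on a two-fossil cherry."""
    topo = Tree.from_newick("(A,B);")
    cal = CalibrationTable({
        "A": {"kind": "uniform", "min_age": 10.0, "max_age": 20.0},
        "B": {"kind": "uniform", "min_age": 5.0, "max_age": 15.0}})
    priors = PriorSet(root_min=40.0, root_max=50.0)
    config = ChainConfig(n_generations=8000, n_runs=1, n_chains=2,
                         sample_frequency=4, likelihood=False,
                         tree_prior=False)
    return run_mcmc(None, topo, cal, priors, config, seed=11)


class TestPriorRecovery:
    def test_marginals_match_priors(self, prior_run):
        """With likelihood and tree prior off, the sampler (moves, Hastings
        ratios, chain swaps included) must reproduce the hyperpriors."""
        from scipy import stats
        tr = prior_run.traces[0]
        tr = tr.iloc[int(0.25 * len(tr)):].iloc[::8]
        a = -0.25 / 0.05
        checks = {
            "d": stats.kstest(tr["d"], "expon", args=(0, 1 / 50)).pvalue,
            "sigma2": stats.kstest(tr["sigma2"], "expon",
                                   args=(0, 1 / 3)).pvalue,
            "clock": stats.kstest(tr["clock_rate"], "truncnorm",
                                  args=(a, np.inf, 0.25, 0.05)).pvalue,
            "age_A": stats.kstest(tr["age_A"], "uniform",
                                  args=(10, 10)).pvalue,
            "age_B": stats.kstest(tr["age_B"], "uniform", args=(5, 10)).pvalue,
            "root": stats.kstest(tr["root_age"], "uniform",
                                 args=(40, 10)).pvalue,
        }
        assert all(p > 0.01 for p in checks.values()), checks

    def test_prior_mean_tip_age(self, prior_run):
        tr = prior_run.traces[0].iloc[500:]
        assert tr["age_A"].mean() == pytest.approx(15.0, abs=0.4)

    def test_more_generations_never_hurt_ess(self):
        topo = Tree.from_newick("(A,B);")
        cal = CalibrationTable({
            "A": {"kind": "uniform", "min_age": 10.0, "max_age": 20.0},
            "B": {"kind": "fixed", "fixed_age": 0.0}})
        priors = PriorSet(root_min=40.0, root_max=50.0)
        for seed in (1, 2, 3):
            esses = []
            for gens in (600, 1200):
                config = ChainConfig(n_generations=gens, n_runs=1,
                                     n_chains=1, sample_frequency=2,
                                     likelihood=False, tree_prior=False)
                out = run_mcmc(None, topo, cal, priors, config, seed=seed)
                tr = out.traces[0].iloc[int(0.25 * gens // 2):]
                ess = np.median([effective_sample_size(tr[p].to_numpy())
                                 for p in ("d", "sigma2", "age_A")])
                esses.append(ess)
            assert esses[1] >= esses[0] * 0.9  # allow estimator noise


class TestMoves:
    def test_tip_proposals_respect_windows(self, prior_run):
        tr = prior_run.traces[0]
        assert tr["age_A"].between(10 - 1e-9, 20 + 1e-9).all()
        assert tr["age_B"].between(5 - 1e-9, 15 + 1e-9).all()

    def test_no_valid_state_reports_conflict(self):
        topo = Tree.from_newick("(A,B);")
        cal = CalibrationTable({
            "A": {"kind": "fixed", "fixed_age": 60.0},
            "B": {"kind": "fixed", "fixed_age": 0.0}})
        priors = PriorSet(root_min=40.0, root_max=50.0)
        config = ChainConfig(n_generations=10, n_runs=1, n_chains=1,
                             likelihood=False)
        with pytest.raises(RuntimeError, match="conflicts"):
            run_mcmc(None, topo, cal, priors, config, seed=0)

    def test_generations_validated(self):
        topo = Tree.from_newick("(A,B);")
        cal = CalibrationTable({"A": {"kind": "fixed", "fixed_age": 0.0},
                                "B": {"kind": "fixed", "fixed_age": 0.0}})
        with pytest.raises(ValueError):
            run_mcmc(None, topo, cal, PriorSet(),
                     ChainConfig(n_generations=0), seed=0)


class TestDiagnostics:
    def test_white_noise_ess(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(1000)
        assert 800 <= effective_sample_size(x) <= 1200

    def test_ar1_ess(self):
        rng = np.random.default_rng(8)
        n, phi = 20000, 0.9
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        expected = n * (1 - phi) / (1 + phi)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.3)

    def test_identical_runs_asdsf_zero_psrf_one(self):
        rng = np.random.default_rng(1)
        trace = pd.DataFrame({"gen": range(100),
                              "x": rng.standard_normal(100)})
        samples = [TreeSample({frozenset("AB"): 3.0},
                              {"A": 1.0, "B": 2.0}, {}, 3.0)] * 50
        out = MCMCOutput([trace, trace.copy()], [samples, list(samples)],
                         ChainConfig(n_runs=2), Tree.from_newick("(A,B);"))
        df = diagnostics(out)
        assert df.attrs["asdsf"] == 0.0
        assert df.loc["x", "psrf"] == pytest.approx(1.0, abs=0.02)

    def test_asdsf_disagreement(self):
        s1 = [TreeSample({frozenset("AB"): 1.0}, {}, {}, 1.0)] * 10
        s2 = [TreeSample({frozenset("AC"): 1.0}, {}, {}, 1.0)] * 10
        # each split present in one run only: frequency s.d. of {1,0} = 0.5
        assert asdsf([s1, s2]) == pytest.approx(0.5)


class TestHPD:
    def test_uniform_width(self):
        rng = np.random.default_rng(3)
        lo, hi = hpd_interval(rng.uniform(0, 1, 10_000))
        assert (hi - lo) == pytest.approx(0.95, abs=0.01)

    def test_degenerate_sample(self):
        lo, hi = hpd_interval(np.full(50, 7.3))
        assert lo == hi == 7.3

    def test_shortest_property(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(2000)
        lo, hi = hpd_interval(x, 0.9)
        # symmetric unimodal: HPD approximates the central interval
        q = np.quantile(x, [0.05, 0.95])
        assert hi - lo <= (q[1] - q[0]) + 0.05


class TestSummarize:
    def _mk_output(self, samples, n_runs=1):
        trace = pd.DataFrame({"gen": range(len(samples)),
                              "clock_rate": np.linspace(0.2, 0.3,
                                                        len(samples))})
        cfg = ChainConfig(n_runs=n_runs, burn_in=0.0)
        return MCMCOutput([trace] * n_runs, [samples] * n_runs, cfg,
                          Tree.from_newick("((A,B),C);"))

    def test_identical_samples_zero_width(self):
        s = TreeSample({frozenset("AB"): 4.0, frozenset("ABC"): 9.0},
                       {"A": 1.0, "B": 2.0, "C": 0.0}, {}, 9.0)
        out = self._mk_output([s] * 20)
        summ = summarize(out, burn_in=0.0)
        assert summ.tip_ages.loc["A", "hpd_lo"] == summ.tip_ages.loc["A", "hpd_hi"] == 1.0
        assert summ.clade_pp[frozenset("AB")] == 1.0
        assert summ.clade_median_age[frozenset("AB")] == 4.0

    def test_clade_pp_matches_counts(self):
        ab = TreeSample({frozenset("AB"): 4.0, frozenset("ABC"): 9.0},
                        {"A": 1.0, "B": 2.0, "C": 0.0}, {}, 9.0)
        ac = TreeSample({frozenset("AC"): 5.0, frozenset("ABC"): 9.0},
                        {"A": 1.0, "B": 2.0, "C": 0.0}, {}, 9.0)
        out = self._mk_output([ab, ab, ab, ac])
        summ = summarize(out, burn_in=0.0)
        assert summ.clade_pp[frozenset("AB")] == pytest.approx(0.75)
        assert frozenset("AC") not in summ.clade_pp
        labels = {n.label for n in summ.consensus.leaves()}
        assert labels == {"A", "B", "C"}

    def test_order_invariance_and_pooling(self):
        rng = np.random.default_rng(9)
        samples = []
        for _ in range(30):
            age = float(rng.uniform(3, 5))
            samples.append(TreeSample({frozenset("AB"): age,
                                       frozenset("ABC"): age + 3},
                                      {"A": 1.0, "B": 2.0, "C": 0.0}, {},
                                      age + 3))
        out1 = self._mk_output(samples)
        out2 = self._mk_output(samples[::-1])
        s1 = summarize(out1, burn_in=0.0)
        s2 = summarize(out2, burn_in=0.0)
        assert s1.clade_median_age == s2.clade_median_age
        assert s1.tip_ages.equals(s2.tip_ages)

    def test_empty_post_burn_in_rejected(self):
        s = TreeSample({frozenset("ABC"): 9.0},
                       {"A": 1.0, "B": 2.0, "C": 0.0}, {}, 9.0)
        out = self._mk_output([s])
        with pytest.raises(ValueError):
            summarize(out, burn_in=1.0)


class TestConjugateSanity:
    def test_normal_mean_posterior(self):
        """MH machinery recovers the analytic posterior of a normal mean
        with (effectively) known variance: star phylogeny, iid tips."""
        from tipchron.traits import TraitModel, _TraitPriors
        rng = np.random.default_rng(6)
        n, depth, sigma2 = 12, 1.0, 0.25
        newick = "(" + ",".join(f"T{i}:1.0" for i in range(n)) + ");"
        tree = Tree.from_newick(newick)
        for node in tree.postorder():
            node.age = 0.0 if node.is_leaf else depth
        x = rng.normal(0.7, np.sqrt(sigma2 * depth), n)
        traits = {f"T{i}": float(x[i]) for i in range(n)}
        ln_s2 = np.log(sigma2)
        priors = _TraitPriors(ln_sigma2_range=(ln_s2 - 1e-6, ln_s2 + 1e-6))
        model = TraitModel(tree, traits, kind="random_walk",
                           transform="none", priors=priors)
        res = model.fit(n_generations=4000, seed=2, sample_ancestral=False)
        post = res.posterior["alpha0"].to_numpy()
        exact_mean = x.mean()
        exact_sd = np.sqrt(sigma2 * depth / n)
        mc_se = exact_sd / np.sqrt(effective_sample_size(post))
        assert post.mean() == pytest.approx(exact_mean, abs=3 * mc_se + 0.01)
        assert post.std() == pytest.approx(exact_sd, rel=0.25)
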