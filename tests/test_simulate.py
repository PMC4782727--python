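"""Synthetic-data generator: tree process, characters, windows, traits."""

import numpy as np
import pytest
from scipy import stats

from tipchron.matrix import POLY
from tipchron.mk import transition_matrices
from tipchron.simulate import (_try_simulate, assign_localities,
                               make_calibrations, paperlike_dataset,
                               simulate_bm_traits, simulate_characters,
                               simulate_fbd_tree)
from tipchron.trees import Tree


class TestFBDTree:
    def test_pure_birth_no_fossils(self):
        tree = simulate_fbd_tree(0.3, 0.0, 0.0, 1.0, 12.0, seed=1)
        assert all(l.age == 0.0 for l in tree.leaves())

    def test_extant_count_matches_branching_expectation(self):
        lam, mu, origin = 0.35, 0.15, 10.0
        rng = np.random.default_rng(7)
        counts = []
        for _ in range(500):
            t = _try_simulate(lam, mu, 0.0, 1.0, origin, rng, 1)
            counts.append(0 if t is None else len(t.leaves()))
        expected = np.exp((lam - mu) * origin)
        se = np.std(counts) / np.sqrt(len(counts))
        assert np.mean(counts) == pytest.approx(expected, abs=4 * se)

    def test_fossil_count_increases_with_psi(self):
        rng1, rng2 = np.random.default_rng(3), np.random.default_rng(4)
        def mean_fossils(psi, rng):
            out = []
            for _ in range(300):
                t = _try_simulate(0.3, 0.1, psi, 1.0, 10.0, rng, 1)
                if t is None:
                    out.append(0)
                else:
                    out.append(sum(1 for l in t.leaves() if l.age > 1e-9))
            return np.array(out)
        lo, hi = mean_fossils(0.05, rng1), mean_fossils(0.10, rng2)
        test = stats.ttest_ind(hi, lo, alternative="greater")
        assert test.pvalue < 0.01

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            simulate_fbd_tree(0.1, 0.2, 0.0, 1.0, 10.0, seed=0)
        with pytest.raises(ValueError):
            simulate_fbd_tree(0.3, 0.1, -0.1, 1.0, 10.0, seed=0)

    def test_fossils_are_terminal_and_ages_consistent(self):
        tree = simulate_fbd_tree(0.3, 0.15, 0.1, 0.5, 15.0, seed=9,
                                 min_tips=6)
        for node in tree.postorder():
            if node.parent is not None:
                assert node.parent.age > node.age - 1e-12


@pytest.fixture(scope="module")
def char_tree():
    return simulate_fbd_tree(0.3, 0.15, 0.08, 0.5, 15.0, seed=2, min_tips=8)


class TestCharacters:

    def test_no_polymorphisms_at_rate_zero(self, char_tree):
        tree = char_tree
        m, _ = simulate_characters(tree, 0.2, 0.02, 30, 0.7, {2: 1.0}, 1.0,
                                   0.0, seed=1)
        assert all(c.kind != POLY for row in m.cells for c in row)

    def test_no_constant_characters(self, char_tree):
        tree = char_tree
        m, _ = simulate_characters(tree, 0.2, 0.02, 40, 0.5, {2: 0.5, 3: 0.5},
                                   1.0, 0.05, seed=2)
        assert m.classification["n_constant"] == 0
        assert m.n_char == 40

    def test_strict_clock_effective_lengths(self, char_tree):
        tree = char_tree
        m, true_v = simulate_characters(tree, 0.2, 0.0, 10, 0.5, {2: 1.0},
                                        np.inf, 0.0, seed=3)
        nodes = list(tree.postorder())
        below = {}
        for n in nodes:
            if n.is_leaf:
                below[id(n)] = frozenset([n.label])
            else:
                below[id(n)] = frozenset().union(*(below[id(c)]
                                                   for c in n.children))
        for n in nodes:
            if n.parent is None:
                continue
            t = n.parent.age - n.age
            assert true_v[below[id(n)]] == pytest.approx(0.2 * t, abs=1e-12)

    def test_three_tip_pattern_frequencies_match_model(self):
        """Counting oracle: under a strict clock with homogeneous rates,
        simulated variable-pattern frequencies on a 3-tip tree follow the
        conditional (variable-coding) pattern probabilities computed by
        the pruning likelihood; checked with a chi-square test."""
        import itertools
        from tipchron.mk import MkLikelihood, MkModel, TopologyIndex
        from test_mk import pattern_matrix
        t = Tree.from_newick("((A,B),C);")
        for leaf in t.leaves():
            leaf.age = 0.0
        internals = [n for n in t.postorder() if not n.is_leaf]
        internals[0].age, internals[1].age = 3.0, 8.0
        n = 3000
        m, _ = simulate_characters(t, 0.1, 0.0, n, 0.0, {2: 1.0}, np.inf,
                                   0.0, seed=5)
        taxa = {lab: i for i, lab in enumerate(m.taxa)}
        counts: dict[tuple, int] = {}
        for j in range(n):
            pat = tuple(m.recoded[taxa[lab]][j] for lab in ("A", "B", "C"))
            counts[pat] = counts.get(pat, 0) + 1
        pats = [p for p in itertools.product(range(2), repeat=3)
                if len(set(p)) > 1]
        # no-gamma pruning probabilities, conditioned on variable
        pm = pattern_matrix("ABC", pats, k=2)
        lik = MkLikelihood(pm, t, MkModel(coding="variable",
                                          n_gamma_categories=1))
        top = lik.top
        v = np.array([0.1 * (t_.parent.age - t_.age) if t_.parent else 0.0
                      for t_ in top.nodes])
        probs = np.exp(lik.loglik(v, gamma_shape=1.0, per_character=True))
        # patterns and their mirror (state relabeling) are distinct here
        observed = np.array([counts.get(p, 0) for p in pats])
        chi = stats.chisquare(observed, probs * n)
        assert chi.pvalue > 0.01


class TestCalibrationsAndLocalities:
    def test_zero_jitter_centering(self):
        cal = make_calibrations({"F1": 12.0}, window_width=4.0, jitter=0.0,
                                seed=0)
        assert cal.bounds("F1") == (10.0, 14.0)

    def test_windows_always_contain_truth(self):
        rng = np.random.default_rng(1)
        for i in range(1000):
            age = float(rng.uniform(0.01, 40))
            cal = make_calibrations({"F": age}, window_width=6.0,
                                    jitter=1.0, seed=i)
            lo, hi = cal.bounds("F")
            assert lo - 1e-9 <= age <= hi + 1e-9

    def test_extant_fixed_at_zero(self):
        cal = make_calibrations({"E1": 0.0, "F1": 5.0}, 4.0, 0.5, seed=2)
        assert cal["E1"]["kind"] == "fixed"
        assert cal["E1"]["fixed_age"] == 0.0

    def test_locality_mean_bookkeeping(self):
        ages = {"F1": 10.0, "F2": 11.0, "F3": 30.0, "F4": 31.0, "E1": 0.0}
        mapping = assign_localities(ages, 2, seed=0)
        assert mapping["E1"] == "RECENT"
        from tipchron.biochron import locality_estimates
        fossil_ages = {t: a for t, a in ages.items() if a > 0}
        ests = {e.locality: e for e in locality_estimates(
            fossil_ages, {t: mapping[t] for t in fossil_ages})}
        for est in ests.values():
            assert est.mean_age == pytest.approx(
                np.mean([fossil_ages[t] for t in est.tips]))
        # localities group similar ages
        assert mapping["F1"] == mapping["F2"]
        assert mapping["F3"] == mapping["F4"]
        assert mapping["F1"] != mapping["F3"]


@pytest.fixture(scope="module")
def bm_tree():
    return simulate_fbd_tree(0.3, 0.1, 0.08, 0.6, 12.0, seed=6, min_tips=5)


class TestBMTraits:

    def test_degenerate_variance(self, bm_tree):
        tree = bm_tree
        tips, anc = simulate_bm_traits(tree, alpha0=0.7, sigma2_bm=0.0,
                                       lambda_scale=1.0, beta=0.0, seed=1)
        assert all(v == pytest.approx(0.7) for v in tips.values())
        tips_d, _ = simulate_bm_traits(tree, alpha0=0.7, sigma2_bm=0.0,
                                       lambda_scale=1.0, beta=0.1, seed=1)
        root_age = tree.root.age
        for leaf in tree.leaves():
            expected = 0.7 + 0.1 * (root_age - leaf.age)
            assert tips_d[leaf.label] == pytest.approx(expected)

    def test_sample_covariance_matches_theory(self):
        t = Tree.from_newick("((A,B),C);")
        for node, age in zip(t.postorder(), []):
            pass
        ages = {"A": 0.0, "B": 1.0, "C": 0.0}
        internals = [n for n in t.postorder() if not n.is_leaf]
        for leaf in t.leaves():
            leaf.age = ages[leaf.label]
        internals[0].age, internals[1].age = 4.0, 9.0
        from tipchron.traits import tip_covariance
        C, labels = tip_covariance(t, "lambda", 0.8)
        draws = np.array([list(simulate_bm_traits(t, 0.0, 0.5, 0.8, 0.0,
                                                  seed=s)[0][l]
                               for l in labels)
                          for s in range(2000)])
        sample_cov = np.cov(draws.T)
        assert np.allclose(sample_cov, 0.5 * C,
                           atol=0.05 * np.max(0.5 * C))

    def test_star_independence(self, bm_tree):
        tree = bm_tree
        draws = []
        labels = sorted(l.label for l in tree.leaves())
        for s in range(600):
            tips, _ = simulate_bm_traits(tree, 0.0, 0.3, 0.0, 0.0, seed=s)
            draws.append([tips[l] for l in labels])
        draws = np.array(draws)
        corr = np.corrcoef(draws.T)
        off = corr[~np.eye(len(labels), dtype=bool)]
        assert np.abs(off).max() < 0.15


class TestReproducibility:
    def test_same_seed_same_dataset(self):
        m1, t1, c1, l1, tr1, truth1 = paperlike_dataset(5, n_char=30,
                                                        target_tips=12)
        m2, t2, c2, l2, tr2, truth2 = paperlike_dataset(5, n_char=30,
                                                        target_tips=12)
        assert m1 == m2
        assert t1.to_newick() == t2.to_newick()
        assert c1 == c2 and l1 == l2 and tr1 == tr2
        assert truth1.tip_ages == truth2.tip_ages

    def test_shape_matches_request(self):
        m, tree, cal, locmap, traits, truth = paperlike_dataset(
            8, n_char=30, target_tips=12)
        assert m.n_char == 30
        assert abs(len(tree.leaves()) - 12) <= 6
        assert set(m.taxa) == set(traits)
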