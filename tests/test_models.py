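"""Migration models: constraints, pruning likelihood, MCMC, stepping stone."""

import math

import numpy as np
import pytest

import phylogeo_gec as pg
from phylogeo_gec.models import stepping_stone_betas

from conftest import random_generator_matrix, random_regions, random_timed_tree


# -- oracles -----------------------------------------------------------------

def symmetric_p(r, t, k=3):
    """Closed-form k-state symmetric transition probabilities."""
    same = 1.0 / k + (1 - 1.0 / k) * math.exp(-k * r * t)
    diff = 1.0 / k - (1.0 / k) * math.exp(-k * r * t)
    return same, diff


def enumeration_loglik(tree, regions, Q, root_prior, states=pg.DEFAULT_STATES):
    """Likelihood by summing over all internal-node state assignments."""
    from itertools import product

    from scipy.linalg import expm

    k = len(states)
    P = {i: expm(Q * tree.lengths[i]) for i in range(tree.n_nodes)
         if tree.parent[i] >= 0}
    internal = [i for i in range(tree.n_nodes) if tree.children[i]]
    tip_state = {i: states.index(regions[tree.labels[i]]) for i in tree.tip_indices}

    def conditional(root_state):
        total = 0.0
        for combo in product(range(k), repeat=len(internal)):
            assign = dict(zip(internal, combo))
            if assign[tree.root] != root_state:
                continue
            assign.update(tip_state)
            term = 1.0
            for i in range(tree.n_nodes):
                p = tree.parent[i]
                if p >= 0:
                    term *= P[i][assign[p], assign[i]]
            total += term
        return total

    per_root = np.array([conditional(s) for s in range(k)])
    if root_prior.kind == "equal":
        val = per_root.mean()
    elif root_prior.kind == "fixed":
        val = per_root[states.index(root_prior.state)]
    else:
        tot = per_root.sum()
        val = float(per_root @ (per_root / tot)) if tot > 0 else 0.0
    return math.log(val) if val > 0 else -math.inf


# -- model construction ------------------------------------------------------

class TestBuildModel:
    def test_saturated_has_six_parameters(self):
        assert pg.bundled_models()["all"].n_params == 6

    def test_null_has_one_parameter(self):
        assert pg.bundled_models()["null"].n_params == 1

    def test_model9_ties_wallacea_new_guinea_exchange(self):
        m9 = pg.bundled_models()["m9"]
        assert m9.n_params == 2
        q = m9.q_matrix([1.0, 2.0])
        # tied PAP<->WLC rates equal; WLC>AUS separate; others zero
        assert q[1, 2] == q[2, 1]
        assert q[2, 0] != q[1, 2]
        assert q[0, 1] == q[0, 2] == q[1, 0] == 0.0

    def test_q_matrix_structure(self):
        m = pg.build_model({"AUS>PAP": "free", "PAP>AUS": "tie:g",
                            "WLC>PAP": "tie:g"})
        assert m.n_params == 2
        q = m.q_matrix([0.3, 0.7])
        np.testing.assert_allclose(q.sum(axis=1), 0.0, atol=1e-15)
        assert q[1, 0] == q[2, 1] == 0.7 and q[0, 1] == 0.3

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            pg.build_model({})

    def test_unknown_pair_rejected(self):
        with pytest.raises(ValueError):
            pg.build_model({"AUS>XYZ": "free"})


# -- likelihood --------------------------------------------------------------

class TestLogLikelihood:
    def test_zero_generator_same_state(self, simple_tree):
        regions = pg.TipRegionMap({t: "WLC" for t in "ABC"})
        ll = pg.log_likelihood(simple_tree, regions, np.zeros((3, 3)))
        assert ll == pytest.approx(math.log(1 / 3))

    def test_zero_generator_mixed_states_impossible(self, simple_tree, regions_ab_wlc):
        ll = pg.log_likelihood(simple_tree, regions_ab_wlc, np.zeros((3, 3)))
        assert ll == -math.inf

    def test_two_tip_symmetric_closed_form(self):
        """(A:1,B:1); both tips state 1, null rate r: sum_j (1/3) P(j->1)^2."""
        tree = pg.TimedTree(parent=[-1, 0, 0], lengths=[0.0, 1.0, 1.0],
                            labels=[None, "A", "B"])
        regions = pg.TipRegionMap({"A": "AUS", "B": "AUS"})
        r = 0.1
        same, diff = symmetric_p(r, 1.0)
        oracle = (1 / 3) * (same**2 + 2 * diff**2)
        q = pg.bundled_models()["null"].q_matrix([r])
        assert pg.log_likelihood(tree, regions, q) == pytest.approx(
            math.log(oracle), rel=1e-12)

    def test_null_model_matches_closed_form_on_any_tree(self):
        """Symmetric-model pruning equals a closed-form-P recursion."""
        rng = np.random.default_rng(31)
        null = pg.bundled_models()["null"]
        for _ in range(5):
            tree = random_timed_tree(rng, 8)
            regions = random_regions(rng, tree)
            r = 10 ** rng.uniform(-5.5, -3.5)
            q = null.q_matrix([r])
            # oracle: plain recursion using the closed-form matrix
            def p_mat(t):
                same, diff = symmetric_p(r, t)
                return np.full((3, 3), diff) + np.eye(3) * (same - diff)

            def partial(node):
                if not tree.children[node]:
                    out = np.zeros(3)
                    out[regions.state_index(tree.labels[node])] = 1.0
                    return out
                acc = np.ones(3)
                for c in tree.children[node]:
                    acc = acc * (p_mat(tree.lengths[c]) @ partial(c))
                return acc

            oracle = math.log(partial(tree.root).mean())
            assert pg.log_likelihood(tree, regions, q) == pytest.approx(
                oracle, rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("prior", [pg.RootPrior("equal"),
                                       pg.RootPrior("empirical"),
                                       pg.RootPrior("fixed", "PAP")])
    def test_matches_enumeration_on_small_trees(self, prior):
        rng = np.random.default_rng(32)
        for _ in range(10):
            tree = random_timed_tree(rng, int(rng.integers(3, 7)))
            regions = random_regions(rng, tree)
            q = random_generator_matrix(rng, scale=2.0 / tree.root_age)
            got = pg.log_likelihood(tree, regions, q, prior)
            want = enumeration_loglik(tree, regions, q, prior)
            if math.isinf(want):
                assert math.isinf(got)
            else:
                assert got == pytest.approx(want, rel=1e-10)

    def test_invariant_to_child_order(self):
        rng = np.random.default_rng(33)
        tree = random_timed_tree(rng, 10)
        regions = random_regions(rng, tree)
        q = random_generator_matrix(rng, scale=1.0 / tree.root_age)
        base = pg.log_likelihood(tree, regions, q)
        # rebuild with children visited in reversed index order
        order = list(range(tree.n_nodes))[::-1]
        pos = {old: new for new, old in enumerate(order)}
        flipped = pg.TimedTree(
            parent=[pos[tree.parent[o]] if tree.parent[o] >= 0 else -1 for o in order],
            lengths=[tree.lengths[o] for o in order],
            labels=[tree.labels[o] for o in order],
        )
        assert pg.log_likelihood(flipped, regions, q) == pytest.approx(base, rel=1e-12)

    def test_invariant_to_zero_length_root_stalk(self):
        """Adding a zero-length edge above the root changes nothing."""
        rng = np.random.default_rng(34)
        tree = random_timed_tree(rng, 8)
        regions = random_regions(rng, tree)
        q = random_generator_matrix(rng, scale=1.0 / tree.root_age)
        stalked = pg.TimedTree(
            parent=[-1] + [p + 1 if p >= 0 else 0 for p in tree.parent],
            lengths=[0.0] + list(tree.lengths),
            labels=[None] + list(tree.labels),
        )
        assert pg.log_likelihood(stalked, regions, q) == pytest.approx(
            pg.log_likelihood(tree, regions, q), rel=1e-12)

    def test_invalid_generator_rejected(self, simple_tree, regions_ab_wlc):
        with pytest.raises(ValueError):
            pg.log_likelihood(simple_tree, regions_ab_wlc, np.ones((3, 3)))


# -- MCMC --------------------------------------------------------------------

class TestFitMCMC:
    settings = pg.MCMCSettings(iterations=600, burnin=150, thin=3, seed=5)

    def test_same_seed_same_samples(self, small_dataset):
        null = pg.bundled_models()["null"]
        a = pg.fit_mcmc(small_dataset.tree, small_dataset.regions, null,
                        settings=self.settings)
        b = pg.fit_mcmc(small_dataset.tree, small_dataset.regions, null,
                        settings=self.settings)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_uniform_tips_concentrate_below_prior_median(self):
        """All tips one state: likelihood decreasing in rate, so the
        posterior median falls below the prior median."""
        tree = pg.TimedTree.from_newick(
            "((A:1000,B:1000):1000,(C:1000,D:1000):1000);")
        regions = pg.TipRegionMap({t: "PAP" for t in "ABCD"})
        null = pg.bundled_models()["null"]
        fit = pg.fit_mcmc(tree, regions, null, settings=self.settings)
        prior_median = math.log(2) / tree.root_age  # Exp(mean 1/root_age)
        assert np.median(fit.samples) < prior_median

    def test_root_posterior_sums_to_one(self, small_dataset):
        fit = pg.fit_mcmc(small_dataset.tree, small_dataset.regions,
                          pg.bundled_models()["m9"], settings=self.settings)
        assert fit.root_state_posterior.sum() == pytest.approx(1.0)

    def test_low_ess_flagged_not_fatal(self, small_dataset):
        tiny = pg.MCMCSettings(iterations=60, burnin=20, thin=1, seed=1,
                               min_ess=1000.0)
        fit = pg.fit_mcmc(small_dataset.tree, small_dataset.regions,
                          pg.bundled_models()["null"], settings=tiny)
        assert fit.warnings and "effective sample size" in fit.warnings[0]


# -- stepping stone ----------------------------------------------------------

class TestSteppingStone:
    def test_beta_schedule_concentrates_near_prior(self):
        betas = stepping_stone_betas(10)
        assert betas[0] == 0.0 and betas[-1] == 1.0
        assert np.all(np.diff(betas) > 0)
        assert np.sum(betas < 0.1) > np.sum(betas > 0.9)

    def test_point_mass_prior_returns_loglik(self, small_dataset):
        null = pg.bundled_models()["null"]
        r = 1e-4
        ss = pg.marginal_likelihood_stepping_stone(
            small_dataset.tree, small_dataset.regions, null,
            prior=pg.PointMassPrior((r,)))
        want = pg.log_likelihood(small_dataset.tree, small_dataset.regions,
                                 null.q_matrix([r]))
        assert ss.log_marginal == pytest.approx(want)

    def test_matches_quadrature_within_3_se(self):
        from scipy.integrate import quad

        cfg = pg.SimulationConfig(n_tips=8, seed=12, n_posterior=1)
        tree = pg.simulate_tree(cfg)
        regions, _ = pg.evolve_trait(tree, cfg.Q_true, "WLC", seed=13)
        null = pg.bundled_models()["null"]
        engine = pg.PruningEngine(tree, regions)
        mean = 1.0 / tree.root_age

        def integrand(r):
            ll = engine.log_likelihood(null.q_matrix([r]), pg.RootPrior("equal"))
            return math.exp(ll - r / mean) / mean

        val, _ = quad(integrand, 0, 200 * mean, limit=400)
        ss = pg.marginal_likelihood_stepping_stone(
            tree, regions, null, stones=25, iterations_per_stone=250, seed=3)
        assert abs(ss.log_marginal - math.log(val)) < 3 * ss.se

    def test_more_stones_reduce_variance(self):
        """Doubling the stone count roughly halves estimator variance."""
        cfg = pg.SimulationConfig(n_tips=8, seed=12, n_posterior=1)
        tree = pg.simulate_tree(cfg)
        regions, _ = pg.evolve_trait(tree, cfg.Q_true, "WLC", seed=13)
        null = pg.bundled_models()["null"]
        coarse, fine = [], []
        for seed in range(20):
            coarse.append(pg.marginal_likelihood_stepping_stone(
                tree, regions, null, stones=4, iterations_per_stone=60,
                seed=seed).log_marginal)
            fine.append(pg.marginal_likelihood_stepping_stone(
                tree, regions, null, stones=8, iterations_per_stone=60,
                seed=100 + seed).log_marginal)
        assert np.var(fine) < 0.85 * np.var(coarse)


# -- Bayes factors -----------------------------------------------------------

class TestBayesFactor:
    def test_equal_marginals_weak(self):
        report = pg.bayes_factor(-10.0, -10.0)
        assert report.bf == 0.0 and report.category == "weak"

    def test_log10_gap_1p5_is_strong(self):
        report = pg.bayes_factor(-8.5, -10.0, "a", "b")
        assert report.bf == pytest.approx(3.0)
        assert report.category == "strong" and report.model_j == "a"

    def test_log10_gap_2p6_is_very_strong(self):
        report = pg.bayes_factor(-10.0, -7.4, "a", "b")
        assert report.bf == pytest.approx(5.2)
        assert report.category == "very strong" and report.model_j == "b"
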