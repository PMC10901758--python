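import numpy as np
import pytest

import phyloconv as pc
from phyloconv.errors import LikelihoodError
from phyloconv.likelihood import TreeLikelihood, transition_probabilities
from phyloconv.seqio import AA_STATES

from conftest import make_aln


def equal_rates_model(gamma=None, k=1):
    S = np.ones((20, 20))
    np.fill_diagonal(S, 0.0)
    return pc.SubstitutionModel(
        "WAG", "aa", AA_STATES, S, np.full(20, 0.05),
        gamma_shape=gamma, n_rate_categories=k,
    )


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self, wag):
        P = transition_probabilities(wag, 0.0)
        assert np.abs(P - np.eye(20)).max() < 1e-10

    @pytest.mark.parametrize("t", [0.05, 0.3, 1.0, 3.0])
    def test_equal_rates_closed_form(self, t):
        """K-state equal-rates chain: P_same = 1/K + (1-1/K) e^{-Kt/(K-1)}."""
        P = transition_probabilities(equal_rates_model(), t)
        expected = 1 / 20 + (19 / 20) * np.exp(-20 * t / 19)
        assert np.abs(np.diag(P) - expected).max() < 1e-12

    def test_long_branch_reaches_stationarity(self, wag):
        P = transition_probabilities(wag, 500.0)
        assert np.abs(P - wag.frequencies[None, :]).max() < 1e-8

    def test_rows_sum_to_one_nonnegative(self, wag):
        P = transition_probabilities(wag, 0.37, rate=2.4)
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-10
        assert P.min() >= 0

    def test_negative_time_rejected(self, wag):
        with pytest.raises(LikelihoodError):
            transition_probabilities(wag, -0.1)


def brute_force_site_logliks(aln, model, t_tips, t_internal):
    """4-taxon tree ((A,B):u,(C,D):v); sum over all internal state pairs."""
    pi = model.frequencies
    idx = {a: i for i, a in enumerate(model.states)}
    tA, tB, tC, tD = t_tips
    tU, tV = t_internal
    out = []
    for s in range(aln.n_columns):
        obs = [idx[aln.columns[i, s]] for i in range(4)]
        tot = 0.0
        for r in model.category_rates:
            PA = transition_probabilities(model, tA, r)
            PB = transition_probabilities(model, tB, r)
            PC = transition_probabilities(model, tC, r)
            PD = transition_probabilities(model, tD, r)
            PU = transition_probabilities(model, tU, r)
            PV = transition_probabilities(model, tV, r)
            L = 0.0
            for u in range(20):
                for v in range(20):
                    L += (
                        float(pi @ (PU[:, u] * PV[:, v]))
                        * PA[u, obs[0]] * PB[u, obs[1]]
                        * PC[v, obs[2]] * PD[v, obs[3]]
                    )
            tot += L / len(model.category_rates)
        out.append(np.log(tot))
    return np.array(out)


class TestSiteLogLikelihoods:
    def test_all_gap_column_has_probability_one(self, wag):
        aln = make_aln({"A": "-", "B": "-"})
        tree = pc.parse_newick("(A:0.1,B:0.2);")
        assert pc.site_log_likelihoods(aln, tree, wag)[0] == pytest.approx(0.0)

    def test_two_taxa_zero_length_identical_residue(self, wag):
        aln = make_aln({"A": "W", "B": "W"})
        tree = pc.parse_newick("(A:0.0,B:0.0);")
        lw = pc.site_log_likelihoods(aln, tree, wag)[0]
        pi_w = wag.frequencies[AA_STATES.index("W")]
        assert lw == pytest.approx(np.log(pi_w), abs=1e-10)

    def test_pruning_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        model = pc.build_model("WAG", gamma_shape=0.7, n_categories=4)
        cols = rng.choice(list(AA_STATES), size=(4, 8))
        aln = pc.Alignment(["A", "B", "C", "D"], cols, "aa", "g")
        tree = pc.parse_newick("((A:0.12,B:0.3):0.08,(C:0.2,D:0.45):0.1);")
        fast = pc.site_log_likelihoods(aln, tree, model)
        slow = brute_force_site_logliks(
            aln, model, (0.12, 0.3, 0.2, 0.45), (0.08, 0.1)
        )
        assert np.abs(fast - slow).max() < 1e-10

    def test_taxon_mismatch_rejected(self, wag):
        aln = make_aln({"A": "M", "Z": "M"})
        with pytest.raises(LikelihoodError):
            pc.site_log_likelihoods(aln, pc.parse_newick("(A:0.1,B:0.1);"), wag)

    def test_pulley_principle(self, wag, sim_tree):
        """Reversible model: total lnL invariant to root placement."""
        aln = pc.simulate_alignment(sim_tree, wag, 50, seed=2)
        aln = pc.Alignment(aln.taxon_ids[:4], aln.columns[:4], "aa", "g4")
        r1 = pc.parse_newick("((tgtA:0.1,bg1:0.2):0.05,(tgtB:0.3,bg2:0.4):0.07);")
        r2 = pc.parse_newick("(tgtA:0.02,((tgtB:0.3,bg2:0.4):0.12,bg1:0.2):0.08);")
        l1 = pc.site_log_likelihoods(aln, r1, wag).sum()
        l2 = pc.site_log_likelihoods(aln, r2, wag).sum()
        assert l1 == pytest.approx(l2, abs=1e-8)


class TestFitGene:
    def test_identical_sequences_zero_branches(self, wag):
        aln = make_aln({"A": "MKVWRI" * 10, "B": "MKVWRI" * 10})
        fit = pc.fit_gene(aln, pc.parse_newick("(A,B);"), wag)
        assert np.nansum(fit.lengths) < 1e-5

    def test_ssls_additivity(self, small_fit):
        assert small_fit.site_logliks.sum() == pytest.approx(
            small_fit.total_loglik, abs=1e-6
        )

    def test_refit_is_fixed_point(self, small_fit):
        eng = small_fit.engine
        again = eng.loglik(small_fit.lengths, small_fit.model.gamma_shape)
        assert again == pytest.approx(small_fit.total_loglik, abs=1e-6)

    def test_fit_deterministic(self, sim_tree, wag):
        aln = pc.simulate_alignment(sim_tree, wag, 80, seed=5)
        spec = lambda: pc.build_model("WAG", gamma_shape=1.0, n_categories=4)
        f1 = pc.fit_gene(aln, sim_tree, spec())
        f2 = pc.fit_gene(aln, sim_tree, spec())
        assert f1.total_loglik == f2.total_loglik
        assert np.array_equal(
            np.nan_to_num(f1.lengths), np.nan_to_num(f2.lengths)
        )

    def test_alpha_within_bounds(self, small_fit):
        assert 0.02 <= small_fit.model.gamma_shape <= 100.0
        assert np.nanmax(small_fit.lengths) <= 20.0


class TestAncestralReconstruction:
    def test_posteriors_normalized(self, small_fit):
        rec = pc.marginal_ancestral_states(small_fit)
        sums = rec.posterior.sum(axis=1)
        assert np.abs(sums - 1.0).max() < 1e-9

    def test_conserved_column_maps_to_shared_residue(self, wag):
        aln = make_aln({t: "W" * 30 for t in ["A", "B", "C", "D"]})
        tree = pc.parse_newick("((A:0.01,B:0.01):0.01,(C:0.01,D:0.01):0.01);")
        fit = pc.fit_gene(aln, tree, wag)
        rec = pc.marginal_ancestral_states(fit)
        w_idx = AA_STATES.index("W")
        for v in range(rec.ct.n_nodes):
            if rec.ct.is_leaf(v):
                continue
            assert np.all(rec.map_state[v] == w_idx)
            assert np.all(rec.map_posterior[v] > 0.99)

    def test_three_taxon_bayes_enumeration(self):
        """Root posterior equals the direct 20-term Bayes computation."""
        model = pc.build_model("JTT", gamma_shape=0.9, n_categories=4)
        rng = np.random.default_rng(23)
        cols = rng.choice(list(AA_STATES), size=(3, 5))
        aln = pc.Alignment(["A", "B", "C"], cols, "aa", "g3")
        tree = pc.parse_newick("(A:0.15,B:0.25,C:0.4);")
        engine = TreeLikelihood(aln, tree, model)
        lengths = engine.ct.lengths
        fit = pc.FittedGeneModel(
            "g3", tree, model,
            float(engine.loglik(lengths, model.gamma_shape)),
            engine.site_log_likelihoods(),
            engine=engine, lengths=lengths,
        )
        rec = pc.marginal_ancestral_states(fit)
        pi = model.frequencies
        idx = {a: i for i, a in enumerate(AA_STATES)}
        for s in range(aln.n_columns):
            obs = [idx[cols[i, s]] for i in range(3)]
            num = np.zeros(20)
            for r in model.category_rates:
                PA = transition_probabilities(model, 0.15, r)
                PB = transition_probabilities(model, 0.25, r)
                PC = transition_probabilities(model, 0.4, r)
                num += (
                    pi * PA[:, obs[0]] * PB[:, obs[1]] * PC[:, obs[2]]
                ) / len(model.category_rates)
            expected = num / num.sum()
            got = rec.posterior[rec.ct.root, :, s]
            assert np.abs(got - expected).max() < 1e-10
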