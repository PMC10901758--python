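import numpy as np
import pytest

import phyloconv as pc
from phyloconv.ccs import CONVERGENT, PARALLEL
from phyloconv.likelihood import AncestralReconstruction, TreeLikelihood, compile_tree
from phyloconv.seqio import AA_STATES
from phyloconv.simulate import DEFAULT_TARGETS

from conftest import make_aln


def handmade_recon(tree_newick, map_residues, posteriors=None, n_sites=1):
    """Build an AncestralReconstruction with hand-set MAP states.

    ``map_residues``: node label -> residue string per site (internal nodes
    are labeled node{i} in preorder)."""
    tree = pc.parse_newick(tree_newick)
    ct = compile_tree(tree, default_length=0.1)
    K = 20
    map_state = np.zeros((ct.n_nodes, n_sites), dtype=int)
    map_post = np.ones((ct.n_nodes, n_sites))
    for v, lab in enumerate(ct.node_labels):
        res = map_residues.get(lab, "A" * n_sites)
        for s in range(n_sites):
            map_state[v, s] = AA_STATES.index(res[s])
            if posteriors and lab in posteriors:
                map_post[v, s] = posteriors[lab]
    posterior = np.zeros((ct.n_nodes, K, n_sites))
    for v in range(ct.n_nodes):
        for s in range(n_sites):
            posterior[v, map_state[v, s], s] = map_post[v, s]
    return AncestralReconstruction(
        "g", ct, AA_STATES, posterior, map_state, map_post
    )


# 5-taxon tree; A and D are the target pair
TREE = "((A,B)node1,(C,(D,E)node5)node4)node0;"
TREE_PLAIN = "((A,B),(C,(D,E)));"


class TestIdentifySites:
    def tree_recon(self, parent_a, parent_d, mrca, post=None):
        # node1 = parent of A, node5 = parent of D, node0 (root) = MRCA(A,D)
        return handmade_recon(
            TREE_PLAIN,
            {"node1": parent_a, "node6": parent_d, "node0": mrca},
            posteriors=post,
        )

    def test_parallel_call(self):
        rec = self.tree_recon("S", "S", "S")
        aln = make_aln({t: s for t, s in zip("ABCDE", "LSSLS")})
        calls = pc.identify_convergent_sites(rec, aln, ["A", "D"])
        assert len(calls) == 1
        assert calls[0].call_type == PARALLEL
        assert calls[0].derived_state == "L"

    def test_convergent_call(self):
        rec = self.tree_recon("T", "S", "S")
        aln = make_aln({t: s for t, s in zip("ABCDE", "LSSLS")})
        calls = pc.identify_convergent_sites(rec, aln, ["A", "D"])
        assert len(calls) == 1
        assert calls[0].call_type == CONVERGENT

    def test_rule_one_fails_different_tips(self):
        rec = self.tree_recon("S", "S", "S")
        aln = make_aln({t: s for t, s in zip("ABCDE", "LSSVS")})
        assert pc.identify_convergent_sites(rec, aln, ["A", "D"]) == []

    def test_rule_two_fails_no_change_from_mrca(self):
        rec = self.tree_recon("S", "S", "L")
        aln = make_aln({t: s for t, s in zip("ABCDE", "LSSLS")})
        assert pc.identify_convergent_sites(rec, aln, ["A", "D"]) == []

    def test_low_posterior_site_skipped(self):
        rec = self.tree_recon("S", "S", "S", post={"node1": 0.5})
        aln = make_aln({t: s for t, s in zip("ABCDE", "LSSLS")})
        assert (
            pc.identify_convergent_sites(rec, aln, ["A", "D"], posterior_min=0.7)
            == []
        )

    def test_strict_terminal_flag(self):
        # tip equals its parent state: visible change only from the MRCA
        rec = self.tree_recon("L", "S", "S")
        aln = make_aln({t: s for t, s in zip("ABCDE", "LSSLS")})
        assert pc.identify_convergent_sites(rec, aln, ["A", "D"]) == []
        relaxed = pc.identify_convergent_sites(
            rec, aln, ["A", "D"], strict_terminal=False
        )
        assert len(relaxed) == 1

    def test_observed_count_monotone_in_posterior_threshold(
        self, small_fit, small_gene
    ):
        rec = pc.marginal_ancestral_states(small_fit)
        counts = [
            len(
                pc.identify_convergent_sites(
                    rec, small_gene, DEFAULT_TARGETS, posterior_min=p
                )
            )
            for p in (0.0, 0.5, 0.7, 0.9, 0.99)
        ]
        assert counts == sorted(counts, reverse=True)


class TestExpectedRate:
    def make_fit(self, lengths_by_label, n_sites=1, seed=0):
        tree = pc.parse_newick("((A:0.1,B:0.1):0.05,C:0.1);")
        model = pc.build_model("JTT", gamma_shape=1.0, n_categories=4)
        rng = np.random.default_rng(seed)
        cols = rng.choice(list(AA_STATES), size=(3, n_sites))
        aln = pc.Alignment(["A", "B", "C"], cols, "aa", "g")
        engine = TreeLikelihood(aln, tree, model)
        for v, lab in enumerate(engine.ct.node_labels):
            if lab in lengths_by_label:
                engine.ct.lengths[v] = lengths_by_label[lab]
        lengths = engine.ct.lengths
        fit = pc.FittedGeneModel(
            "g", tree, model, 0.0, engine.site_log_likelihoods(),
            engine=engine, lengths=lengths,
        )
        return fit, aln

    def test_zero_terminal_branches_zero_lambda(self):
        fit, _ = self.make_fit({"A": 0.0, "B": 0.0})
        rec = pc.marginal_ancestral_states(fit)
        lam, _ = pc.expected_convergence_rate(fit, rec, ["A", "B"])
        assert lam == pytest.approx(0.0, abs=1e-12)

    def test_lambda_symmetric_in_pair_order(self):
        fit, _ = self.make_fit({"A": 0.2, "B": 0.07}, n_sites=10, seed=3)
        rec = pc.marginal_ancestral_states(fit)
        lam_ab, _ = pc.expected_convergence_rate(fit, rec, ["A", "B"])
        lam_ba, _ = pc.expected_convergence_rate(fit, rec, ["B", "A"])
        assert lam_ab == pytest.approx(lam_ba, abs=1e-12)

    def test_lambda_additivity_bookkeeping(self, small_fit):
        rec = pc.marginal_ancestral_states(small_fit)
        lam, per_pair = pc.expected_convergence_rate(
            small_fit, rec, DEFAULT_TARGETS
        )
        assert lam == pytest.approx(
            sum(v.sum() for v in per_pair.values()), abs=1e-9
        )

    def make_conserved_fit(self, t_branch=0.5):
        """Single conserved column, so the parent state is effectively
        known; longer terminal branches give a measurable event rate.  A
        single rate category matches the lambda formula's branch-
        independence assumption (the factorization over categories is an
        approximation once rates vary per site)."""
        tree = pc.parse_newick("((A:0.1,B:0.1):0.05,C:0.1);")
        model = pc.build_model("JTT")
        aln = pc.Alignment(
            ["A", "B", "C"], np.array([["A"], ["A"], ["A"]]), "aa", "g"
        )
        engine = TreeLikelihood(aln, tree, model)
        for v, lab in enumerate(engine.ct.node_labels):
            if lab in ("A", "B"):
                engine.ct.lengths[v] = t_branch
        fit = pc.FittedGeneModel(
            "g", tree, model, 0.0, engine.site_log_likelihoods(),
            engine=engine, lengths=engine.ct.lengths,
        )
        return fit

    def test_monte_carlo_oracle_single_site(self):
        """lambda matches simulation of the two terminal branches within
        3 MC standard errors (parent state known from a conserved column)."""
        fit = self.make_conserved_fit()
        rec = pc.marginal_ancestral_states(fit)
        lam, _ = pc.expected_convergence_rate(fit, rec, ["A", "B"])

        model = fit.model
        ct = rec.ct
        p_node = ct.parent[ct.leaf_index["A"]]
        assert p_node == ct.parent[ct.leaf_index["B"]]
        rng = np.random.default_rng(99)
        n_rep = 100_000
        rates = model.category_rates
        # sample (category, parent state) from the site posterior
        cat_w = rec.cat_weights[:, 0]
        cats = rng.choice(len(rates), size=n_rep, p=cat_w)
        par_post = rec.post_by_cat[:, p_node, :, 0]
        par_post = par_post / par_post.sum(axis=1, keepdims=True)
        hits = 0
        from phyloconv.likelihood import transition_probabilities

        t_a = fit.lengths[ct.leaf_index["A"]]
        t_b = fit.lengths[ct.leaf_index["B"]]
        P_by_cat = {
            c: (
                transition_probabilities(model, t_a, rates[c]),
                transition_probabilities(model, t_b, rates[c]),
            )
            for c in range(len(rates))
        }
        for c in range(len(rates)):
            mask = cats == c
            n = int(mask.sum())
            if n == 0:
                continue
            parents = rng.choice(20, size=n, p=par_post[c])
            PA, PB = P_by_cat[c]
            ua, ub = rng.random(n), rng.random(n)
            xa = (ua[:, None] < np.cumsum(PA[parents], axis=1)).argmax(axis=1)
            xb = (ub[:, None] < np.cumsum(PB[parents], axis=1)).argmax(axis=1)
            hits += int(
                np.sum((xa == xb) & (xa != parents) & (xb != parents))
            )
        p_hat = hits / n_rep
        se = np.sqrt(max(p_hat, 1e-6) * (1 - p_hat) / n_rep)
        assert abs(lam - p_hat) < 3 * se


class TestPoisson:
    def test_zero_observed_is_one(self):
        assert pc.poisson_upper_tail(0, 5.0) == 1.0

    def test_worked_partial_sum(self):
        # 1 - e^{-1} (1 + 1 + 1/2)
        assert pc.poisson_upper_tail(3, 1.0) == pytest.approx(
            1 - np.exp(-1) * 2.5, abs=1e-9
        )

    def test_zero_lambda(self):
        assert pc.poisson_upper_tail(1, 0.0) == 0.0
        assert pc.poisson_upper_tail(0, 0.0) == 1.0

    def test_negative_inputs(self):
        with pytest.raises(ValueError):
            pc.poisson_upper_tail(-1, 1.0)


class TestIntersection:
    def test_basic_and_empty(self):
        assert pc.adaptive_convergence_intersect({"g1", "g2"}, {"g2", "g3"}) == {
            "g2"
        }
        assert pc.adaptive_convergence_intersect({"g1"}, set()) == set()


class TestRecovery:
    # Short background branches give sharp ancestral states; target terminal
    # branches long enough that a terminal change is plausible.  With very
    # short target branches the reconstruction legitimately prefers a deep
    # origin of the shared residue and the calls are (correctly) suppressed.
    RECOVERY_TREE = (
        "(((((tgtA:0.15,bg1:0.05):0.05,(tgtB:0.15,bg2:0.05):0.05):0.05,"
        "(bg3:0.05,bg4:0.05):0.05):0.05,tgtC:0.20):0.05,outgroup:0.10);"
    )

    def test_injected_parallel_sites_recovered(self, wag):
        """>=90% of ground-truth injected sites (pooled over genes) yield a
        call at the default posterior threshold."""
        tree = pc.parse_newick(self.RECOVERY_TREE)
        total = recovered = 0
        for seed in (77, 101, 202, 303, 404):
            aln = pc.simulate_alignment(tree, wag, 300, seed=seed)
            inj, sites = pc.inject_convergence(
                aln, tree, DEFAULT_TARGETS, 0.05, "parallel", seed=seed + 1
            )
            spec = pc.build_model(
                "JTT", frequencies="empirical", alignment=inj,
                gamma_shape=1.0, n_categories=4,
            )
            fit = pc.fit_gene(inj, tree, spec)
            rec = pc.marginal_ancestral_states(fit)
            calls = pc.identify_convergent_sites(
                rec, inj, DEFAULT_TARGETS, posterior_min=0.7
            )
            called_sites = {c.site - 1 for c in calls}
            total += len(sites)
            recovered += sum(s in called_sites for s in sites)
        assert recovered / total >= 0.9
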