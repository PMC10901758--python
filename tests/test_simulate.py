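import math

import numpy as np
import pytest
from scipy import stats

import phyloconv as pc
from phyloconv.simulate import DEFAULT_TARGETS


class TestSimulateAlignment:
    def test_same_seed_identical(self, sim_tree, wag):
        a = pc.simulate_alignment(sim_tree, wag, 100, seed=9)
        b = pc.simulate_alignment(sim_tree, wag, 100, seed=9)
        assert np.array_equal(a.columns, b.columns)
        c = pc.simulate_alignment(sim_tree, wag, 100, seed=10)
        assert not np.array_equal(a.columns, c.columns)

    def test_zero_length_star_identical_rows(self, wag):
        star = pc.parse_newick("(A:0.0,B:0.0,C:0.0,D:0.0);")
        aln = pc.simulate_alignment(star, wag, 50, seed=1)
        for t in ["B", "C", "D"]:
            assert aln.sequence(t) == aln.sequence("A")

    def test_two_taxon_identity_fraction_closed_form(self):
        """Equal-rates 20-state chain at separation t: P(identical column)
        = 1/20 + (19/20) e^{-20t/19}, within 3 binomial SE."""
        S = np.ones((20, 20))
        np.fill_diagonal(S, 0.0)
        model = pc.SubstitutionModel(
            "WAG", "aa", "ARNDCQEGHILKMFPSTWYV", S, np.full(20, 0.05)
        )
        tree = pc.parse_newick("(A:0.25,B:0.25);")
        n = 20000
        aln = pc.simulate_alignment(tree, model, n, seed=4)
        frac = np.mean(aln.columns[0] == aln.columns[1])
        expected = 1 / 20 + (19 / 20) * math.exp(-20 * 0.5 / 19)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se

    def test_long_branch_tip_frequencies_reach_equilibrium(self, wag):
        tree = pc.parse_newick("(A:25.0,B:25.0);")
        aln = pc.simulate_alignment(tree, wag, 50000, seed=6)
        counts = np.array(
            [np.sum(aln.columns[0] == a) for a in wag.states], dtype=float
        )
        chi2 = stats.chisquare(counts, wag.frequencies * 50000)
        assert chi2.pvalue > 0.01

    def test_unset_lengths_rejected(self, wag):
        from phyloconv.errors import LikelihoodError

        with pytest.raises(LikelihoodError):
            pc.simulate_alignment(pc.parse_newick("(A,B);"), wag, 10, seed=0)


class TestInjectConvergence:
    def test_fraction_zero_is_identity(self, sim_tree, wag):
        aln = pc.simulate_alignment(sim_tree, wag, 60, seed=2)
        out, sites = pc.inject_convergence(
            aln, sim_tree, DEFAULT_TARGETS, 0.0, "parallel", seed=3
        )
        assert sites == []
        assert np.array_equal(out.columns, aln.columns)

    def test_fraction_one_all_targets_identical(self, sim_tree, wag):
        aln = pc.simulate_alignment(sim_tree, wag, 40, seed=2)
        out, sites = pc.inject_convergence(
            aln, sim_tree, DEFAULT_TARGETS, 1.0, "parallel", seed=3
        )
        assert len(sites) == 40
        rows = [out.row(t) for t in DEFAULT_TARGETS]
        for s in range(40):
            assert rows[0][s] == rows[1][s] == rows[2][s]

    @pytest.mark.parametrize("fraction", [0.05, 0.33, 0.5])
    def test_ground_truth_size_and_untouched_sites(
        self, sim_tree, wag, fraction
    ):
        n = 97
        aln = pc.simulate_alignment(sim_tree, wag, n, seed=8)
        out, sites = pc.inject_convergence(
            aln, sim_tree, DEFAULT_TARGETS, fraction, "parallel", seed=9
        )
        assert len(sites) == math.ceil(fraction * n)
        assert len(set(sites)) == len(sites)
        untouched = sorted(set(range(n)) - set(sites))
        assert np.array_equal(
            out.columns[:, untouched], aln.columns[:, untouched]
        )

    def test_injected_residue_differs_from_true_parents(self, sim_tree, wag):
        aln = pc.simulate_alignment(sim_tree, wag, 50, seed=13)
        out, sites = pc.inject_convergence(
            aln, sim_tree, DEFAULT_TARGETS, 0.2, "parallel", seed=14
        )
        ct = aln.sim_tree_compiled
        for s in sites:
            derived = out.row("tgtA")[s]
            for t in DEFAULT_TARGETS:
                p = ct.parent[ct.leaf_index[t]]
                assert wag.states[aln.ancestral_states[p][s]] != derived

    def test_convergent_mode_changes_one_parent(self, sim_tree, wag):
        aln = pc.simulate_alignment(sim_tree, wag, 50, seed=21)
        out, sites = pc.inject_convergence(
            aln, sim_tree, DEFAULT_TARGETS, 0.3, "convergent", seed=22
        )
        ct = aln.sim_tree_compiled
        p0 = ct.parent[ct.leaf_index[DEFAULT_TARGETS[0]]]
        changed = [
            s for s in sites
            if out.ancestral_states[p0][s] != aln.ancestral_states[p0][s]
        ]
        assert changed  # the first target's parent was re-drawn


class TestSimulateCodonPair:
    def test_zero_distance_identical_thirds(self):
        aln = pc.simulate_codon_pair(0.0, np.full(4, 0.25), 500, seed=3)
        s = pc.extract_4d_sites(aln)
        assert s.n_sites == 500
        assert np.array_equal(
            s.third_position_matrix[0], s.third_position_matrix[1]
        )

    def test_same_seed_identical(self):
        a = pc.simulate_codon_pair(0.2, np.full(4, 0.25), 200, seed=5)
        b = pc.simulate_codon_pair(0.2, np.full(4, 0.25), 200, seed=5)
        assert np.array_equal(a.columns, b.columns)

    def test_invalid_composition(self):
        with pytest.raises(ValueError):
            pc.simulate_codon_pair(0.1, [0.5, 0.5, 0.2, 0.1], 10, seed=0)

    def test_skewed_composition_recovery(self):
        comp = np.array([0.4, 0.3, 0.2, 0.1])
        res_cfg = dict(d_tv=0.15, n_codons=40000, seed=11)
        pair = pc.simulate_codon_pair(
            res_cfg["d_tv"], comp, res_cfg["n_codons"], seed=res_cfg["seed"]
        )
        rec = pc.pairwise_4dtv(pair)
        c = 2 * rec.pi_R * rec.pi_Y
        se = math.sqrt(rec.raw_4dtv * (1 - rec.raw_4dtv) / rec.n_4d_sites)
        tol = 3 * se / (1 - rec.raw_4dtv / c)
        assert abs(rec.corrected_4dtv - res_cfg["d_tv"]) < tol
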