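"""Seeded calibration and power experiments.

These functions measure the statistical behavior of the convergence tests
on simulated data at desk scale: false-positive rates under the null
(no convergence), power under controlled injections or a true convergence
topology, and estimator-recovery checks for the likelihood engine and the
4DTv correction.  They are used by the test suite and the reproduction
script, and are part of the public API so users can re-run the calibration
with their own sizes and seeds.
"""

from __future__ import annotations

import numpy as np

from .ccs import ccs_gene_test
from .dssls import FAVORS_H1, classify_gene, compute_delta
from .fourdtv import pairwise_4dtv
from .likelihood import compile_tree, fit_gene, marginal_ancestral_states
from .models import build_model
from .simulate import (
    DEFAULT_CONTROL,
    DEFAULT_TARGETS,
    default_tree,
    inject_convergence,
    simulate_alignment,
    simulate_codon_pair,
)
from .trees import force_clade, matched_distortion_control


def _hypothesis_trees():
    h0 = default_tree()
    h1 = force_clade(h0, DEFAULT_TARGETS)
    h1p = matched_distortion_control(h0, h1, DEFAULT_TARGETS, DEFAULT_CONTROL)
    return h0, h1, h1p


def _wag_spec(aln, k=4):
    return build_model(
        "WAG", frequencies="empirical", alignment=aln,
        gamma_shape=1.0, n_categories=k,
    )


def _jtt_spec(aln, k=4):
    return build_model(
        "JTT", frequencies="empirical", alignment=aln,
        gamma_shape=1.0, n_categories=k,
    )


def dssls_null_calibration(
    n_genes: int = 200, n_sites: int = 200, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Fraction of favors_H1 verdicts on genes simulated under H0 (no
    convergence); should not exceed alpha by more than 3 binomial SE."""
    h0, h1, h1p = _hypothesis_trees()
    sim_model = build_model("WAG", gamma_shape=1.0, n_categories=4)
    n_fav = 0
    for g in range(n_genes):
        aln = simulate_alignment(h0, sim_model, n_sites, seed=(seed * 100003 + g) % 2**31)
        f0 = fit_gene(aln, h0, _wag_spec(aln))
        f1 = fit_gene(aln, h1, _wag_spec(aln))
        f1p = fit_gene(aln, h1p, _wag_spec(aln))
        res = classify_gene(compute_delta(f0, f1, f1p), alpha=alpha)
        n_fav += res.verdict == FAVORS_H1
    se = float(np.sqrt(alpha * (1 - alpha) / n_genes))
    return {
        "fraction": n_fav / n_genes,
        "bound": alpha + 3 * se,
        "n_genes": n_genes,
    }


def dssls_power(
    n_genes: int = 10, n_sites: int = 5000, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Fraction of favors_H1 verdicts on genes simulated on the H1 topology
    (targets truly sister)."""
    h0, h1, h1p = _hypothesis_trees()
    sim = h1.copy()
    sim.set_all_branch_lengths(0.08)
    sim_model = build_model("WAG", gamma_shape=1.0, n_categories=4)
    n_fav = 0
    for g in range(n_genes):
        aln = simulate_alignment(sim, sim_model, n_sites, seed=(seed * 100019 + g) % 2**31)
        f0 = fit_gene(aln, h0, _wag_spec(aln))
        f1 = fit_gene(aln, h1, _wag_spec(aln))
        f1p = fit_gene(aln, h1p, _wag_spec(aln))
        res = classify_gene(compute_delta(f0, f1, f1p), alpha=alpha)
        n_fav += res.verdict == FAVORS_H1
    return {"fraction": n_fav / n_genes, "n_genes": n_genes}


def ccs_null_calibration(
    n_genes: int = 200, n_sites: int = 300, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Fraction of genes with Poisson P < alpha when nothing was injected."""
    h0 = default_tree()
    sim_model = build_model("WAG", gamma_shape=1.0, n_categories=4)
    n_sig = 0
    for g in range(n_genes):
        aln = simulate_alignment(h0, sim_model, n_sites, seed=(seed * 100043 + g) % 2**31)
        fit = fit_gene(aln, h0, _jtt_spec(aln))
        recon = marginal_ancestral_states(fit)
        res = ccs_gene_test(fit, recon, aln, DEFAULT_TARGETS, alpha=alpha)
        n_sig += res.nonrandom
    se = float(np.sqrt(alpha * (1 - alpha) / n_genes))
    return {
        "fraction": n_sig / n_genes,
        "bound": alpha + 3 * se,
        "n_genes": n_genes,
    }


def ccs_power(
    n_genes: int = 50,
    n_sites: int = 300,
    fraction: float = 0.05,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Fraction of genes detected (Poisson P < alpha, observed > expected)
    after injecting parallel substitutions at the given fraction of sites."""
    h0 = default_tree()
    sim_model = build_model("WAG", gamma_shape=1.0, n_categories=4)
    n_sig = 0
    for g in range(n_genes):
        aln = simulate_alignment(h0, sim_model, n_sites, seed=(seed * 100057 + g) % 2**31)
        aln, _ = inject_convergence(
            aln, h0, DEFAULT_TARGETS, fraction, "parallel",
            seed=(seed * 100069 + g) % 2**31,
        )
        fit = fit_gene(aln, h0, _jtt_spec(aln))
        recon = marginal_ancestral_states(fit)
        res = ccs_gene_test(fit, recon, aln, DEFAULT_TARGETS, alpha=alpha)
        n_sig += res.nonrandom and res.observed_count > res.expected_count
    return {"fraction": n_sig / n_genes, "n_genes": n_genes}


def branch_length_recovery(n_sites: int = 10000, seed: int = 7) -> dict:
    """Fit data simulated on the packaged tree and report the maximum
    relative error over the identifiable branch set.

    Under a reversible model the root position carries no information, so
    only the sum of the two root-adjacent branch lengths is identifiable;
    the root-adjacent pair is therefore assessed through its sum.
    """
    tree = default_tree()
    model = build_model("WAG", gamma_shape=1.0, n_categories=4)
    aln = simulate_alignment(tree, model, n_sites, seed=seed)
    fit = fit_gene(aln, tree, build_model("WAG", gamma_shape=1.0, n_categories=4))
    ct = compile_tree(tree)
    root_kids = set(ct.children[ct.root])
    rels = []
    for v in range(ct.n_nodes):
        if ct.parent[v] == -1 or v in root_kids:
            continue
        rels.append(abs(fit.lengths[v] - ct.lengths[v]) / ct.lengths[v])
    true_span = sum(ct.lengths[v] for v in root_kids)
    est_span = sum(fit.lengths[v] for v in root_kids)
    rels.append(abs(est_span - true_span) / true_span)
    return {"max_rel_error": float(max(rels)), "n_sites": n_sites}


def fourdtv_recovery(
    d_tv: float = 0.2, n_codons: int = 50000, seed: int = 5
) -> dict:
    """Estimate the corrected 4DTv from a pair simulated at known
    transversion distance; the tolerance is 3 SE of the estimator obtained
    by the delta method from the binomial error of the raw proportion."""
    pair = simulate_codon_pair(d_tv, np.full(4, 0.25), n_codons, seed=seed)
    rec = pairwise_4dtv(pair)
    c = 2.0 * rec.pi_R * rec.pi_Y
    se_raw = float(np.sqrt(rec.raw_4dtv * (1 - rec.raw_4dtv) / rec.n_4d_sites))
    tol = 3.0 * se_raw / (1.0 - rec.raw_4dtv / c)
    return {
        "estimate": rec.corrected_4dtv,
        "truth": d_tv,
        "tolerance_3se": tol,
        "n_codons": n_codons,
    }
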