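"""Convergent-site detection and the Poisson excess test (the CCS method).

A site is called convergent/parallel for an unordered pair of target
lineages when (i) both extant target residues are identical and
unambiguous, and (ii) the change is inferred to have occurred between each
extant lineage and the pair's most recent common ancestor: the shared tip
residue differs from the MAP reconstruction at each tip's parent node and at
the MRCA.  MAP states are trusted only above a posterior threshold
(unresolvable sites are skipped).  The call is "parallel" when the two
parent states agree, "convergent" otherwise.

The expected number of such events per gene is accumulated from the fitted
model: for each site, pair, and derived state x, the probability that each
terminal branch ends in x having changed, marginalizing the parent node's
posterior state distribution and the gamma-category posterior; the two
branches are taken independent given their parents.  The observed count is
tested against this expectation with a one-sided (upper-tail) Poisson test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import LikelihoodError
from .likelihood import AncestralReconstruction, FittedGeneModel
from .seqio import Alignment

log = logging.getLogger(__name__)

PARALLEL = "parallel"
CONVERGENT = "convergent"


@dataclass
class ConvergentSiteCall:
    gene_id: str
    site: int  # 1-based
    lineage_pair: tuple[str, str]
    derived_state: str
    parent_states: tuple[str, str]
    mrca_state: str
    call_type: str
    min_posterior: float


@dataclass
class CCSGeneResult:
    gene_id: str
    observed_count: int
    expected_count: float
    poisson_p: float
    nonrandom: bool
    n_parallel: int = 0
    n_convergent: int = 0
    calls: list[ConvergentSiteCall] = None


def identify_convergent_sites(
    recon: AncestralReconstruction,
    aln: Alignment,
    targets: list[str],
    posterior_min: float = 0.7,
    strict_terminal: bool = True,
) -> list[ConvergentSiteCall]:
    """Scan every unordered target pair and site for convergent/parallel
    substitutions under rules (i)-(ii).

    With ``strict_terminal`` (default) the change must be visible on each
    terminal branch (tip != parent MAP) in addition to tip != MRCA MAP;
    without it only the MRCA condition is required.
    """
    if not 0.0 <= posterior_min <= 1.0:
        raise ValueError("posterior_min must lie in [0, 1]")
    ct = recon.ct
    for t in targets:
        if t not in ct.leaf_index:
            raise LikelihoodError(f"target {t!r} is not a leaf of the tree")
    calls: list[ConvergentSiteCall] = []
    n_sites = recon.map_state.shape[1]
    for a, b in itertools.combinations(targets, 2):
        va, vb = ct.leaf_index[a], ct.leaf_index[b]
        pa, pb = ct.parent[va], ct.parent[vb]
        vm = ct.mrca(va, vb)
        row_a = aln.row(a)
        row_b = aln.row(b)
        for s in range(n_sites):
            tip_a, tip_b = row_a[s], row_b[s]
            if tip_a != tip_b or tip_a not in recon.states:
                continue  # rule (i): identical, unambiguous
            post_ok = (
                recon.map_posterior[pa, s] >= posterior_min
                and recon.map_posterior[pb, s] >= posterior_min
                and recon.map_posterior[vm, s] >= posterior_min
            )
            if not post_ok:
                continue
            st_pa = recon.map_residue(pa, s)
            st_pb = recon.map_residue(pb, s)
            st_m = recon.map_residue(vm, s)
            if tip_a == st_m:
                continue  # rule (ii): change between tip and MRCA
            if strict_terminal and (tip_a == st_pa or tip_a == st_pb):
                continue
            calls.append(
                ConvergentSiteCall(
                    gene_id=recon.gene_id,
                    site=s + 1,
                    lineage_pair=(a, b),
                    derived_state=tip_a,
                    parent_states=(st_pa, st_pb),
                    mrca_state=st_m,
                    call_type=PARALLEL if st_pa == st_pb else CONVERGENT,
                    min_posterior=float(
                        min(
                            recon.map_posterior[pa, s],
                            recon.map_posterior[pb, s],
                            recon.map_posterior[vm, s],
                        )
                    ),
                )
            )
    return calls


def expected_convergence_rate(
    fit: FittedGeneModel,
    recon: AncestralReconstruction,
    targets: list[str],
) -> tuple[float, dict[tuple[str, str], np.ndarray]]:
    """Model-based expected count of (site, pair) convergence events.

    Returns the gene-level lambda and the per-pair, per-site lambda terms.
    lambda = sum over sites, pairs, and derived states x of
    Pr[branch A ends in x with a change] * Pr[branch B ends in x with a
    change], each branch marginalized over its parent's (per-category)
    posterior and the site's gamma-category posterior.
    """
    if fit.model.kind != "JTT":
        log.warning(
            "expected_convergence_rate: model is %s, not the JTT-f_genes "
            "convention", fit.model.kind,
        )
    engine = fit.engine
    ct = engine.ct
    model = fit.model
    rates = model.category_rates
    w, left, right = model.eigen()

    def branch_change_prob(leaf: int) -> np.ndarray:
        """(n_sites, K): Pr[tip ends in x AND x != parent state]."""
        p = ct.parent[leaf]
        t = fit.lengths[leaf]
        ex = np.exp(w[None, :] * t * rates[:, None])  # (C, K)
        P = np.einsum("im,cm,mj->cij", left, ex, right)
        np.clip(P, 0.0, None, out=P)
        Pc = P.copy()
        for c in range(len(rates)):
            np.fill_diagonal(Pc[c], 0.0)  # change required: x != parent
        # post_by_cat: (C, nodes, K, S); cat_weights: (C, S)
        par_post = recon.post_by_cat[:, p]  # (C, K, S)
        pr = np.einsum("cs,cas,caj->sj", recon.cat_weights, par_post, Pc)
        return pr

    per_pair: dict[tuple[str, str], np.ndarray] = {}
    total = 0.0
    branch_cache: dict[str, np.ndarray] = {}
    for tgt in targets:
        branch_cache[tgt] = branch_change_prob(ct.leaf_index[tgt])
    for a, b in itertools.combinations(targets, 2):
        lam_site = np.einsum("sj,sj->s", branch_cache[a], branch_cache[b])
        per_pair[(a, b)] = lam_site
        total += float(lam_site.sum())
    return total, per_pair


def poisson_upper_tail(observed: int, lam: float) -> float:
    """P = Pr[X >= observed] for X ~ Poisson(lam), one-sided excess test.

    lam = 0 is handled exactly: P = 1 iff observed = 0, else 0.
    """
    if observed < 0 or lam < 0:
        raise ValueError("observed and lambda must be non-negative")
    if observed == 0:
        return 1.0
    if lam == 0.0:
        return 0.0
    return float(stats.poisson.sf(observed - 1, lam))


def ccs_gene_test(
    fit: FittedGeneModel,
    recon: AncestralReconstruction,
    aln: Alignment,
    targets: list[str],
    posterior_min: float = 0.7,
    alpha: float = 0.05,
    strict_terminal: bool = True,
) -> CCSGeneResult:
    """Full per-gene CCS test: observed calls, expected lambda, Poisson P.

    Parallel and convergent events are pooled in the test (both classes are
    also counted separately)."""
    calls = identify_convergent_sites(
        recon, aln, targets, posterior_min=posterior_min,
        strict_terminal=strict_terminal,
    )
    lam, _ = expected_convergence_rate(fit, recon, targets)
    observed = len(calls)
    p = poisson_upper_tail(observed, lam)
    return CCSGeneResult(
        gene_id=fit.gene_id,
        observed_count=observed,
        expected_count=lam,
        poisson_p=p,
        nonrandom=p < alpha,
        n_parallel=sum(c.call_type == PARALLEL for c in calls),
        n_convergent=sum(c.call_type == CONVERGENT for c in calls),
        calls=calls,
    )


def adaptive_convergence_intersect(
    nonrandom_genes: set[str], psg_ids: set[str]
) -> set[str]:
    """Genes that are both non-randomly convergent and positively selected
    are inferred to have undergone adaptive convergence."""
    return set(nonrandom_genes) & set(psg_ids)
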