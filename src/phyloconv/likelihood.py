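"""Felsenstein-pruning site likelihoods, per-gene parameter optimization,
and empirical-Bayes marginal ancestral reconstruction.

Site likelihoods average over equal-weight discrete-gamma rate categories.
Per-column scaling (log-space accumulation at each internal node) keeps long
genes from underflowing.  Optimization is a deterministic cyclic scheme:
Brent on each branch length in turn (each 1-D problem uses cached partial
likelihoods above and below the branch, so a single matrix build per trial
value), then Brent on the gamma shape, repeated until the total
log-likelihood improves by less than the tolerance.  A move is accepted only
if it does not decrease the likelihood, so sweeps are monotone by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

import dendropy

from .errors import LikelihoodError, TreeError
from .models import SubstitutionModel
from .seqio import Alignment
from .trees import PhyloTree

_TINY = 1e-300

BRANCH_BOUNDS = (0.0, 20.0)
ALPHA_BOUNDS = (0.02, 100.0)


def transition_probabilities(
    model: SubstitutionModel, t: float, rate: float = 1.0
) -> np.ndarray:
    """P(t * rate) = exp(Q t rate) via the model's eigendecomposition."""
    if t < 0:
        raise LikelihoodError("negative branch length")
    w, left, right = model.eigen()
    P = (left * np.exp(w * t * rate)) @ right
    np.clip(P, 0.0, None, out=P)
    return P


@dataclass
class CompiledTree:
    """Array view of a rooted tree for the pruning recursions."""

    taxa: list[str]
    parent: np.ndarray  # parent node index; -1 for root
    children: list[list[int]]
    lengths: np.ndarray  # edge length to parent; nan for root
    postorder: list[int]
    preorder: list[int]
    leaf_index: dict[str, int]  # taxon label -> node index
    node_labels: list[str]  # leaf label or internal id like "node7"
    root: int

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    def mrca(self, a: int, b: int) -> int:
        anc = set()
        x = a
        while x != -1:
            anc.add(x)
            x = self.parent[x]
        x = b
        while x not in anc:
            x = self.parent[x]
        return x


def compile_tree(tree: PhyloTree, default_length: float | None = None) -> CompiledTree:
    nodes = list(tree.tree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=int)
    lengths = np.full(len(nodes), np.nan)
    children: list[list[int]] = [[] for _ in nodes]
    leaf_index: dict[str, int] = {}
    labels: list[str] = []
    for i, n in enumerate(nodes):
        if n.parent_node is not None:
            p = index[id(n.parent_node)]
            parent[i] = p
            children[p].append(i)
            if n.edge.length is not None:
                lengths[i] = n.edge.length
            elif default_length is not None:
                lengths[i] = default_length
            else:
                raise LikelihoodError(
                    "tree has unset branch lengths and no default was given"
                )
        if n.is_leaf():
            leaf_index[n.taxon.label] = i
            labels.append(n.taxon.label)
        else:
            labels.append(f"node{i}")
    preorder = list(range(len(nodes)))
    postorder = preorder[::-1]
    return CompiledTree(
        taxa=sorted(leaf_index),
        parent=parent,
        children=children,
        lengths=lengths,
        postorder=postorder,
        preorder=preorder,
        leaf_index=leaf_index,
        node_labels=labels,
        root=0,
    )


class TreeLikelihood:
    """Likelihood machinery for one alignment on one topology.

    Holds compressed site patterns, leaf partials, and the model eigen
    system; exposes evaluation, cyclic optimization, and the up/down
    messages needed for ancestral posteriors.
    """

    def __init__(
        self,
        aln: Alignment,
        tree: PhyloTree,
        model: SubstitutionModel,
        default_length: float = 0.1,
    ):
        if aln.alphabet_tag != model.alphabet_tag:
            raise LikelihoodError(
                f"alignment alphabet {aln.alphabet_tag!r} does not match "
                f"model alphabet {model.alphabet_tag!r}"
            )
        if set(aln.taxon_ids) != set(tree.leaf_labels):
            raise LikelihoodError(
                "tree leaves and alignment taxa differ: "
                f"{sorted(set(aln.taxon_ids) ^ set(tree.leaf_labels))}"
            )
        self.aln = aln
        self.phylo = tree
        self.model = model
        self.ct = compile_tree(tree, default_length=default_length)

        # site-pattern compression
        cols = aln.columns  # (ntaxa, nsites)
        _, inverse, counts = np.unique(
            cols, axis=1, return_inverse=True, return_counts=True
        )
        order = {}
        pattern_cols = []
        self.pattern_of_site = np.empty(aln.n_columns, dtype=int)
        for s in range(aln.n_columns):
            p = inverse[s]
            if p not in order:
                order[p] = len(pattern_cols)
                pattern_cols.append(s)
            self.pattern_of_site[s] = order[p]
        self.weights = np.zeros(len(pattern_cols))
        for s in range(aln.n_columns):
            self.weights[self.pattern_of_site[s]] += 1
        self.n_patterns = len(pattern_cols)

        K = model.n_states
        state_index = {a: i for i, a in enumerate(model.states)}
        self.leaf_partials: dict[int, np.ndarray] = {}
        for ti, taxon in enumerate(aln.taxon_ids):
            part = np.zeros((K, self.n_patterns))
            for pi, s in enumerate(pattern_cols):
                sym = cols[ti, s]
                if sym in state_index:
                    part[state_index[sym], pi] = 1.0
                else:  # gap / ambiguity: missing data
                    part[:, pi] = 1.0
            self.leaf_partials[self.ct.leaf_index[taxon]] = part

    # -- transition matrices ------------------------------------------------

    def _pmats(self, lengths: np.ndarray, rates: np.ndarray) -> np.ndarray:
        """P matrices for every node's parent edge x category: (N, C, K, K)."""
        w, left, right = self.model.eigen()
        t = np.where(np.isnan(lengths), 0.0, lengths)
        ex = np.exp(w[None, None, :] * t[:, None, None] * rates[None, :, None])
        P = np.einsum("im,ncm,mj->ncij", left, ex, right)
        np.clip(P, 0.0, None, out=P)
        return P

    # -- pruning ------------------------------------------------------------

    def _lowers(self, P: np.ndarray, n_cat: int):
        """Post-order partials: per node (C, K, S) plus accumulated log
        scalers (C, S)."""
        ct = self.ct
        S = self.n_patterns
        K = self.model.n_states
        lowers: list[np.ndarray | None] = [None] * ct.n_nodes
        scales: list[np.ndarray | None] = [None] * ct.n_nodes
        for v in ct.postorder:
            if ct.is_leaf(v):
                lowers[v] = np.broadcast_to(
                    self.leaf_partials[v], (n_cat, K, S)
                )
                scales[v] = np.zeros((n_cat, S))
                continue
            part = np.ones((n_cat, K, S))
            sc = np.zeros((n_cat, S))
            for c in ct.children[v]:
                msg = np.einsum("cij,cjs->cis", P[c], lowers[c])
                part = part * msg
                sc = sc + scales[c]
            m = np.maximum(part.max(axis=1), _TINY)
            part = part / m[:, None, :]
            lowers[v] = part
            scales[v] = sc + np.log(m)
        return lowers, scales

    def _uppers(self, P: np.ndarray, lowers, lower_scales, n_cat: int):
        """Pre-order 'rest-of-tree' messages with log scalers.

        For each non-root node v with parent u, ``pre[v]`` is the message at
        u excluding v's subtree (not yet passed through v's edge) and
        ``post[v]`` = pre[v] @ P(t_v), so the site likelihood decomposes as
        sum_j post[v]_j * lower[v]_j * exp(scales).  ``pre`` is what a 1-D
        optimization of t_v needs; ``post`` is what node posteriors need.
        """
        ct = self.ct
        S = self.n_patterns
        K = self.model.n_states
        pi = self.model.frequencies
        pre: list[np.ndarray | None] = [None] * ct.n_nodes
        pre_sc: list[np.ndarray | None] = [None] * ct.n_nodes
        post: list[np.ndarray | None] = [None] * ct.n_nodes
        post_sc: list[np.ndarray | None] = [None] * ct.n_nodes
        post[ct.root] = np.broadcast_to(
            pi[None, :, None], (n_cat, K, S)
        ).copy()
        post_sc[ct.root] = np.zeros((n_cat, S))
        for u in ct.preorder:
            kids = ct.children[u]
            if not kids:
                continue
            msgs = {}
            for c in kids:
                msgs[c] = np.einsum("cij,cjs->cis", P[c], lowers[c])
            for v in kids:
                up = post[u].copy()
                sc = post_sc[u].copy()
                for w_ in kids:
                    if w_ != v:
                        up = up * msgs[w_]
                        sc = sc + lower_scales[w_]
                m = np.maximum(up.max(axis=1), _TINY)
                up = up / m[:, None, :]
                sc = sc + np.log(m)
                pre[v] = up
                pre_sc[v] = sc
                post[v] = np.einsum("cis,cij->cjs", up, P[v])
                post_sc[v] = sc
        return pre, pre_sc, post, post_sc

    def _site_logliks_from_root(self, lowers, scales, n_cat: int):
        pi = self.model.frequencies
        root = self.ct.root
        L = np.einsum("j,cjs->cs", pi, lowers[root])  # (C, S)
        logL = np.log(np.maximum(L, _TINY)) + scales[root]
        m = logL.max(axis=0)
        site = m + np.log(np.mean(np.exp(logL - m[None, :]), axis=0))
        return site  # per pattern

    def loglik(self, lengths: np.ndarray, alpha: float | None) -> float:
        model = self.model if alpha is None else self.model.with_gamma_shape(alpha)
        rates = model.category_rates
        P = self._pmats(lengths, rates)
        lowers, scales = self._lowers(P, len(rates))
        site = self._site_logliks_from_root(lowers, scales, len(rates))
        total = float(np.dot(site, self.weights))
        if not np.isfinite(total):
            bad = int(np.argmin(np.isfinite(site)))
            raise LikelihoodError(
                f"non-finite likelihood at pattern {bad} of gene "
                f"{self.aln.gene_id!r}"
            )
        return total

    def site_log_likelihoods(
        self, lengths: np.ndarray | None = None, alpha: float | None = None
    ) -> np.ndarray:
        """Per-original-column log-likelihoods (SSLS vector)."""
        lengths = self.ct.lengths if lengths is None else lengths
        model = self.model if alpha is None else self.model.with_gamma_shape(alpha)
        rates = model.category_rates
        P = self._pmats(lengths, rates)
        lowers, scales = self._lowers(P, len(rates))
        site = self._site_logliks_from_root(lowers, scales, len(rates))
        return site[self.pattern_of_site]

    # -- optimization -------------------------------------------------------

    def _edge_loglik(self, A_v, A_sc_v, lower_v, lower_sc_v, rates, t):
        """Total log-likelihood as a function of one branch length, with all
        other branches' contributions fixed in the cached messages."""
        w, left, right = self.model.eigen()
        ex = np.exp(w[None, :] * t * rates[:, None])  # (C, K)
        P = np.einsum("im,cm,mj->cij", left, ex, right)
        np.clip(P, 0.0, None, out=P)
        L = np.einsum("cis,cij,cjs->cs", A_v, P, lower_v)
        logL = np.log(np.maximum(L, _TINY)) + A_sc_v + lower_sc_v
        m = logL.max(axis=0)
        site = m + np.log(np.mean(np.exp(logL - m[None, :]), axis=0))
        return float(np.dot(site, self.weights))

    def _edge_pmat(self, t: float, rates: np.ndarray) -> np.ndarray:
        w, left, right = self.model.eigen()
        ex = np.exp(w[None, :] * t * rates[:, None])
        P = np.einsum("im,cm,mj->cij", left, ex, right)
        np.clip(P, 0.0, None, out=P)
        return P

    def optimize(
        self,
        init_length: float = 0.1,
        init_alpha: float = 1.0,
        max_sweeps: int = 50,
        tol: float = 1e-6,
        use_initial_lengths: bool = False,
    ) -> tuple[np.ndarray, float | None, float]:
        """Cyclic branch-length / gamma-shape optimization.

        Branches are visited in postorder; lower partials are refreshed
        incrementally (a node's subtree is final when its edge is visited)
        and the rest-of-tree message is rebuilt along the root path, so each
        1-D Brent evaluation costs a single edge-matrix build.  A candidate
        is accepted only if it improves the current total log-likelihood, so
        the optimization is monotone and deterministic.

        Returns (lengths, alpha, total_loglik).
        """
        ct = self.ct
        lengths = ct.lengths.copy()
        if not use_initial_lengths or np.any(np.isnan(np.delete(lengths, ct.root))):
            lengths[:] = init_length
        lengths[ct.root] = np.nan
        has_gamma = self.model.gamma_shape is not None
        alpha = (self.model.gamma_shape or init_alpha) if has_gamma else None

        # path from root to each node (root excluded, node included)
        paths: list[list[int]] = []
        for v in range(ct.n_nodes):
            path = []
            x = v
            while x != ct.root:
                path.append(x)
                x = ct.parent[x]
            paths.append(path[::-1])

        current = self.loglik(lengths, alpha)
        for _sweep in range(max_sweeps):
            previous = current
            rates = (
                self.model.with_gamma_shape(alpha).category_rates
                if alpha is not None
                else self.model.category_rates
            )
            n_cat = len(rates)
            pi = self.model.frequencies
            P = self._pmats(lengths, rates)
            lowers, lsc = self._lowers(P, n_cat)

            def msg(c):
                Pc = self._edge_pmat(lengths[c], rates)
                return np.einsum("cij,cjs->cis", Pc, lowers[c]), lsc[c]

            for v in ct.postorder:
                if v == ct.root:
                    continue
                if not ct.is_leaf(v):
                    # refresh lower(v): descendants are final for this sweep
                    part = np.ones_like(lowers[v])
                    sc = np.zeros_like(lsc[v])
                    for c in ct.children[v]:
                        m_c, s_c = msg(c)
                        part = part * m_c
                        sc = sc + s_c
                    mx = np.maximum(part.max(axis=1), _TINY)
                    lowers[v] = part / mx[:, None, :]
                    lsc[v] = sc + np.log(mx)
                # rest-of-tree message at parent(v), excluding v's subtree
                up = np.broadcast_to(
                    pi[None, :, None], lowers[v].shape
                ).copy()
                up_sc = np.zeros_like(lsc[v])
                node = ct.root
                for step in paths[v]:
                    for c in ct.children[node]:
                        if c != step:
                            m_c, s_c = msg(c)
                            up = up * m_c
                            up_sc = up_sc + s_c
                    mx = np.maximum(up.max(axis=1), _TINY)
                    up = up / mx[:, None, :]
                    up_sc = up_sc + np.log(mx)
                    if step != v:
                        up = np.einsum(
                            "cis,cij->cjs", up, self._edge_pmat(lengths[step], rates)
                        )
                    node = step

                # project both messages into the eigenbasis once; each trial
                # branch length is then only an exponential reweighting
                w_eig, left, right = self.model.eigen()
                Z = np.einsum("cis,im->cms", up, left) * np.einsum(
                    "mj,cjs->cms", right, lowers[v]
                )
                comb_sc = up_sc + lsc[v]

                def neg(t, _Z=Z, _sc=comb_sc):
                    ex = np.exp(w_eig[None, :] * t * rates[:, None])
                    L = np.einsum("cms,cm->cs", _Z, ex)
                    logL = np.log(np.maximum(L, _TINY)) + _sc
                    mx = logL.max(axis=0)
                    site = mx + np.log(
                        np.mean(np.exp(logL - mx[None, :]), axis=0)
                    )
                    return -float(np.dot(site, self.weights))

                res = minimize_scalar(
                    neg,
                    bounds=BRANCH_BOUNDS,
                    method="bounded",
                    options={"xatol": 1e-5},
                )
                cand, cand_t = -res.fun, float(res.x)
                at_zero = -neg(0.0)  # bounded Brent never tries the bound
                if at_zero >= cand:
                    cand, cand_t = at_zero, 0.0
                if cand > current:
                    lengths[v] = cand_t
                    current = cand
            if has_gamma:
                def neg_alpha(log_a):
                    return -self.loglik(lengths, float(np.exp(log_a)))

                res = minimize_scalar(
                    neg_alpha,
                    bounds=(np.log(ALPHA_BOUNDS[0]), np.log(ALPHA_BOUNDS[1])),
                    method="bounded",
                    options={"xatol": 1e-3},
                )
                if -res.fun > current:
                    alpha = float(np.exp(res.x))
                    current = -res.fun
            if current - previous < tol:
                break
        # snap near-zero lengths to the bound
        lengths = np.where(lengths < 1e-9, 0.0, lengths)
        current = self.loglik(lengths, alpha)
        return lengths, alpha, current


@dataclass
class FittedGeneModel:
    """One gene fitted on one topology: optimized branch lengths, optimized
    gamma shape, and the per-site log-likelihood (SSLS) vector."""

    gene_id: str
    tree: PhyloTree
    model: SubstitutionModel
    total_loglik: float
    site_logliks: np.ndarray
    engine: TreeLikelihood = field(repr=False, compare=False, default=None)
    lengths: np.ndarray = field(repr=False, compare=False, default=None)


def fit_gene(
    aln: Alignment,
    topology: PhyloTree,
    model_spec: SubstitutionModel,
    tol: float = 1e-6,
    max_sweeps: int = 50,
) -> FittedGeneModel:
    """Optimize branch lengths and gamma shape for one gene on one topology
    and populate its SSLS vector."""
    if aln.n_taxa < 2:
        raise LikelihoodError("need at least two taxa")
    if aln.n_columns < 1:
        raise LikelihoodError("alignment has no columns")
    engine = TreeLikelihood(aln, topology, model_spec, default_length=0.1)
    lengths, alpha, total = engine.optimize(tol=tol, max_sweeps=max_sweeps)
    engine.ct.lengths = lengths
    fitted_model = (
        model_spec.with_gamma_shape(alpha) if alpha is not None else model_spec
    )
    engine.model = fitted_model
    site = engine.site_log_likelihoods(lengths, None if alpha is None else alpha)

    fitted_tree = topology.copy()
    nodes = list(fitted_tree.tree.preorder_node_iter())
    for i, n in enumerate(nodes):
        if n.parent_node is not None:
            n.edge.length = float(lengths[i])
    return FittedGeneModel(
        gene_id=aln.gene_id,
        tree=fitted_tree,
        model=fitted_model,
        total_loglik=total,
        site_logliks=site,
        engine=engine,
        lengths=lengths,
    )


@dataclass
class AncestralReconstruction:
    """Marginal (empirical-Bayes) ancestral posteriors.

    ``posterior`` is (n_nodes, K, n_sites), category-averaged; ``map_state``
    and ``map_posterior`` give the argmax per node x site.  Per-category
    posteriors and site category weights are retained for the expected-
    convergence computation.
    """

    gene_id: str
    ct: CompiledTree
    states: str
    posterior: np.ndarray
    map_state: np.ndarray  # (n_nodes, n_sites) of state indices
    map_posterior: np.ndarray  # (n_nodes, n_sites)
    post_by_cat: np.ndarray = field(repr=False, default=None)  # (C, nodes, K, S)
    cat_weights: np.ndarray = field(repr=False, default=None)  # (C, S)

    def map_residue(self, node: int, site: int) -> str:
        return self.states[self.map_state[node, site]]


def marginal_ancestral_states(fit: FittedGeneModel) -> AncestralReconstruction:
    """Empirical-Bayes marginal ancestral posteriors for every node,
    integrating over gamma categories weighted by their posterior given the
    column."""
    engine = fit.engine
    if engine is None:
        raise LikelihoodError("fit carries no likelihood engine")
    ct = engine.ct
    model = engine.model
    rates = model.category_rates
    n_cat = len(rates)
    K = model.n_states
    P = engine._pmats(fit.lengths, rates)
    lowers, lsc = engine._lowers(P, n_cat)
    _, _, post, _ = engine._uppers(P, lowers, lsc, n_cat)

    S = engine.n_patterns
    # per-category site log-likelihood for category weights
    pi = model.frequencies
    L_root = np.einsum("j,cjs->cs", pi, lowers[ct.root])
    logL = np.log(np.maximum(L_root, _TINY)) + lsc[ct.root]
    m = logL.max(axis=0)
    wcat = np.exp(logL - m[None, :])
    wcat = wcat / wcat.sum(axis=0, keepdims=True)  # (C, S)

    post_by_cat = np.zeros((n_cat, ct.n_nodes, K, S))
    for v in range(ct.n_nodes):
        if v == ct.root:
            joint = pi[None, :, None] * lowers[v]
        else:
            joint = post[v] * lowers[v]
        norm = np.maximum(joint.sum(axis=1, keepdims=True), _TINY)
        post_by_cat[:, v] = joint / norm
    posterior_pat = np.einsum("cs,cvks->vks", wcat, post_by_cat)

    idx = engine.pattern_of_site
    posterior = posterior_pat[:, :, idx]
    map_state = posterior.argmax(axis=1)
    map_posterior = posterior.max(axis=1)
    return AncestralReconstruction(
        gene_id=fit.gene_id,
        ct=ct,
        states=model.states,
        posterior=posterior,
        map_state=map_state,
        map_posterior=map_posterior,
        post_by_cat=post_by_cat[:, :, :, idx],
        cat_weights=wcat[:, idx],
    )


def site_log_likelihoods(
    aln: Alignment, tree: PhyloTree, model: SubstitutionModel
) -> np.ndarray:
    """SSLS vector for fixed branch lengths (no optimization)."""
    if not tree.has_branch_lengths:
        raise TreeError("tree has unset branch lengths")
    engine = TreeLikelihood(aln, tree, model)
    return engine.site_log_likelihoods()
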