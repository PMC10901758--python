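"""Rooted-tree handling and the alternative-topology constructions.

The convergence tests compare a species tree H0 against two constructed
hypotheses: H1, in which the designated target ("electric") taxa are forced
into one clade, and H1', a control in which an equal amount of topological
distortion is applied without clustering the targets.  "Equal distortion" is
operationalized as equal Robinson-Foulds distance from H0; a user-supplied
H1' bypasses construction but is verified against the same two constraints.

Newick parsing and bipartition distances are delegated to dendropy; the
topology surgery itself runs on a plain nested-tuple representation so the
constructions are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import dendropy
from dendropy.calculate import treecompare

from .errors import TreeError

Nested = object  # leaf label (str) or tuple of Nested


@dataclass
class PhyloTree:
    """A rooted tree with optional branch lengths and a role tag
    (H0 / H1 / H1prime / simulation / other)."""

    tree: dendropy.Tree
    role_tag: str = "other"
    outgroup: str | None = None

    @classmethod
    def from_newick(cls, text: str, role_tag: str = "other") -> "PhyloTree":
        return parse_newick(text, role_tag=role_tag)

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def has_branch_lengths(self) -> bool:
        return all(
            e.length is not None
            for e in self.tree.preorder_edge_iter()
            if e.head_node is not self.tree.seed_node
        )

    def newick(self, lengths: bool = True) -> str:
        s = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_edge_lengths=not lengths,
        ).strip()
        return s

    def copy(self, role_tag: str | None = None) -> "PhyloTree":
        t = self.tree.clone(depth=1)
        return PhyloTree(t, role_tag or self.role_tag, self.outgroup)

    def set_all_branch_lengths(self, value: float) -> None:
        for e in self.tree.preorder_edge_iter():
            if e.head_node is not self.tree.seed_node:
                e.length = value


def parse_newick(text: str, role_tag: str = "other") -> PhyloTree:
    """Parse a Newick string into a rooted :class:`PhyloTree`.

    Branch lengths may be absent (they must then be set before any
    likelihood computation).  Malformed strings and duplicate leaf labels
    raise :class:`TreeError`.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted DataError subtypes
        raise TreeError(f"could not parse Newick: {exc}") from exc
    tree.is_rooted = True
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted(l for l in set(labels) if labels.count(l) > 1)
        raise TreeError(f"duplicate leaf labels: {dupes}")
    if not labels:
        raise TreeError("tree has no leaves")
    return PhyloTree(tree, role_tag)


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Unrooted Robinson-Foulds distance: the number of non-trivial
    bipartitions present in exactly one of the two trees."""
    l1, l2 = set(t1.leaf_labels), set(t2.leaf_labels)
    if l1 != l2:
        raise TreeError(
            f"leaf-set mismatch: only-in-first={sorted(l1 - l2)}, "
            f"only-in-second={sorted(l2 - l1)}"
        )
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=t1.newick(lengths=False),
        schema="newick",
        taxon_namespace=tns,
        preserve_underscores=True,
    )
    b = dendropy.Tree.get(
        data=t2.newick(lengths=False),
        schema="newick",
        taxon_namespace=tns,
        preserve_underscores=True,
    )
    a.is_rooted = False
    b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))


def mrca(tree: PhyloTree, taxa: Sequence[str]) -> dendropy.Node:
    """Most recent common ancestor node of the given taxa (the leaf itself
    for a singleton)."""
    taxa = list(taxa)
    leaves = set(tree.leaf_labels)
    unknown = [t for t in taxa if t not in leaves]
    if unknown:
        raise TreeError(f"unknown taxa: {unknown}")
    if len(taxa) == 1:
        return tree.tree.find_node_with_taxon_label(taxa[0])
    node = tree.tree.mrca(taxon_labels=taxa)
    if node is None:
        raise TreeError(f"no common ancestor found for {taxa}")
    return node


def is_monophyletic(tree: PhyloTree, taxa: Sequence[str]) -> bool:
    """True when some clade's leaf set equals exactly the given taxa."""
    target = set(taxa)
    node = mrca(tree, list(taxa))
    clade = {lf.taxon.label for lf in node.leaf_iter()}
    return clade == target


# ---------------------------------------------------------------------------
# nested-tuple topology surgery


def _to_nested(node: dendropy.Node) -> Nested:
    if node.is_leaf():
        return node.taxon.label
    return tuple(_to_nested(c) for c in node.child_nodes())


def _leafset(n: Nested) -> frozenset:
    if isinstance(n, str):
        return frozenset([n])
    return frozenset().union(*(_leafset(c) for c in n))


def _nested_newick(n: Nested) -> str:
    def fmt(x: Nested) -> str:
        if isinstance(x, str):
            return x
        return "(" + ",".join(fmt(c) for c in x) + ")"

    return fmt(n) + ";"


def _prune(n: Nested, remove: set) -> Nested | None:
    if isinstance(n, str):
        return None if n in remove else n
    kids = [k for k in (_prune(c, remove) for c in n) if k is not None]
    if not kids:
        return None
    if len(kids) == 1:  # suppress unifurcation
        return kids[0]
    return tuple(kids)


def _replace_clade(n: Nested, leafset: frozenset, subtree: Nested) -> Nested:
    """Insert ``subtree`` on the edge subtending the clade with the given
    leaf set: that clade C becomes (subtree, C)."""
    if _leafset(n) == leafset:
        return (subtree, n)
    if isinstance(n, str):
        return n
    return tuple(_replace_clade(c, leafset, subtree) for c in n)


def _ladder(labels: Sequence[str]) -> Nested:
    clade: Nested = (labels[0], labels[1])
    for lab in labels[2:]:
        clade = (clade, lab)
    return clade


def _attachment_leafset(
    root: Nested, first: str, moved: set
) -> frozenset:
    """Leaf set of the clade marking where ``first`` was attached, after the
    moved taxa are pruned: the nearest sibling subtree (walking rootward)
    that still contains non-moved leaves."""

    def path_to(n: Nested, target: str) -> list[Nested] | None:
        if n == target:
            return [n]
        if isinstance(n, str):
            return None
        for c in n:
            p = path_to(c, target)
            if p is not None:
                return [n] + p
        return None

    path = path_to(root, first)
    if path is None:
        raise TreeError(f"taxon {first!r} not in tree")
    # walk from the leaf's parent rootward collecting sibling leaves
    for depth in range(len(path) - 2, -1, -1):
        node = path[depth]
        child_on_path = path[depth + 1]
        sibs: set = set()
        for c in node:
            if c is not child_on_path:
                sibs |= set(_leafset(c))
        sibs -= moved
        if sibs:
            return frozenset(sibs)
    raise TreeError("no non-target leaves remain to attach the clade to")


def _from_nested(n: Nested, role_tag: str) -> PhyloTree:
    t = parse_newick(_nested_newick(n), role_tag=role_tag)
    return t


def force_clade(h0: PhyloTree, targets: Sequence[str]) -> PhyloTree:
    """Construct H1: the target taxa forced into one clade.

    Deterministic construction: prune all targets, join them in input-list
    order into a ladderized subclade, and regraft that subclade onto the
    branch where the first-listed target was attached.  Branch lengths are
    reset (each hypothesis is re-fitted per gene).  If the targets are
    already monophyletic the input topology is returned, tagged H1.
    """
    targets = list(targets)
    if len(targets) < 2:
        raise TreeError("force_clade requires at least two target taxa")
    leaves = set(h0.leaf_labels)
    unknown = [t for t in targets if t not in leaves]
    if unknown:
        raise TreeError(f"unknown target taxa: {unknown}")
    if is_monophyletic(h0, targets):
        out = h0.copy(role_tag="H1")
        return out
    nested = _to_nested(h0.tree.seed_node)
    attach = _attachment_leafset(nested, targets[0], set(targets))
    pruned = _prune(nested, set(targets))
    if pruned is None:
        raise TreeError("pruning the targets removed the whole tree")
    clade = _ladder(targets)
    new = _replace_clade(pruned, attach, clade)
    out = _from_nested(new, "H1")
    out.outgroup = h0.outgroup
    return out


def _iter_regrafts(pruned: Nested, clade: Nested) -> Iterator[Nested]:
    """All trees obtainable by inserting ``clade`` on one edge of ``pruned``
    (plus at the root), in deterministic preorder."""
    yield (clade, pruned)

    def recurse(n: Nested, rebuild) -> Iterator[Nested]:
        if isinstance(n, str):
            return
        for i, c in enumerate(n):
            def rebuild_c(x, _i=i, _n=n, _rebuild=rebuild):
                return _rebuild(tuple(x if j == _i else k for j, k in enumerate(_n)))

            yield rebuild_c((clade, c))
            yield from recurse(c, rebuild_c)

    yield from recurse(pruned, lambda x: x)


def verify_h1prime(
    h0: PhyloTree,
    h1: PhyloTree,
    candidate: PhyloTree,
    targets: Sequence[str],
) -> None:
    """Check the two H1' constraints: equal RF distortion from H0 as H1,
    and targets not monophyletic.  Raises :class:`TreeError` on failure."""
    rf_h1 = robinson_foulds(h0, h1)
    rf_cand = robinson_foulds(h0, candidate)
    if rf_cand != rf_h1:
        raise TreeError(
            f"H1' distortion RF(H0,H1')={rf_cand} differs from RF(H0,H1)={rf_h1}"
        )
    if is_monophyletic(candidate, targets):
        raise TreeError("targets are monophyletic in the H1' candidate")


def matched_distortion_control(
    h0: PhyloTree,
    h1: PhyloTree,
    targets: Sequence[str],
    control: Sequence[str],
) -> PhyloTree:
    """Construct H1': cluster the control taxa with the same construction as
    H1, verifying equal RF distortion from H0 and that the targets remain
    non-monophyletic.  If the primary construction fails verification, scan
    alternative control regraft positions in deterministic preorder; raise
    when no admissible topology exists."""
    targets = list(targets)
    control = list(control)
    if set(control) & set(targets):
        raise TreeError("control taxa overlap the target set")
    if len(control) < 2:
        raise TreeError("need at least two control taxa")
    leaves = set(h0.leaf_labels)
    unknown = [t for t in control if t not in leaves]
    if unknown:
        raise TreeError(f"unknown control taxa: {unknown}")

    rf_h1 = robinson_foulds(h0, h1)

    def admissible(cand: PhyloTree) -> bool:
        return (
            robinson_foulds(h0, cand) == rf_h1
            and not is_monophyletic(cand, targets)
        )

    try:
        primary = force_clade(h0, control)
        primary.role_tag = "H1prime"
        if admissible(primary):
            return primary
    except TreeError:
        pass

    nested = _to_nested(h0.tree.seed_node)
    pruned = _prune(nested, set(control))
    if pruned is None:
        raise TreeError("pruning the control taxa removed the whole tree")
    clade = _ladder(control)
    for cand_nested in _iter_regrafts(pruned, clade):
        cand = _from_nested(cand_nested, "H1prime")
        if admissible(cand):
            cand.outgroup = h0.outgroup
            return cand
    raise TreeError(
        "no control regraft position yields a topology with "
        f"RF(H0,.) == {rf_h1} and non-monophyletic targets"
    )
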