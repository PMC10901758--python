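# Methods

This note documents the models, the constructions, the numerical choices
and the calibration experiments implemented in `phyloconv`, and states
where the design was genuinely open and what was chosen.

## Substitution models and likelihoods

Amino-acid evolution is modelled as a reversible continuous-time Markov
chain assembled from an exchangeability matrix S and equilibrium
frequencies π: q_ij = s_ij π_j, rows normalized so the stationary flow is
one expected substitution per site, so all branch lengths are in
substitutions/site. WAG and JTT exchangeabilities (with their published
default frequencies) are shipped as PAML-format text files in
`phyloconv/data/`, state order ARNDCQEGHILKMFPSTWYV. HKY is provided for
nucleotides with transition/transversion parameter κ (default 2).

Gene-empirical frequencies (the "f_genes" convention) are observed residue
proportions with a pseudocount of 0.1 added to every residue before
normalization; the floor keeps rates to unobserved residues positive in
short genes. Among-site rate variation uses k = 4 equal-probability
discrete-gamma categories with category rate equal to the bin mean
(computed from incomplete-gamma differences) and the mean renormalized to
exactly 1.

Transition probabilities come from the symmetric-similarity
eigendecomposition of Q (real spectrum guaranteed by reversibility);
entries are clipped at zero against round-off. Site likelihoods are
computed by Felsenstein pruning vectorized over sites and categories, with
per-node rescaling and log-space accumulation so long genes do not
underflow; site patterns are compressed with multiplicity weights. Gaps and
ambiguity codes are missing data (partial likelihood 1 in every state), so
an all-gap column has log-likelihood exactly 0.

### Optimization

Per gene and topology, branch lengths and the gamma shape are optimized by
a deterministic cyclic scheme: bounded Brent on each branch in postorder,
then Brent on log α, repeated until the total log-likelihood improves by
less than 1e-6 or 50 sweeps. Branch bounds are [0, 20], α ∈ [0.02, 100];
initialization is 0.1 for every branch and α = 1. Each 1-D branch problem
uses cached partial likelihoods above and below the branch projected into
the eigenbasis, so a trial branch length costs only an exponential
reweighting; because bounded Brent never evaluates at the boundary, t = 0
is probed explicitly. A candidate is accepted only if it does not decrease
the current total log-likelihood, which makes the optimization monotone and
exactly reproducible. There are no random restarts.

Under a reversible model the likelihood is invariant to the root position
(pulley principle), so only the **sum** of the two root-adjacent branch
lengths is identifiable; recovery experiments therefore assess that pair
through its sum and every other branch individually.

### Ancestral reconstruction

Marginal (empirical-Bayes) posteriors are computed per internal node and
site from the product of the node's upward and downward messages,
integrating over gamma categories weighted by each category's posterior
given the column (not best-category-only). The MAP state and its posterior
are recorded; per-category posteriors are retained because the
expected-convergence computation needs them.

## The ΔSSLS test

H1 is constructed from the species tree by a deterministic operation:
prune the target taxa, join them in input-list order into a ladderized
clade, and regraft that clade onto the branch where the first-listed target
was attached. H1′ applies the same operation to a user-chosen control set
and is verified to (a) have the same Robinson–Foulds distance from H0 as H1
and (b) leave the targets non-monophyletic; if the primary construction
fails verification, alternative regraft positions are scanned in
deterministic preorder, and an error is raised if none is admissible. A
user-supplied H1′ bypasses construction but is verified the same way.
"Equal distortion" had no stated metric; equal RF distance is the choice
here, and it is overridable by supplying H1′ explicitly. Branch lengths are
never copied between hypotheses — every topology is re-fitted per gene.

Each gene's verdict combines three conditions, all configurable: KS
two-sample P < α between the per-site ΔL(H0−H1) and ΔL(H0−H1′)
distributions (exact enumeration when both samples ≤ 25, asymptotic
otherwise), mean ΔL(H0−H1) < 0, and mean ΔL(H0−H1) < mean ΔL(H0−H1′). The
conjunction operationalizes "the two ΔL distributions do not overlap in the
favorable direction"; testing is per gene (a pooled mode is not enabled by
default), and no multiple-testing correction is applied by default
(a Benjamini–Hochberg helper is provided).

## The CCS test

For every unordered pair of target lineages and site, a call requires:
identical unambiguous residues in both extant targets; the shared residue
differing from the MAP state at the pair's MRCA; and (with the default
`strict_terminal`) differing from the MAP state at each tip's parent, so
the change is visible on the terminal branch. All three MAP posteriors must
reach `posterior_min` (default 0.7) or the site is skipped. The call is
*parallel* when the two parent states agree and *convergent* otherwise;
both classes are pooled in the excess test and also reported separately.
With three targets a site can contribute up to three (site, pair) events,
and the gene-level observed count counts those events, matching the λ
bookkeeping.

The expectation is
λ = Σ_sites Σ_pairs Σ_x Pr_A(x) Pr_B(x), with
Pr_branch(x) = Σ_cat w_cat(site) Σ_a post_cat(parent = a) P_cat(a→x; t) ·
1[x ≠ a]. Two approximations are explicit: the two branches are treated as
independent given their parents, and the gamma category is marginalized per
branch rather than jointly (per site the true category is shared, so λ
slightly understates the joint tail when rate variation is strong). The
Poisson test is one-sided (upper tail) because the question is excess
convergence; Pr[X ≥ obs] is computed by the stable survival function, with
λ = 0 handled exactly.

A caveat the calibration experiments make visible: when several short
target branches are overwritten with the same residue, marginal
reconstruction can legitimately prefer a deep origin of that residue
followed by reversions, which suppresses calls. Detection is sharpest when
background branches are short (sharp ancestral states) and target terminal
branches are long enough that a terminal change is plausible.

## 4D sites and 4DTv

A codon column is a 4D site only when all taxa share identical, unambiguous
first+second positions, the prefix belongs to one of the eight four-fold
families (GC, CG, GG, CT, CC, TC, AC, GT), and no taxon has a gap or N —
the strict cross-taxon convention; the six-fold Leu/Arg families qualify
only via their CTN/CGN prefixes. The raw 4DTv of a sequence pair is the
fraction of retained third positions differing by a transversion. The
corrected distance is the HKY/TN93 transversion component
d = −2π_Rπ_Y ln(1 − Q/(2π_Rπ_Y)), with π_R/π_Y pooled over both sequences'
retained third positions (pooling, not per-sequence averaging). Because the
purine/pyrimidine partition lumps the HKY chain into a two-state chain
whose switching events are exactly the transversions, this correction
recovers the expected number of transversion substitutions per site; in the
equal-frequency limit it reduces to −0.5 ln(1 − 2Q). The correction is
undefined once Q ≥ 2π_Rπ_Y and is then flagged rather than extrapolated.
Histogram summaries report local maxima (bin count strictly above both
neighbors) on raw or corrected values — both are available.

## Demography scalings

g = a + s/(1−s) converts age at first reproduction a (years) and expected
adult survival s into a generation time, and μ_gen = μ_year · g converts a
per-year mutation rate to per-generation units. These are the exact
scalings applied to coalescent-inference axes; the coalescent inference
itself is out of scope here.

## Alignment trimming

Heuristic alignment cleaning is replaced by a transparent two-rule column
filter: drop a column when its gap fraction exceeds `max_gap_fraction`
(default 0.5) or, if `drop_ambiguous` (default on), when any ambiguity
symbol is present; codon alignments drop whole codon columns, and a codon
with a partial gap counts as ambiguous. The mapping from kept to original
column indices is returned, and all user-facing tables are 1-based and say
so in their headers.

## Synthetic data

The packaged simulation tree has eight taxa: one outgroup, three target
lineages (two in different subclades of one clade, one distant) and four
background taxa, with root-to-tip path lengths near 0.5 substitutions/site.
It emulates the *shape* of a small vertebrate phylogeny with repeated
origins of a trait; it is not a published, dated tree. Genes are simulated
by drawing root states from π and evolving edge by edge, with each site's
gamma category drawn uniformly and held across the tree (no rate
autocorrelation along the sequence). Convergence injection overwrites the
target tips at ⌈fraction·n⌉ seeded sites with a residue drawn from π that
differs from each target's true parent state in the recorded simulation
history; *convergent* mode first re-draws one target's parent state and
re-evolves that parent's other descendants so the two starting points
differ. All simulators are byte-reproducible under a fixed seed.

What the simulations do not emulate: indels and alignment error,
selection (sites are exchangeable draws), rate autocorrelation,
compositional heterogeneity across lineages, and model misspecification
(data are generated under the same family fitted to them). Passing
calibration therefore demonstrates internal statistical correctness of the
tests, not robustness to the violations real ortholog sets contain.

## Calibration experiments and problem sizes

The reproduction script and the acceptance tests run, per seed:

- ΔSSLS null calibration: 200 genes × 200 residues simulated on H0;
  the favors_H1 fraction must stay within α + 3 binomial SE of α = 0.05.
- ΔSSLS power: 10 genes × 5000 residues simulated on the H1 topology
  (all branches 0.08); detection fraction ≥ 0.8 expected.
- CCS null calibration: 200 genes × 300 residues, nothing injected; the
  Poisson-significant fraction must stay within α + 3 SE.
- CCS power: 50 genes × 300 residues with parallel injection at 5% of
  sites; detection fraction ≥ 0.8 expected.
- Branch-length recovery: one 10,000-site gene; ≤ 10% relative error on
  the identifiable branch set.
- 4DTv recovery: one pair of 50,000 codons at true distance 0.2; agreement
  within 3 delta-method SE.

These sizes are the package's chosen desk-scale conditions; all of them can
be rerun at other sizes through `phyloconv.experiments`.

## Known limitations

- The ΔSSLS verdict rule is a stated operationalization; other conjunction
  rules (or pooled genome-wide testing) are defensible and the components
  are exposed for users who prefer them.
- λ factorizes over branches and categories (see above); genes with
  extreme rate heterogeneity will have slightly conservative expectations.
- Only the standard genetic code is supported; codon-model likelihoods
  (dN/dS) and tree search are out of scope — the species tree, ortholog
  alignments and PSG lists are inputs.
- The H1 construction is deterministic but not unique; supplying explicit
  H1/H1′ topologies overrides it.
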