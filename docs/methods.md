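# Methods

## Derived non-conservative substitution calling

The survey operates on residue state sets at homologous sites, indexed
either in bovine Rhodopsin coordinates or, for sites outside the
Rhodopsin-alignable region, in jewel-beetle UV-opsin-2 coordinates
(rendered with a trailing asterisk, e.g. `29*`). Sites are identified
by the pair (number, scheme), so the two numbering systems never
collide; cross-lineage comparisons only match sites within one scheme.

For a focal clade F with sister clade S and outgroup set O at one
site:

- the **ancestral set** A and the **sister set** S_S are plain unions
  of the observed residues (gaps and `X` excluded). Using the union
  rather than a consensus is deliberate: a polymorphic outgroup row
  such as V/I/L must suppress a derived call for any of its members.
- the **focal set** S_F keeps only residues carried by more than the
  *minor-variant fraction* (default 0.25) of the focal members, so a
  single aberrant sequence in a clade of four or five does not veto a
  clade-wide replacement, while 1-of-3 variants (which clear 0.25)
  keep the clade polymorphic. If filtering would empty the set, the
  unfiltered set is used instead.

Verdicts:

- `derived_in_focal` — S_F ∩ A = ∅, S_F ∩ S_S = ∅, S_S ∩ A ≠ ∅, and
  at least one focal residue is non-conservative against **every**
  ancestral residue. The third condition demands that the sister still
  carries an outgroup state: without it the pre-duplication state is
  not inferable and no directional call is justified.
- `retained` — S_F shares a residue with A.
- `shared_derived` — S_F is novel but shared with the sister: the
  change predates the paralog split and says nothing about
  differential paralog evolution.
- `ambiguous` — anything else, with a machine-readable reason:
  an empty state set (all-gap clade), `sister_not_ancestral`
  (both clades novel), or `conservative_change` (novel but
  physicochemically conservative). Ambiguous sites are listed
  separately and never enter derived counts.

Conservative groups default to {I,L,V} and {R,K} — deliberately
minimal so that charge-changing (K→V), aromatic (Y→F, F→Y), and
polarity-changing replacements all count as non-conservative, while
branched-aliphatic and long-basic swaps do not. Both the groups and
the minor-variant fraction are arguments on every entry point.

The tuning-site catalog defaults to the five Rhodopsin-numbered sites
with prior evidence of spectral tuning (90, 105, 125, 293, 294) and
can be replaced by any TSV of (site, scheme) rows. Whether site 125
belongs to the demonstrated (rather than proposed) subset is not
settled; it is retained in the default catalog and the catalog is
user-overridable.

### The shipped state-matrix fixture

The per-site states of the aphid and planthopper UV-opsin clades are
shipped as a plain TSV and expanded into a synthetic alignment at run
time: clade-wide variants (`V/L/C`, `R,K`) are distributed as evenly
as possible over the clade members, and parenthesized minor variants
(`K(T)`) occupy exactly one member. Aphid clades have five members,
planthopper clades three, outgroups three singletons each — matching
the species sampling the states were scored from. This expansion is a
fixture-generation device, not data: only the state sets matter to the
classifier, and every set relation in the TSV is preserved exactly.

## Substitution model and distances

The JTT empirical exchangeabilities and frequencies (the widely
redistributed `jones.dat` values, cross-checked against the copy
shipped in the R package phangorn) define a reversible rate matrix
Q_ij = s_ij π_j, normalized to one expected substitution per site at
equilibrium. Transition matrices come from the eigendecomposition of
the π-symmetrized form (real-symmetric by reversibility), which makes
P(t) two 20×20 matrix products — important because the likelihood
optimizers evaluate thousands of them.

Rate heterogeneity uses the discrete gamma approximation with k = 4
equal-probability categories at their conditional means (for α = 1:
0.137, 0.477, 1.000, 2.386), renormalized to mean exactly 1. α is
fixed (default 1), not co-estimated.

Pairwise ML distances maximize the site-summed log-likelihood
Σ log[π_a · mean_c P(d·r_c)_ab] over d ∈ [10⁻⁶, 10] with bounded
scalar minimization (tolerance 10⁻⁸); pair count matrices are
symmetrized, which is exact under reversibility and makes d(A,B) and
d(B,A) bit-identical. Sites with a gap or `X` in either sequence are
deleted pairwise (not complete-deletion), because clade-mean
comparisons span different sequence subsets. Identical sequences
short-circuit to d = 0; estimates at the upper bound are flagged
saturated. Standard errors come from the observed curvature; clade
means use a site-bootstrap SE (default 100 replicates, seeded,
distances re-estimated per replicate).

Neighbor joining is delegated to scikit-bio with negative branch
lengths clamped to zero.

## Rate-constancy tests

Tajima's relative rate test counts lineage-unique differences m_A
(A differs, B = outgroup) and m_B over gap-free triplet sites and
refers (m_A − m_B)²/(m_A + m_B) to χ²(1); m_A + m_B = 0 yields p = 1.

The clock LRT fits branch lengths on a fixed rooted bifurcating
topology twice with Felsenstein pruning over compressed site patterns
(gamma mixture averaged per site, missing data as all-ones partials):

- **free fit** — coordinate ascent over branches, each line search on
  log(length + 10⁻⁹) to keep lengths non-negative; 2n−3 identifiable
  parameters (the two root-adjacent branches are confounded).
- **clock fit** — node heights with tips at height zero, n−1
  parameters. Heights are parameterized as the root height plus each
  internal node's *fraction* of its parent's height. Plain
  height-by-height ascent wedges at the ordering constraints (a child
  capped at its parent blocks both coordinates); the fractional
  parameterization gives every coordinate fixed bounds and rescales
  whole subtrees per move, and matches derivative-free joint
  optimization to ~10⁻⁴ log-likelihood units in spot checks.

Both ascents stop when a full round gains < 10⁻⁶ lnL. The free fit is
initialized at the clock solution, so lnL_free ≥ lnL_clock by
construction. The statistic 2(lnL_free − lnL_clock) is referred to
χ²(n−2) — the standard degrees of freedom for a fixed rooted
bifurcating topology. Root placement is by explicit outgroup; there is
no automatic rooting.

Published p-values for the real opsin alignments are not reproduced
here: they require sequence retrieval plus a specific
alignment/trimming toolchain. The tests are instead validated on
simulated data (below), where their type-I error at α = 0.05 is
checked against the binomial 95% interval and null p-values against
uniformity.

## Reconciliation and Dollo mapping

LCA reconciliation maps each gene node to the LCA of its children's
species images; a node is a duplication iff its image equals a child's
image. Losses are placed on the sibling species branches skipped along
each child's image path (the last step is exempt at speciation nodes).
Gene trees are assumed rooted by the supplied outgroup; species-tree
polytomies are allowed and treated as hard. One caveat for sparse gene
trees: species sampled in the species tree but absent from the gene
tree surface as loss events (e.g. the whitefly branch in the aphid
UV-opsin fixture); duplication placements are unaffected.

Dollo mapping places a single gain at the LCA of all carriers and
returns the maximal branches below it whose entire scored leaf set
lacks the family — the unique minimum under single-gain parsimony
(verified against subset enumeration in the tests). Species missing
from the presence matrix are treated as unsampled, not absent. Only
the minimum-loss solution is reported.

## Locus arithmetic

Coordinates are 1-based inclusive gene ranges. Both the between-gene
gap (downstream start − upstream end) and the outer span (max end −
min start) are exposed, because published interlocus distances mix the
two conventions across rows; for non-overlapping records
span = gap + len₁ + len₂ − 2 under these definitions. Overlapping
records report gap 0 with an overlap flag. BED export converts to
0-based half-open.

## Simulator

Sequences evolve from an equilibrium-drawn root along a newick tree;
each site is assigned one discrete-gamma category for the whole tree
(rates are drawn, not marginalized, so the same gamma machinery is
exercised end to end), and each branch applies P(length × branch
multiplier × site rate). A single seeded generator drives all draws;
identical seeds give bit-identical alignments.

Forced tuning-site switches model a selective sweep at a spectral
tuning site: on the named branch the site is overwritten with a
residue non-conservative relative to the parent state (or a specified
residue) and the forced state is held fixed in all descendants — the
generative analog of a derived state maintained by selection, and the
property the survey is supposed to detect.

The duplication scenario builds an ultrametric pectinate ingroup
(default step 0.03 substitutions/site between successive splits), a
duplication on the ingroup stem producing mirror-image paralog clades,
a der-stem rate multiplier, and an outgroup singleton; it emits the
matched gene tree, species tree, and leaf map so reconciliation can be
exercised on the same object. The clock scenario is an ultrametric
pectinate tree (step 0.08) with one optionally rate-scaled terminal
branch.

## Validation design and problem sizes

The published divergence means and p-values for the real alignments
are inputs-dependent and out of scope; the statistical layer is
validated by properties instead, at sizes chosen to be decisive yet
desk-scale:

- ML distances vs an independent dense-grid oracle (scipy `expm`,
  10⁻³ grid) on 200-site pairs — agreement to the grid step.
- Type-I error of both rate tests over 200 null simulations (3 taxa ×
  500 sites for Tajima; 4 taxa × 300 sites for the clock LRT) within
  the binomial 95% interval of α = 0.05, plus a KS uniformity check
  on the null p-values.
- Duplication scenarios with stem multiplier 3: the accelerated clade
  shows the larger mean outgroup divergence in ≥ 95/100 seeds, and
  the survey recovers a median ≥ 80% of truly shifted sites over 50
  seeds (500 sites, 5 shifted sites). The dominant non-recovery mode
  is outgroup drift at fast sites, which removes the ancestral-state
  anchor (condition iii) — a real limitation of outgroup-anchored
  ancestral assignment, not an implementation artifact.

What the simulator does *not* emulate: indels and alignment error,
codon-level effects and dN/dS, among-lineage compositional drift, and
site-specific structural constraints. Passing these tests therefore
shows the estimators are correct under the model they assume, not that
the model captures every feature of real opsin data.

## Known limitations

- The clock LRT assumes the fitted topology; no topology search is
  performed anywhere.
- `trim_gappy_columns` is a plain per-column gap-fraction filter
  (default threshold 0.5, `X` counts as a residue), not a dynamic
  slope-based trimmer; outputs are labeled accordingly.
- The Tajima test conditions on the outgroup being outside the (A, B)
  pair; it does not verify that assumption.
- Bootstrap SEs for clade divergences are Monte-Carlo estimates;
  their replicate count (default 100) is a convention, not a derived
  quantity.
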