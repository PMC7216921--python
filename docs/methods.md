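# Methods

## The model

`nitromet` treats metal dependence (Mo vs. V vs. Fe cofactor) as a property
encoded in the ~30 residues lining the nitrogenase D-subunit cofactor
pocket, and infers it for sequences whose dependence is unknown — including
statistically reconstructed ancestors — from a classifier trained on
sequences of known dependence.

### Substitution model and site features

All sequence probability is computed under the Jones–Taylor–Thornton (JTT)
amino-acid replacement model. The exchangeability and frequency tables ship
as a PAML-dialect text file (`src/nitromet/data/jtt.dat`); the rate matrix
is built as Q_ij = S_ij·π_j, balanced by detailed balance, and normalized to
one expected substitution per site per unit time. Transition probabilities
P(t) = exp(Qt) are computed from the symmetrized spectral decomposition
(exact for a reversible model, and cheaper and more stable than a generic
matrix exponential; tests cross-check it against `scipy.linalg.expm`).

An observed residue is encoded as a probability distribution over the 20
amino acids: the weighted average of

1. a point mass on the observed residue,
2. the JTT transition row from that residue after a short evolutionary
   distance (default 0.01 substitutions/site) — nearby residues borrow
   probability from plausible one-step neighbours, and
3. a diffuse regularizer (default: the JTT equilibrium frequencies), which
   keeps every amino acid at non-zero probability.

The three weights default to the plain unweighted average (1/3, 1/3, 1/3);
they are configurable, as is the regularizer vector, so a Dirichlet-mixture
profile can be plugged in. Gap and ambiguity characters carry no residue
information and are encoded as the regularizer alone. A sequence restricted
to 30 active-site positions therefore becomes a 600-dimensional feature row
in which every consecutive 20-block sums to one.

### Marginal ancestral reconstruction

Ancestors are reconstructed on a fixed rooted tree with branch lengths in
substitutions/site. Felsenstein pruning computes, per internal node and
site, the exact marginal posterior over the 20 states given all leaves, with
the equilibrium frequencies as root prior and sites independent; an
outside ("up") pass propagates the information from the rest of the tree, so
posteriors condition on *all* data, not just the subtree. Per-site scaling
keeps the computation stable on large trees; total log-likelihood is
retained and is invariant to re-rooting (a property test asserts this —
under a reversible model the root placement is statistically irrelevant).

Point ancestors are the per-site argmax of the marginal posteriors, with
exact ties broken toward the alphabetically first residue. Gaps are handled
as a separate presence/absence character under Fitch parsimony, with
ambiguous assignments resolved toward presence — a residue, not a hole, is
the conservative input for downstream feature extraction. Bayesian-sampled
ancestor variants draw each site independently from its posterior (default
100 samples per node, seeded). Note the package reconstructs *marginal*
posteriors and takes their argmax as the point ancestor rather than running
a joint maximum-likelihood reconstruction: every downstream consumer
(classification, sampling, support summaries) operates on site posteriors,
for which the marginal quantities are the exact objects.

### Classification protocol

Training rows are labeled Nif/Vnf/Anf; unknown-labeled rows are excluded
from training and classified afterwards. The protocol, replicated ten times
by default:

* random 60/40 train/test split (unstratified by default; a stratified
  option exists),
* per-sample class weights w(c) = n_train/(3·count(c)) — inverse class
  frequency, so the rare V and Fe classes are not swamped by the Mo
  majority,
* RBF kernel with γ = 1/(n_features·Var(features)), the variance pooled over
  the whole training feature matrix,
* regularization parameter C selected from {0.1, 1, 10, 100} by five-fold
  cross-validated multiclass accuracy on the training split (deterministic
  contiguous folds; ties go to the smallest C),
* one-vs-rest: one weighted binary SVC per class; a sample's predicted label
  is the class whose hyperplane it sits deepest inside, and the per-class
  signed distances are reported as classification support.

The one-vs-rest machines are fit explicitly (not through a multiclass
wrapper) so that the reported distances are genuine per-class hyperplane
distances and the class weighting enters as per-sample weights, exactly as
the weight formula states. After the evaluation replicates, the deployed
model is refit on 100% of the labeled data using the last replicate's
cross-validated C; the final replicate's split model is retained alongside
for audit. A PCA check reports the minimal number of principal components on
which Nif separates from Vnf∪Anf and Vnf from Anf, using exact disjoint-range
(1-D) or LP-feasibility (k-D) separability tests.

### Pocket volumes

The cavity volume of a structure is measured on an axis-aligned 0.5 Å
lattice anchored at the bounding-box minimum of a user-supplied inclusion
region (a union of spheres; the anchor rule makes runs bit-reproducible).
Lattice points are removed if they fall within any receptor atom's van der
Waals radius plus a 1.09 Å pad (Bondi-style radii table with common metals;
the cofactor group is excluded from the receptor since the pocket being
measured is the space it occupies), then filtered to the convex hull of the
pocket-lining atoms (receptor atoms within 8 Å of the region), and finally
to a single 26-connected lattice component (seeded, or the largest). Volume
is the retained point count × spacing³. Group comparisons report means, SDs,
ranges, and pairwise two-sided Mann–Whitney rank-sum tests of median
differences.

## The synthetic family generator

The generator emulates the structure of the nitrogenase D(HDK) phylogeny so
that every stage has known ground truth: clades Nif-I (30 taxa), Nif-II
(20), and an uncharacterized/V/Fe lineage of Clfx (3), F-Mc (8), Mb-Mc (8),
Vnf (14), and Anf (14), on the fixed topology
((Nif-I,Nif-II),(Clfx,(F-Mc,(Mb-Mc,(Vnf,Anf))))). Clfx, F-Mc, and Mb-Mc are
emitted unlabeled so the classify-the-uncharacterized path is exercised;
their planted active sites are Mo-like, and V/Fe sizes are equal (14/14) to
avoid sampling bias between the minority classes.

Sequences (500 residues) evolve by JTT from an equilibrium root. Thirty
active-site positions carry planted structure:

* **10 universally conserved residues** (Val-70, Gln-191, His-195, Cys-275,
  Arg-277, Ser-278, Gly-356, Phe-381, Gly-424, His-442) are invariant
  everywhere — these reconstruct with posterior 1.0, as absolute
  conservation implies.
* **Clade-signature residues** — 3 Mo-specific (Ala-65, Arg-96, Gln-440),
  6 V-specific (Leu-69, Trp-300, Thr-355, Pro-358, Pro-425, Val-427),
  5 Fe-specific (His-69, Pro-355, Lys-359, Pro-427, Ala-441), and 6 shared
  by the V/Fe union (Cys-65, Lys-96, Leu-360, Lys-380, Arg-426, Asn-440) —
  are switched in on the stem of the owning clade and invariant within it.
* At a signature position a clade does **not** own, the clade carries a
  deterministic two-residue polymorphism: members split between two decoy
  residues disjoint from every signature residue at that position. A clade
  left free to drift there would become accidentally conserved with
  probability ≈ e^(−rate·tree-length) per site, which would inject spurious
  rows into the unique-residue table; the planted polymorphism rules this
  out under every seed. The split point varies by position (multiplicative
  hash) so the within-clade variation decoheres across sites instead of
  forming one dominant principal component; decoy residues are chosen with
  high JTT exchangeability toward the owning clade's residue (e.g. S/A
  opposite Pro-358), which keeps the ancestral-state contest at such
  positions decided by the tree geometry rather than by rate artifacts. The
  Mo-side decoys at 355–360 spell an IGG·RP-like loop, so the Mo backbone
  ancestors reconstruct a NifD-like loop while the V/Fe ancestor
  reconstructs the V-form TGGPRL.
* **Six filler active-site positions** (59, 66, 192, 196, 357, 382) evolve
  at a 0.2 rate multiplier (active sites are constrained relative to the 1.0
  background). One anchor taxon per clade is pinned to the ancestral state
  at fillers, which provably blocks accidental clade-unique conservation
  there: a drifted group-wide residue would have to be absent from every
  other group, but each group's anchor still carries the shared ancestral
  state.

Branch lengths were chosen once so that the family reproduces the field's
observed identity structure — between-lineage full-sequence identity ≈ 46–50%
against Vnf↔Anf ≈ 68–74% and within-Nif ≈ 78% — and so that the V/Fe
ancestor's marginal reconstruction is dominated by its descendant clades:
the V stem is short (0.015), the Fe stem long (0.22, Fe-nitrogenases being
the faster-diverging lineage), and the edge above the V/Fe ancestor is long
(0.40). With this geometry the V/Fe ancestor reconstructs the V-form
carbonate-loop residues (T-355, P-358, L-360) and classifies Vnf, while all
deeper ancestors classify Nif — under both the ML-sequence and the
posterior-distribution encodings.

What the generator does *not* emulate: indel evolution (simulation is
gap-free; gap handling is exercised by hand-built fixtures), rate
heterogeneity across background sites, site-interdependence, alignment
error, and database curation noise. Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline under the stated
evolutionary model — not robustness to misalignment or model violation in
real data. One known limit of marginal reconstruction shows up directly in
the synthetic truth: a clade-exclusive residue that is both rare and slow
under JTT (Trp-300) is unrecoverable at the V/Fe ancestor, because a single
substitution on the short V stem explains the data better than two flanking
events; the ancestor's feature block there simply stays uncommitted, and
classification is carried by the other signature positions.

Structural fixtures are analytic: a Fibonacci-lattice shell of carbon atoms
of radius R leaves a carveable cavity of radius R − 1.70 − 1.09 with a
closed-form volume; a two-chamber variant (two disjoint shells) checks that
the contiguity filter keeps exactly one cavity; a toy ligand complex places
single-atom residues at exact distances for the 5 Å shell test.

## Numerical and design choices

* Transition matrices clip tiny negative eigendecomposition round-off and
  renormalize rows; posteriors renormalize per site.
* The pairwise reference mapping uses global alignment with BLOSUM62 and
  affine gaps (open −11 / extend −1) — the standard scoring for
  well-conserved protein pairs; a DP oracle validates the induced maps.
* Alternate PDB conformer locations resolve to the highest-occupancy copy;
  hydrogens are ignored in distance work (crystal structures carry them
  inconsistently).
* Cross-validation folds are deterministic contiguous blocks: reproducible,
  and adequate because replicate splits are already randomized.
* `compare_volume_groups` uses `scipy.stats.mannwhitneyu` (exact for small
  tie-free samples); a permutation-enumeration oracle pins its values in
  tests.
* Problem sizes: the default family (97 taxa × 500 residues) reconstructs
  and trains in a few seconds; the test suite and the acceptance script
  each complete in about a minute on one CPU.

## Known limitations

* Joint vs. marginal reconstruction can disagree at individual sites; only
  marginal ancestors are implemented (see above for why that is the right
  object for this pipeline).
* The classifier is a separating-hyperplane method on near-separable data:
  support distances are comparable within a run, but are not calibrated
  probabilities.
* Real-structure inclusion regions must be supplied by the user (sphere
  unions in JSON); the package does not model structures and ships no
  crystallographic coordinates.
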