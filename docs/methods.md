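# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical choices a user reproducing results should know about.

## Family curation and coordinates

Sequence identifiers are assumed to follow the UniProt entry-name
convention (`B2MG_HUMAN`); the token after the last underscore is the
species label unless an explicit id→species TSV is supplied, which takes
precedence. When a species has several sequences, non-fragments are
preferred; among the remainder the representative maximizes the mean
pairwise percent identity (computed over columns where both rows are
non-gap; zero-overlap pairs score 0) to the sequences of *other* species,
with lexicographic id as the tie-break. Identity was chosen over
similarity or tree distance because it is deterministic, cheap and the
conventional reading of "most similar"; the scorer is a plain function and
can be swapped.

Residue positions of interest are given in the numbering of a reference
row and converted to alignment columns by counting its non-gap symbols; no
signal-peptide arithmetic is applied — the caller supplies coordinates in
the frame of the reference row as given.

## Conservation annotation

Three per-column measures:

* **consensus** — most frequent non-gap residue; its percentage uses all
  rows in the denominator (a gap-rich column cannot reach 100%); ties
  break alphabetically.
* **conservation** — the number of the ten Livingstone–Barton
  physicochemical classes (hydrophobic, polar, small, tiny, aliphatic,
  aromatic, positive, negative, charged, proline) whose status is uniform
  down the column: present in every residue or absent from every residue.
  The table is hard-coded and versioned in `conservation.PROPERTY_TABLE`.
  Gap policy `exclude` (default) ignores gaps; `penalize` treats a gap as
  a property-less residue, so any gap defeats every "present in all"
  class. `exclude` is the default because a score of 10 should be
  attainable for a column whose minority symbols are gaps or rare
  variants.
* **quality** — for every ordered pair of differing residues (weighted by
  their counts) the ratio BLOSUM62′(a,b)/max(BLOSUM62′(a,a), BLOSUM62′(b,b))
  is a conservativeness in [0,1], where BLOSUM62′ is BLOSUM62 shifted by
  +4 (its negated minimum) so ratios are defined and non-negative. The
  column score is 1 minus the mean penalty (1 − ratio) over all ordered
  non-gap pairs: exactly 1 for a fully conserved column, 0 for the
  theoretical worst. A display scale (default ×215, the approximate
  ceiling of values reported by interactive alignment viewers) is
  configurable. Absolute quality values from other tools are
  version-specific; only orderings are meaningful, and only orderings are
  tested. Pair weighting is per ordered sequence pair; the alternative
  (per distinct residue pair) would ignore column composition.

## Substitution model and distances

The JTT replacement model is bundled as a PAML-dialect data file (lower
triangular exchangeabilities + frequencies, ARNDCQEGHILKMFPSTWYV order).
The generator is built as Q = S·diag(π), rows zeroed, normalized to one
expected substitution per site per unit branch length, and diagonalized
once through the symmetrized form diag(√π)·Q·diag(1/√π), so P(t) = exp(Qt)
costs two 20×20 multiplications.

The pairwise distance is the maximum-likelihood branch length: t̂
maximizing Σ over shared non-gap columns of log[π(a)·P(t)<sub>ab</sub>],
optimized by bounded scalar minimization on [0, 10] substitutions/site
(tolerance 1e-10); hitting the bound raises a saturation warning, and the
pair-count matrix is symmetrized first so the distance is exactly
symmetric in floating point. No gamma correction is applied to distances
(plain ML distance, matching common neighbor-joining practice); rate
variation enters in the ancestral-reconstruction stage. Identical
sequences return exactly 0.

Neighbor joining is the standard Saitou–Nei agglomeration with the
Q-criterion; ties break on the smallest (row, column) index pair in the
current label order, negative branch-length estimates are clamped to zero
(logged), and the final three taxa are joined by the closed-form
three-point formulas. Bootstrap supports are percentages of
column-resampled replicates containing each bipartition of the
point-estimate tree; replicates with an undefined distance are dropped and
counted. Supports are treated as properties of bipartitions, not node
identities, so rerooting reassigns rather than moves them. Outgroup
rooting places the root at the midpoint of the outgroup's pendant edge —
the natural uninformed choice when no molecular-clock argument fixes a
position.

## Tree comparison and reconciliation

Robinson–Foulds distance is the unweighted symmetric difference of
nontrivial bipartition sets, computed on the unrooted form of each tree;
multifurcating trees simply contribute fewer splits. Gene trees with
several tips per species are pruned to one tip per species (caller
chooses which) before comparison with a species tree.

Reconciliation is classical LCA mapping: tips map through the supplied
gene→species table, internal nodes to the LCA of their children's images;
a node is a duplication iff its image equals a child's image. Losses are
summed per gene edge (u→v) as depth(M(v)) − depth(M(u)) − 1, plus one if
u is a duplication, floored at zero, with depth counted in edges from the
species root. On binary species trees this is the standard parsimony loss
count; under multifurcations it is a lower bound and the result carries a
flag saying so. The weighted score uses the duplication/loss costs 1.35
and 0.9 by default, the costs conventionally used for this family's
published reconciliation; a zero-cost "conditional duplication" class
offered by some tools is not implemented (it is tool-specific and
undefined in general). Root inference reconciles every rooting of an
unrooted gene tree (2n−3 candidates, each rooted at the edge midpoint)
and ranks edges by score, then by a canonical edge id, so the output is
deterministic.

## Ancestral reconstruction

Likelihoods use Felsenstein pruning with per-node rescaling (each partial
divided by its maximum; logs accumulated) — scaling rather than log-space
partials keeps the inner loop to matrix products. Gaps and `X` are missing
data (all-ones partials). Rate variation is the usual discrete gamma:
k = 4 equal-probability categories, each represented by its conditional
mean computed from the incomplete-gamma identity and renormalized to mean
exactly 1; shape α defaults to 1.0 and can be estimated by bounded
maximum likelihood on [0.05, 20]. Branch lengths are taken from the input
tree, not re-optimized — the stage is deliberately modular; feed it a tree
whose lengths you trust.

Marginal reconstruction runs an inside–outside pass per category and
mixes node posteriors with the per-site category posterior weights; root
posteriors use π as prior. Joint reconstruction is max-product dynamic
programming over internal states per category, keeping the best
category's assignment. The joint log-likelihood can never exceed the
summed marginal site log-likelihoods, and the test suite checks both
against exhaustive enumeration on four-tip trees.

## Equilibrium unfolding and kinetics

The two-state linear-extrapolation (Santoro–Bolen) model is fit with six
free parameters (ΔG, m and two linear baselines) by unweighted nonlinear
least squares (no per-point error model is available for these data).
R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ so ΔG is in kcal/mol; temperature is curve
metadata (default 293.15 K for equilibrium data, 303.15 K for the
stopped-flow presets). Initialization: baselines from linear fits of the
first/last three points, C<sub>m</sub> from the half-signal crossing,
m = 2 kcal mol⁻¹ M⁻¹. A fit whose optimum leaves fewer than two points in
either baseline region (folded fraction >0.9 / <0.1) is flagged
"poorly determined baselines". Parameter errors come from the covariance
at the optimum; the C<sub>m</sub> error is first-order propagated.

Two ΔΔG estimates are always reported: the direct difference of fitted
ΔG values and the midpoint route ⟨m⟩·(C<sub>m,a</sub> − C<sub>m,b</sub>).
Under the package's standard noise conditions (2% of signal span) the
direct route inherits the large uncertainty of baseline extrapolation
(≈0.4–0.5 kcal/mol per fit), while the midpoint route, in which those
errors largely cancel, is determined to ≈0.05 kcal/mol. The stability
reports and the acceptance script therefore use the midpoint estimate as
the comparison value and print the direct estimate alongside with its
propagated error.

Kinetic traces are fit as offset + ΣA<sub>i</sub>exp(−k<sub>i</sub>t)
(one or two phases) after excluding points inside the instrument dead
time (default 5 ms for 215-nm stopped-flow presets, 0 for conventional
263-nm traces); rates are initialized by log-linear regression of the
decaying residual and reported sorted by decreasing k. Flat traces are
returned flagged `no_signal` rather than as errors. The burst amplitude —
signal completed before the dead time — is
(expected initial − fitted y(0)) / (expected initial − fitted offset).

## Structure superposition

Cα atoms are read from PDB files (gemmi), one per residue, keeping the
highest-occupancy alternate location (ties → altloc A). Partially
occupied residues are included by default — which residues to exclude is
a judgment call the caller can make through the occupancy-threshold flag.
Pairing is by residue number (point mutations allowed), not by sequence
alignment; the two β2-m structures share numbering and general alignment
pairing is out of scope. The optimal rotation is the Kabsch SVD solution
with determinant correction; no outlier trimming is performed, for
determinism.

## Synthetic data: what it emulates, and what it does not

The family simulator grows a gene tree along a rooted species tree:
duplications and losses are Poisson events on gene lineages at rates per
unit species-tree branch length (a duplication copies the subtending
lineage, a loss prunes it; speciations follow the species tree), then
sequences evolve site-independently by exact transition probabilities,
with optional continuous-gamma per-site rates. A designated tracked
column is overwritten post hoc with clade-specific states so annotation
and ancestral-reconstruction stages have a deterministic target; the
default demo assigns Leu to the basal cartilaginous-fish, bony-fish and
amphibian lineages and Trp elsewhere, the pattern reported for β2-m
position 95. The default species tree has 8 taxa with a basal outgroup
(RAJEG) — a deliberately desk-scale stand-in for the ~96-species
vertebrate family, so absolute support values, RF distances and posterior
probabilities from the demo are not comparable to the full-family ones.
No indels are simulated (alignment construction is out of scope; gapped
inputs are exercised with hand-made fixtures), no heterotachy, no codon
structure. Passing recovery tests therefore shows the estimators are
correct under the generating model, not that real alignments satisfy
that model.

Biophysics presets carry the experimentally characterized parameters:
equilibrium ΔG/m = 7.6/4.0 (wild type) and 6.6/4.0 kcal·mol⁻¹(/M)
(variant), i.e. midpoints 1.9 and 1.65 M GdnHCl and a 1.0 kcal/mol gap —
the ΔG and m values are chosen to reproduce the reported midpoints and
stability difference with a shared, typical m; rates 1.65 s⁻¹ (fast
folding, 215 nm), 0.003 s⁻¹ (slow native-structure acquisition, 263 nm),
0.22/0.4 s⁻¹ (wild-type/variant unfolding at 5.1 M GdnHCl). Curve noise
defaults to Gaussian with σ = 2% of the model signal span (41 points,
0–4 M); traces use SNR 20 (σ = |amplitude|/20) on windows matched to each
phase (10 s/1 ms for fast folding, 1500 s/1 s for the slow phase,
20 s/10 ms for unfolding). CD baseline ellipticities are realistic far-UV
values fixed once; they affect nothing but plot scale.

## Problem sizes and determinism

Recovery tests use 8-taxon families with 200–1000 sites, 10–50 bootstrap
replicates, 500 or fewer ASR sites, 50 equilibrium replicates and ≈10
kinetic replicates per preset — sizes chosen so the full suite exercises
every stage while staying desk-scale. Every stochastic stage takes an
explicit integer seed and is bit-reproducible for a fixed seed; the
pipeline records seeds in its provenance block.

## Known limitations

* Pairwise ML distances ignore among-site rate variation; deep
  divergences are therefore compressed relative to a gamma-corrected
  estimate.
* Loss counts under multifurcating species trees are lower bounds.
* The joint reconstruction reports the best single rate-category
  assignment per site rather than maximizing over the category mixture
  exactly.
* Branch lengths are never re-optimized in the ASR stage.
* Kinetic fitting assumes well-separated phases; strongly overlapping
  rates (within ~3×) trade off amplitude and are returned with large
  standard errors rather than rejected.
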