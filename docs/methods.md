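# Methods

This note documents the models and procedures implemented in `epiclass`,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic-data tests do and do not establish about real antigens.

## Coordinates and data model

All intervals are 1-based and inclusive at both ends; a region `(19, 39)`
covers 21 residues. Only the 20 canonical amino-acid letters are accepted —
every attribute table downstream is defined solely for them, so sequences
containing B/Z/X/U/O are rejected at parse time rather than silently
imputed. Score tracks hold one value per residue on [0, 1]; plots
conventionally use a 0–100 axis, which is a display scaling only.

Region labels form a closed vocabulary: `epitope`, `nonepitope`,
`reactive`, `predicted`. Residues covered by neither `epitope` nor
`nonepitope` are *unassigned*: they contribute no training k-mers of their
own but count as negatives in per-residue evaluation, mirroring how mapped
proteins are scored over their full length.

## K-mer decomposition and labeling

Sequences decompose into all substrings of length 3–15 at stride 1. The
stride is fixed at 1 for training: dense enumeration maximizes the labeled
set, and the count obeys Σ_k max(0, ⌊(L−k)/step⌋+1), verified against
brute-force enumeration in the tests.

A k-mer's class comes from the fraction of its residues inside regions of
each class. Three rules are implemented:

* `any_overlap` — fraction > 0,
* `majority` — fraction ≥ 0.5 (the default; "50 % or more", so an exact
  half-overlap counts),
* `full_containment` — fraction = 1.

The positive sets are nested (full ⊆ majority ⊆ any), which is property-
tested, and on single-epitope antigens the majority rule's residue-level
false positives never exceed any-overlap's. When adjacent epitope and
nonepitope regions let a k-mer reach the bar for both classes, the epitope
label wins: the method is tuned for sensitivity to epitopes, and already
loses sensitivity for epitopes under 5 residues. Residues without any
annotation count toward neither class but stay in the denominator, so
k-mers straddling unannotated sequence are conservatively down-weighted.

## The 33 attributes

Every attribute is a function of residue composition, so the classifier is
composition-only by construction (no positional profiles):

| group | attributes | units |
|---|---|---|
| residue composition | 20 mole percents | % |
| charge/character groups | positive RHK, negative DE, uncharged STNQ, special CGP, hydrophobic AVILMFW | % |
| hydropathy | GRAVY = mean Kyte–Doolittle value | — |
| side-chain bulk | aliphatic index, AI = X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu) | — |
| elemental | C, H, N, O, S atom percents | % |
| charge balance | isoelectric point | pH |

Peptide length is deliberately **not** an attribute (the set has exactly
33 members); `include_length=True` appends it as a 34th column for
sensitivity analyses, since length is a k-mer metadata rather than a
chemistry descriptor and dense k-mer sets are length-balanced by design.

Atom counts use free-amino-acid molecular formulas minus one water per
peptide bond, so a 1-mer equals the free amino acid (glycine: C2H5NO2 → C
20 %, H 50 %, N 10 %, O 20 %). The alternative residue-formula convention
differs only by one water per peptide and washes out for k ≥ 3; one
convention had to be pinned and this one makes the smallest case exact.

The isoelectric point solves net charge = 0 for a Henderson–Hasselbalch sum
over the two termini and the ionizable side chains (R, K, H positive; D, E,
C, Y negative) with a pinned Bjellqvist-style pKa table (N-term 7.5, C-term
3.55, K 10.0, R 12.0, H 5.98, D 4.05, E 4.45, C 9.0, Y 10.0). Net charge is
strictly decreasing in pH, so bisection on [0, 14] (60 iterations, residual
|charge| < 1e-4 guaranteed long before that) is exact to machine-level
tolerance; the two-group case reduces to the midpoint of the terminal pKas,
which the tests check in closed form. Residue-position-specific pKa
adjustments are intentionally omitted: the table is a single documented
constant, and only between-peptide contrasts matter for classification.

All attributes are computed from a per-antigen cumulative one-hot matrix,
so featurizing every k-mer of an antigen costs one pass over the sequence
— this is what keeps full-panel training (hundreds of thousands of k-mers)
in the tens of seconds.

## SMOTE

Epitope k-mers are a minority (roughly 1:4 at typical annotation
densities). For each minority row x a synthetic row is drawn as
x + u·(x_nn − x) with u ~ U[0,1] and x_nn one of the k = 5 nearest minority
neighbors by Euclidean distance on the raw attribute space (attributes are
commensurable percents except GRAVY/AI/pI; a z-scaling flag exists but the
default is raw and documented). Synthetic rows remain inside the minority
convex hull — property-tested via pairwise bounding boxes. The default
target ratio is 1:1; the exact deficit is generated (not just multiples of
100 % per row) so the balanced counts match the target exactly.

SMOTE runs strictly inside each training fold. Oversampling before the
train/test split would leak interpolated copies of test-adjacent rows into
training and inflate every held-out metric.

## Decision tree and forest importances

The tree is CART-style: at each node the (attribute, threshold) pair
maximizing the Gini impurity decrease is selected over all attributes, with
candidate thresholds at midpoints of consecutive distinct sorted values.
Determinism is pinned: ties break by lowest attribute index, then lowest
threshold. Zero-gain splits are accepted (impurity decrease is non-negative
for every split by concavity), so XOR-like interactions resolve one level
down, as in standard CART implementations. When a midpoint rounds up to the
right-hand value for adjacent floating-point values — which SMOTE's
near-duplicate rows make likely — the threshold falls back to the left
value so the realized partition matches the counted one.

Defaults: max depth 12, min leaf 5, min split 10. These are conventional
mid-size-tree values exposed in the configuration and recorded by
`summary()`; small instances (≤ 12 rows) are verified node-by-node against
an exhaustive split search, and training accuracy matches scikit-learn's
CART under identical constraints.

A k-mer's score is its leaf's epitope fraction, so scores live on [0, 1]
and the k-mer-level operating cutoff defaults to 0.5.

`forest_importance` grows bootstrap trees with √p random attributes per
split and reports *decreased Gini* (mean over trees of the total
row-weighted impurity decrease credited to each attribute) and *decreased
accuracy* (mean out-of-bag accuracy drop after permuting the attribute
among OOB rows). The acceptance property is rank recovery — planted
discriminative attributes reach the top ranks — not any particular numeric
importance, which is training-set- and ensemble-size-dependent. The
function default is 10,000 trees; tests and the results API subsample rows
and use smaller ensembles since rank stability, not variance of the
estimate, is what is asserted.

## From k-mers to regions

The per-residue score is the fraction of covering k-mers predicted
positive (an alternative — mean predicted probability of covering k-mers —
is available behind a flag; the fraction form is pinned as the default
because it is scale-free in the leaf probabilities). Predicted regions are
maximal runs of residues scoring ≥ 0.2, discarding runs shorter than 3 (the
smallest k-mer). A region's reported score is the mean residue score over
the region. For synthesis, regions are padded by 3 residues per border,
clamped to the sequence — a 9-residue core becomes a 15-mer peptide.

SPOT reactivity tracks mirror the pentadecapeptide membrane geometry:
15-mers at stride 3 tile the antigen, each residue's raw score is the
number of reactive peptides covering it, and the track is rescaled so its
maximum is exactly 1 (all-zero if nothing is reactive).

## Evaluation

The evaluation unit is the residue, over whole proteins. AUC is the
trapezoid integral of the ROC curve swept over all distinct scores and is
asserted equal (to 1e-12) to the pairwise-ranking probability with ties at
1/2. Cohen's κ uses the standard marginal expectation. Cutoff policies:
`default` (the configured operating cutoff, 0.2), `max_precision` (sweep,
ties to higher specificity), and `max_auc_point` — implemented as the
Youden-optimal point J = TPR − FPR, since "maximizing AUC" at a single
cutoff is otherwise undefined. Multi-antigen summaries average per-antigen
metrics rather than pooling residues (a `pool` flag offers the
alternative), so long proteins do not dominate.

Cross-validation defaults to grouping by antigen: overlapping k-mers of one
antigen are near-duplicates, and splitting them across folds overstates
held-out performance. A k-mer-stratified mode exists for comparability.

## Percent identity

Panel identity matrices use pairwise global alignment with affine gaps
(Gotoh, via Biopython's PairwiseAligner) under BLOSUM62 with gap open 10
and extend 0.5 — EMBOSS-needle-style defaults. Percent identity is
identical columns over columns where neither sequence is gapped; the matrix
is symmetric with a 100 diagonal. Alignment scores are cross-checked
against an independent dynamic program on short sequences.

## Synthetic antigens

The generator emulates exactly the signal the classifier exploits:
compositional enrichment of epitope segments. Background residues are drawn
i.i.d. from a background vector (uniform 1/20 by default, so enrichment is
the only signal; a UniProt-like preset adds realistic base frequencies);
inside planted epitopes the background is re-weighted by exp(effect_size)
on the enriched set {R, H, K, E, P, W} — the charged/special residues that
shift isoelectric point and hydropathy — and renormalized. Everything
outside epitopes is annotated `nonepitope`.

Defaults, chosen once as the study conditions: 200 antigens of 100–180
residues (metalloproteinase-catalytic-domain scale), two non-overlapping
epitopes per antigen of 8–20 residues (never under 5, where windowed
labeling loses sensitivity), effect size 3. At effect 0 the generator is an
exact null — epitope composition is chi-square-indistinguishable from
background — and the full pipeline's held-out AUC sits at chance (~0.5).
At effect 3, held-out per-residue AUC is ≈ 0.98 and every planted epitope
panel member is recovered at the 0.2 cutoff.

What this does *not* show: real epitopes are not i.i.d. compositional
islands — they have positional structure, overlap structural constraints,
and their annotations carry experimental noise and incompleteness. Passing
the synthetic recovery tests establishes that the pipeline's machinery
(labeling, featurization, rebalancing, tree induction, aggregation,
calling, evaluation) is correct and well-calibrated, not that any
particular real-world accuracy will be achieved; on curated real panels the
attainable AUC is bounded by annotation quality and class homogeneity.

## Problem sizes

The test suite and the acceptance script train on 200 synthetic antigens
(~340,000 labeled k-mers, ~530,000 rows after SMOTE) with 30 held-out
antigens for the strong-signal condition, and 60/20 for the null; forests
for importance ranking use subsampled rows and modest ensembles. These
sizes give stable estimates (AUC varies by < 0.01 across seeds) at about a
minute of single-CPU compute for the full end-to-end run.

## Known limitations

* Composition-only features cannot represent positional motifs; two k-mers
  with permuted sequences are indistinguishable by design.
* Linear epitopes only — no discontinuous/conformational epitope handling.
* The pKa table and atom-count conventions are pinned choices among several
  defensible ones; absolute pI/atom values are convention-dependent, while
  classification depends only on contrasts.
* Curated real datasets must be supplied by the user as FASTA plus interval
  TSV (accessions are resolved by the user; no remote fetching is built
  in).
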