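# Methods

This note documents the models and procedures implemented in `pepforge`,
the choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish.

## Task and data model

The task is binary classification of short peptides (ACP vs. NACP) from the
primary sequence alone. A peptide is a non-empty string over the 20
canonical residues; lowercase input is normalized on ingest and any other
character (B, J, O, U, X, Z, `*`, gaps) is rejected with the record id and
the offending character, rather than silently dropped — ambiguous residues
have no defined value in the physicochemical scales below, so imputing them
would be invisible noise. Labels attach via an `ACP`/`NACP` header prefix or
an explicit `id → label` table; the policy is always explicit, never
inferred from headers opportunistically.

## Redundancy reduction

Near-duplicate sequences inflate apparent accuracy when copies land on both
sides of a split. The filter is greedy incremental clustering in the CD-HIT
style: visit sequences longest-first (ties by id), keep a sequence as a new
representative unless its identity to an already-kept representative
*exceeds* the threshold (default 0.90; "more than 90%" is read strictly).
Identity is the maximum number of matched identical residues over all global
alignments scored match=1 / mismatch=0 / gap=0 — equivalently the longest
common subsequence — divided by the shorter length, matching CD-HIT's
default identity denominator. Survivors are returned in input order. The
k-mer prefilter heuristics CD-HIT uses for million-sequence inputs are out
of scope; at the hundreds-to-thousands scale here the exact O(n²) pass is
cheap (a 50×50 DP costs microseconds).

Consequences worth knowing: the filter is idempotent; raising the threshold
never removes more sequences; and every discarded peptide exceeds the
threshold against a survivor at least as long as itself.

## Train/test split

70/30 with the training count set by `round(0.7 · total)` under
round-half-to-even — the unique common convention that reproduces both
standard benchmark splits (344 → 241/103 and 2475 → 1732/743, the second
hitting an exact .5). Stratified by class by default, with per-class counts
allocated by largest remainder under the fixed total; whether the original
protocol stratified is unstated, so both modes exist and stratified is the
default (it is the safer choice under the 1:10 imbalance of the larger
corpus shape).

## Encoders

All four encoders produce probability vectors (non-negative, summing to 1
within 1e-12), which makes fused spaces blocks of comparable scale.

* **AAC** (20): residue frequencies `n_j / L`, columns in fixed alphabetical
  order A…Y.
* **DPC** (400): adjacent ordered-pair counts divided by `L−1`. The divisor
  is chosen as the number of windows so the row normalizes to 1, consistent
  with AAC (`/L`) and TPC (`/(L−2)`).
* **TPC** (8000): width-3 sliding-window counts divided by `L−2`. For
  peptides this short the vector is overwhelmingly zero — the known weakness
  of TPC alone on short sequences.
* **IPseAAC** (20+λ): Chou-style pseudo amino-acid composition with nine
  properties instead of the classic three. Tier n is
  `θ_n = (1/(L−n)) Σ_{k=1}^{L−n} I(R_k, R_{k+n})` with
  `I(R_i, R_j) = (1/m) Σ_m [H_m(R_j) − H_m(R_i)]²` over the m selected
  standardized scales. The final vector is
  `f_u / (1 + w Σθ)` for the 20 composition components and
  `w θ_j / (1 + w Σθ)` for the correlation components, weight `w = 0.05`
  (configurable). λ defaults to 1 and must stay below every encoded
  sequence's length. A `tier_mode="literal"` switch reproduces the variant
  in which every tier averages only adjacent-pair correlations `I(k, k+1)`
  over its own window count; the default `canonical` mode uses pairs n
  apart, since under the literal reading all tiers carry nearly identical
  information.

### Property scales

The nine scales ship in `src/pepforge/data/property_scales.tsv`:
Kyte–Doolittle hydrophobicity, Hopp–Woods hydrophilicity, net side-chain
charge at pH 7 (His +0.1), Bhaskaran–Ponnuswamy average flexibility,
Grantham polarity, Charton–Charton polarizability, Tien et al. theoretical
maximum solvent-accessible surface area; irreplaceability is the affine
inverse of Dayhoff relative mutability (conserved residues score high), and
rigidity is derived from side-chain torsional freedom,
`1/(1 + rotatable side-chain bonds)` with proline elevated for its backbone
ring. Each scale is standardized to mean 0 / population SD 1 across the 20
residues before use, so `I(·,·)` is scale-free and any affine choice in a
raw scale is irrelevant. Users can substitute their own table
(`--property-table`); structural invariants (normalization, reversal
symmetry, zero correlation on homopolymers) hold for any table.

## PCA feature pruning

Fitted on training data only and applied unchanged to test data (no
leakage). Columns are centered by the training mean; the sample covariance
uses divisor Q−1 (Q = training peptides). The eigendecomposition is obtained
through a thin SVD of the centered matrix — mathematically identical to
eigendecomposing the assembled covariance, but O(Q²P) rather than O(P³),
which matters when the fused space has 8441 columns and a few hundred rows.
Components beyond the numerical rank carry eigenvalue 0 and are dropped.
Eigenvector sign is fixed by making each component's largest-magnitude
loading positive, so serialized models are bit-stable. K defaults to the
smallest dimension reaching 95% cumulative explained variance — a standard,
reportable criterion — overridable by an explicit K; either way K is clamped
below Q and to the rank. PCA's sensitivity to outliers is documented, not
mitigated; robust/sparse/kernel variants are out of scope.

## Classifiers and the voting ensemble

* **SVM**: RBF kernel `exp(−γ‖x_i−x_j‖²)`. `(C, γ)` are picked by
  stratified k-fold (default 5) cross-validated accuracy over the canonical
  grid C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}, γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}; exact score ties
  resolve toward smaller C, then smaller γ (the weakest-regularization-last
  rule keeps the choice deterministic). The winner is refit on all training
  rows.
* **Random forest**: 100 bootstrap-bagged trees with random feature
  subsetting per split, majority vote across trees, deterministic per seed.
  (A companion phrase "200 iterations" sometimes attached to such forests
  has no standard meaning next to a fixed tree count and is left
  unresolved; trees = 100 is the operative setting.)
* **Gaussian naive Bayes**: per-class feature means/variances with a small
  variance floor; constant features cancel from the posterior ratio.
* **KNN** (standalone only): Euclidean distance, odd k enforced to rule out
  vote ties, distance ties broken toward the lower training-row index.

The ensemble is SVM ⊕ RF ⊕ NB by weighted majority vote: each base casts its
predicted class per row, a class's score is the summed weight of its voters,
argmax wins. "Best weights" are made operational in two modes — `equal`
(default, reproducible and assumption-free) and `cv_accuracy` (weights
proportional to each base's cross-validated training accuracy). Exact score
ties fall to the SVM's vote by default (empirically the strongest individual
learner in this family), or to the training majority class. KNN is never in
the default ensemble. Class weighting for imbalanced data is exposed
(`class_weight="balanced"`) but off by default.

## Evaluation

Confusion counts use ACP as positive. Metrics are the standard
accuracy = (TP+TN)/N, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
F1 = 2·precision·recall/(precision+recall), and
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)). Any ratio with a
zero denominator is reported as NaN together with its reason — never
silently 0, which would fake a defined score for, e.g., a constant
predictor. Human-readable reports print percentages to two decimals; machine
outputs keep full precision. Identities that hold for every confusion
matrix — accuracy = (sens·P + spec·N)/(P+N), sensitivity↔specificity swap
under positive-class exchange — are enforced by tests.

## Synthetic benchmark

The generator emulates the *compositional* signature of the task: real ACPs
are enriched in cationic and hydrophobic residues that mediate binding to
anionic cancer-cell membranes. NACP residues are i.i.d. from a background
composition (uniform 1/20 by default, to keep the null exactly known and the
generator dependency-free; a measured composition can be supplied);
ACP residues come from the same background exponentially tilted toward
{K, R, L, A, G, F, W}. A single `effect_size` knob controls divergence, with
an exact null at 0. Lengths are uniform on 10–50. `generate_benchmark_shaped`
reproduces the class shapes of the two standard corpora (138/206 and
225/2250) for end-to-end rehearsal at realistic scale and imbalance.

What the generator deliberately does **not** model: positional motifs,
amphipathic helicity, secondary structure, length–class correlation, or any
dipeptide/tripeptide order signal beyond what composition induces. Passing
the signal-recovery checks therefore demonstrates that the pipeline's
plumbing, encoders, pruning and ensemble recover a known compositional
signal and stay at chance under the null — it does not certify accuracy on
real ACP corpora, whose published headline numbers additionally depend on
external databases and unstated hyperparameters and are explicitly not
reproduction targets here.

## Problem sizes and numerical choices

The default end-to-end checks run 200+200 peptides per condition over a
handful of seeds — large enough that mean test accuracy ≥ 0.95 and MCC ≥
0.85 at effect size 2 are stable, while a full fused-space run (8441
columns) stays in tens of seconds. Encoder rows are validated to sum to 1
within 1e-12; PCA eigenpairs satisfy C·v = ∂·v within 1e-7 and the
transformed training covariance is diagonal within 1e-6; metric computations
match direct arithmetic within 1e-12. Degenerate inputs have defined
behavior throughout: empty FASTA parses to an empty dataset, single-class
training labels raise, λ ≥ L raises naming the record, empty test sets and
train/test id overlap raise before any number is produced.

## Known limitations

* Identity clustering is exact O(n²·L²); fine to a few thousand peptides,
  not engineered for million-scale databases.
* The shipped property values are standard published scales; a study that
  used different (unpublished) scale variants will produce different
  IPseAAC coordinates, though all structural properties are scale-agnostic.
* The SVM grid search dominates runtime for large K; shrink the grid via
  `SVMConfig` for quick exploration.
* Probability calibration, ROC/AUC, oversampling (SMOTE-style) and
  deep-learning encoders are out of scope.
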