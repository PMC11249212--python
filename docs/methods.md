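# Methods

## Scope and model

`bcrlymph` implements a classification pipeline for bulk IGH (B-cell
receptor heavy chain) repertoires of lymphoma-infiltrated tissue and
blood. The question it operationalizes: can healthy-donor repertoires
(HD) and three B-cell malignancies — nodular lymphocyte predominant
B-cell lymphoma (NLPBL), diffuse large B-cell lymphoma (DLBCL) and
chronic lymphocytic leukemia (CLL) — be told apart from the statistical
architecture of their clonotype tables alone, i.e. from the dominant
(malignant) clonotypes plus the non-malignant bystander repertoire
around them?

A *clonotype* is a unique CDR3 nucleotide sequence with its V/D/J gene
calls and read count. Upstream read processing (alignment, germline
assignment) is out of scope; the pipeline starts from AIRR
Rearrangement-style TSV tables.

## Record-level rules

- Non-productive rearrangements and sequences with fewer than 2 reads
  are discarded. The threshold applies at the record level, before
  collapsing by CDR3.
- Records are collapsed by CDR3 nucleotide sequence: counts summed,
  representative V/D/J from the highest-count member (allele suffix
  stripped at `*`; `/OR` orphon names kept verbatim; comma-separated
  ambiguous calls resolve to the first gene), germline identity as the
  read-count-weighted mean.
- Somatic hypermutation (SHM) is called when V-segment germline
  identity is <= 98.0% (boundary inclusive).

## Repertoire metrics

With fraction vector `p` over `S` clonotypes:

- Shannon index `H' = -sum p_i log2 p_i` (bits),
- Pielou's evenness `J = H'/log2(S)`,
- clonality `1 - J`, with the `S = 1` convention `J := 0`, clonality 1
  (a sample holding only the malignant clone is maximally clonal),
- `shm_fraction`: share of *clonotypes* (not reads) called
  hypermutated; `topn_shm_fraction` restricts to the 10 most frequent.

Base-2 logarithms are used throughout so that clonality 0 corresponds
exactly to a uniform repertoire. No read-depth normalization or
rarefaction is applied; `metric_readcount_correlation` lets users check
on their cohort that richness/clonality/Shannon are essentially
uncorrelated with sequencing depth, the condition under which raw
counts are adequate. Cohort-level metric comparisons use two-sided
Mann-Whitney U tests (exact for small tie-free samples, tie-corrected
normal approximation otherwise) at alpha = 0.05 without
multiple-testing correction.

## Featurization

Each repertoire becomes a fixed-length vector from its top-n clonotypes
(`n` in 1..10, 20, 50, 100). Per slot: clonotype fraction, CDR3
amino-acid length, and the ten mean Kidera factors of the CDR3 peptide;
then one-hot V/D/J blocks over vocabularies learned from the training
repertoires' top-n clonotypes only. Repertoires with fewer than `n`
clonotypes are zero-padded; out-of-vocabulary genes encode as all-zero
blocks (this is also the leakage guard: nothing about the test set can
enter the schema). Four repertoire-level features (clonality, Shannon,
richness, shm_fraction) are appended. Width: `n*(12+|V|+|D|+|J|)+4`.

Choices where the design was open:

- CDR3 length is counted in amino acids, consistent with the Kidera
  amino-acid basis.
- Kidera aggregation is the arithmetic mean over residues (the standard
  peptide-descriptor convention). The bundled per-residue table is the
  published 10-factor set; each factor is standardized (~0 mean, ~unit
  sd) across the 20 residues, which a test asserts.
- shm_fraction is part of the repertoire block: it is among the
  model's informative predictors and cheap to compute.
- Standardization (zero mean/unit variance, training-fitted) is a
  boolean hyperparameter applied to numeric columns only; one-hot
  columns stay 0/1. Padding slots are exactly zero in the unscaled
  representation (scaling shifts them like any other value — the
  padding invariant is a statement about the raw encoding).

## Training protocol

- Stratified 80/20 train/test split. Per-class test seats: total
  `ceil(0.2 N)`, floor allocation by class, remaining seats by largest
  fractional remainder (ties to the larger class, then name order).
  For class sizes (291, 90, 182, 348) this yields test counts
  (58, 18, 37, 70) — the reference cohort arithmetic.
- Random oversampling of all non-majority classes up to the majority
  count, applied after the split and re-fitted inside every CV training
  fold (oversampled duplicates must never appear in a validation fold).
- Stratified 3-fold grid search; selection metric is mean weighted F1
  across folds, ties to the earlier grid point. Grids: logistic
  regression (multinomial loss, L2) C in {0.01, 0.1, 1, 10, 100} x
  scaling {on, off}; random forest trees {100, 300, 500} x depth
  {none, 10, 30} x scaling {on, off}. These are conventional small
  grids; the exact search spaces of the original analysis are not
  published in its main text.
- The best configuration per family is refit on the full oversampled
  training set and scored on the untouched test set: per-class
  precision/recall/F1/support, accuracy, support-weighted F1 and the
  confusion matrix. Undefined precision/recall is reported as 0 and
  flagged.

## Interpretation

- PCA on the feature matrix with a deterministic sign convention
  (largest-|loading| positive per component); group mean structure in
  the PC1/PC2 plane is tested by MANOVA (Wilks' lambda with its F
  approximation, via statsmodels). The MANOVA runs on PC scores, not
  raw features, matching the visual space in which cluster overlap is
  judged; singular within-group covariance is reported as a flagged
  degenerate result.
- Predictor ranking for the linear model: `score(feature) = mean over
  classes of |coefficient|`, top-k (default 20, ties by name), plus a
  signed pairwise table `coef_a - coef_b` per unordered class pair.
  For forests, impurity importances are reported instead and labelled
  as such; they have no pairwise decomposition.

## Synthetic cohort generator

The generator emulates the class-specific statistical structure the
classifier exploits, not sequence evolution. Per class preset:

| parameter | HD | NLPBL | DLBCL | CLL |
|---|---|---|---|---|
| richness range S | 2000–5000 | 500–2000 | 50–500 | 10–200 |
| dominance Beta (a, b) | (1, 19) | (3.5, 6.5) | (7.5, 2.5) | (18, 2) |
| mean top-clone fraction | ~0.05 | ~0.35 | ~0.75 | ~0.90 |
| SHM probability | 0.192 | 0.184 | 0.449 | 0.224 |
| CDR3 length mean (sd) aa | 15.5 (3) | 19 (3) | 16 (3.5) | 17 (3) |
| total reads | 100k | 60k | 30k | 50k |

SHM probabilities are anchored to the reported cohort averages of the
study system; dominance and richness encode the qualitative ordering
(CLL and DLBCL near-monoclonal, NLPBL an intermediate malignant clone
over a broad bystander background, HD polyclonal), which reproduces the
clonality ordering CLL > DLBCL > NLPBL > HD. Read depths and CDR3
length parameters are realistic MiSeq-scale choices (NLPBL gets the
longest CDR3s, mirroring the unusually long malignant NLPBL clonotype).
V/D/J usage biases re-weight a handful of genes per class (e.g.
IGHV4-34 and IGHV4/OR15-8 for DLBCL, IGHV3-30/IGHD3-3/IGHJ6 for NLPBL,
IGHV1-69/IGHV3-21 for CLL) over bundled IMGT-style vocabularies.

Mechanics: S is drawn uniformly from the richness range; the top-clone
fraction from the dominance Beta (a point mass at 1 when b = 0); the
remaining mass is split over S-1 bystanders by a symmetric Dirichlet
(concentration 1). Read counts are one multinomial draw of the total
reads over that fraction vector; clonotypes under the pipeline's
two-read floor are dropped and fractions renormalized, so written
cohorts pass the record filter unchanged and round-trip exactly.
Germline identity is a two-component mixture — uniform on [90, 98] with
the class SHM probability, else uniform on [98.5, 100], rounded to two
decimals — leaving (98.0, 98.5) empty so the generative hypermutation
label coincides exactly with the <=98% call and the per-class SHM
probability is recoverable in expectation through the full calling
path. CDR3 peptides are random 20-letter strings (unique within a
repertoire, lengths from a clipped normal in [6, 32] aa);
nucleotide CDR3s are deterministic back-translations. All randomness
flows through numpy seed sequences; per-sample seeds derive from
(cohort seed, sample index), so regeneration is order-independent.

What the generator does **not** emulate: clonal lineages and realistic
SHM mutation placement (identity is sampled, not computed from
alignments), biased codon usage, public/convergent clonotypes shared
across patients, class-specific CDR3 motifs, and sequencing error.
Passing tests therefore demonstrate that the pipeline recovers the
statistical structure it was told to expect — clonal dominance,
richness, SHM rates, usage biases — not that real cohorts are this
separable.

## Problem sizes and numerical choices

Validation experiments use cohort sizes the package itself chooses:
500 repertoires per class for simulator calibration (Monte-Carlo error
of the mean SHM percentage well under one percentage point) and 100 per
class for the end-to-end classification experiments, where the default
presets yield test weighted F1 above 0.95 for the best-validated model
(the forest at n = 3), while a null cohort in which all four classes
share one preset falls to chance (~0.25 for balanced four-class).
Fraction vectors must sum to 1 within 1e-6 on input and 1e-9 after
normalization; clonality is clipped into [0, 1] against floating-point
round-off; a constant feature column under scaling maps to exactly 0
(sd treated as 1).

## Limitations

- Preset dominance/richness distributions are calibration stand-ins,
  not estimates of the real per-class distributions.
- Coefficient-based interpretation is only defined for the linear
  model, and correlated features (clonality, Shannon, top fraction)
  share their weight in regularized fits; rankings are descriptive, not
  causal.
- The record-level read-count filter is applied before collapsing;
  pipelines that filter after collapsing will retain slightly more
  clonotypes.
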