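# bcrlymph

Machine-learning classification of B-cell lymphoma subtypes from IGH
(B-cell receptor heavy chain) repertoire sequencing data — plus a
synthetic cohort simulator so the entire pipeline can be exercised and
validated without any sequencing data.

## The problem

Bulk BCR repertoire sequencing of lymphoma-infiltrated tissue captures
both the malignant clonotype and the non-malignant bystander
lymphocytes around it. Different entities occupy very different points
on that spectrum: chronic lymphocytic leukemia (CLL) and diffuse large
B-cell lymphoma (DLBCL) repertoires are near-monoclonal, nodular
lymphocyte predominant B-cell lymphoma (NLPBL) hides a malignant clone
inside a dominant bystander background, and healthy-donor (HD) blood is
polyclonal. `bcrlymph` turns each repertoire — a table of clonotypes,
i.e. unique CDR3 nucleotide sequences with V/D/J gene calls and read
counts — into features a classifier can use, and runs the full
training/evaluation protocol.

The core quantities, for a repertoire with clonotype fraction vector
*p* over *S* clonotypes:

- Shannon diversity *H′* = −Σ *pᵢ* log₂ *pᵢ* (bits)
- Pielou's evenness *J* = *H′*/log₂ *S*
- clonality = 1 − *J* (1 = single clonotype, 0 = perfectly even;
  *J* := 0 when *S* = 1)
- somatic hypermutation (SHM): a clonotype is hypermutated when its
  V-segment germline identity is ≤ 98%; `shm_fraction` is the share of
  hypermutated clonotypes

Each repertoire's feature vector concatenates, for its *n* most
dominant clonotypes (*n* ∈ 1..10, 20, 50, 100): clonotype fraction,
CDR3 amino-acid length, the ten mean Kidera factors of the CDR3
peptide, and one-hot V/D/J gene encodings — zero-padded past *S* —
followed by the repertoire block (clonality, *H′*, *S*, shm_fraction).
Training uses a stratified 80/20 split, random oversampling of
non-majority classes, stratified 3-fold grid-search cross-validation
(weighted F1) over multinomial logistic regression and random forest,
and evaluation of the best-validated model on the held-out test set.
Interpretation covers PCA with Wilks'-lambda MANOVA on the PC1/PC2
plane and coefficient-magnitude predictor ranking with pairwise class
contributions.

## Worked example

```python
import bcrlymph as bl
from bcrlymph.classification import CVConfig, Scenario, run_scenario

# 25 synthetic repertoires per class under the default presets
config = bl.CohortConfig(counts={"HD": 25, "NLPBL": 25, "DLBCL": 25, "CLL": 25}, seed=1)
reps, manifest = bl.generate_cohort(config)

table = bl.metrics_table(reps)
print(table.groupby("label")[["clonality", "richness", "shm_fraction"]].mean().round(3))
```

```
       clonality  richness  shm_fraction
label
CLL        0.834     81.04         0.230
DLBCL      0.673    239.96         0.441
HD         0.068   3510.60         0.193
NLPBL      0.303   1170.72         0.185
```

The simulated cohort shows the expected structure: clonality ordering
CLL > DLBCL > NLPBL > HD, thousands of clonotypes in polyclonal HD
blood versus tens in CLL, and DLBCL's elevated hypermutation rate
(~44% of clonotypes versus ~19–23% elsewhere).

```python
scenario = Scenario("HD-NLPBL-DLBCL-CLL", ("HD", "NLPBL", "DLBCL", "CLL"), n_values=(1, 3))
results, reports, models = run_scenario(reps, scenario, CVConfig(seed=1), families=("logistic",))
print(results[["model", "n_clonotypes", "mean_cv_f1", "test_weighted_f1"]].round(3).to_string(index=False))

schema, pipe = models[("logistic", 3)]
print(bl.rank_predictors(pipe, schema.feature_names, k=5).ranking.round(3).to_string(index=False))
```

```
   model  n_clonotypes  mean_cv_f1  test_weighted_f1
logistic             1       0.901             0.949
logistic             3       0.901             0.949
   feature  score
   shannon  0.099
  richness  0.057
c2_j_IGHJ3  0.051
c3_j_IGHJ4  0.043
    c3_kf8  0.043
```

`mean_cv_f1` is the weighted F1 averaged over the three validation
folds for the best grid point; `test_weighted_f1` scores the refit
model on the 20% held-out samples. The predictor ranking lists features
by mean absolute coefficient across classes — here the global
repertoire metrics (Shannon diversity, richness) dominate, with
gene-usage and Kidera-factor features of individual clonotype slots
behind them.

The same pipeline is available from the shell:

```sh
bcrlymph demo --out demo_run --seed 0        # simulate → metrics → train → interpret
bcrlymph simulate --out cohort --seed 0 --samples-per-class 50
bcrlymph metrics --manifest cohort/manifest.tsv --out metrics.tsv
bcrlymph train --manifest cohort/manifest.tsv --scenario HD-NLPBL-DLBCL-CLL \
    --n 1 --n 3 --n 10 --model both --seed 0 --out train_out
bcrlymph interpret --model train_out/best_model.joblib \
    --manifest cohort/manifest.tsv --out interpret_out
```

Real data plug in the same way: one AIRR Rearrangement TSV per sample
(`sequence_id, productive, v_call, d_call, j_call, junction,
junction_aa, duplicate_count, v_identity`) plus a manifest TSV mapping
`sample_id, label, path`.

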