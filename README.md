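# tp53phenocopy

A tested, reusable pipeline for **TP53-loss phenocopy analysis**: label
biallelic *TP53* loss-of-function genotypes from mutation and copy-number
tables, harmonize gene expression across heterogeneous cohorts, train and
lock a pathway-restricted gradient-boosted classifier that recognizes the
transcriptional state of p53 loss, and run the downstream
chemotherapy-response association analyses.

## The problem

*TP53* is the most commonly altered gene in cancer, but DNA mutation status
alone is a poor predictor of p53 *function*: many mono-allelic alterations
retain or alter function in unpredictable ways, while epigenetic or
regulatory changes (e.g. *MDM2* amplification) can silence p53 without any
*TP53* mutation.  A **phenocopy** is a tumor whose transcriptional profile
matches that of a genotype-defined alteration class without necessarily
carrying the DNA alteration.  The strategy implemented here:

1. **Genotype labeling.**  A sample is labeled biallelic "TP53 loss" when it
   carries two *TP53* coding mutations, or one coding mutation plus
   copy-number loss (under dataset-specific thresholds: GISTIC ≤ −1,
   GISTIC < −1, or log2 ratio < −1); *MDM2* alterations optionally count,
   since MDM2 degrades wild-type p53.
2. **Expression harmonization.**  Each sample's expression values are
   replaced by *dense ranks* (ties share a rank; invariant under any
   monotone per-sample transform, which makes microarray and RNA-seq
   comparable), missing genes are imputed by the cohort mean, and cohorts
   are aligned by *reference-batch* empirical-Bayes (ComBat-style) batch
   correction, which leaves the designated reference cohort numerically
   unchanged so a model locked on reference-scaled data stays valid.
3. **Phenocopy signature.**  A gradient-boosted tree classifier (XGBoost)
   is trained on the genotype labels using only genes from a p53-relevant
   pathway gene set, then locked — serialized with its ordered feature
   list, hyperparameters and binarization cutoff — and applied without
   modification to validation cohorts.  Samples scoring ≥ the cutoff are
   *phenocopy* calls.
4. **Association statistics.**  Per-drug linear models
   `sensitivity ~ phenocopy + genotype` (all metrics oriented so lower =
   more sensitive, hence a negative phenocopy coefficient means greater
   chemosensitivity), Fisher's exact tests of pathologic complete response
   (pCR), Cochran–Armitage trend tests over residual-cancer-burden (RCB)
   classes and serial treatment timepoints, covariate-adjusted logistic pCR
   models, and stratified phenocopy-rate summaries with exact binomial
   intervals.

Because the original compendia (pan-cancer tumor atlases, cell-line
pharmacogenomic screens, neoadjuvant breast-cancer trial cohorts) cannot be
redistributed, the package includes a first-class **synthetic-data module**
that plants the full causal structure — genotype ⇒ expression phenotype,
phenocopies at rate π among non-genotype samples, phenotype ⇒ drug
sensitivity / pCR odds / RCB burden / timepoint depletion — so every stage
is testable against known ground truth.

## Worked example

```bash
python analysis/01_simulate.py
python analysis/02_train_signature.py
python analysis/03_score_cohorts.py
python analysis/04_validate_associations.py
```

Stage 1 simulates six cohorts of 1000 samples (genotype prevalence 0.29,
phenocopy rate 0.55 among non-genotype samples) and verifies the genotype
labeling recovers the planted truth exactly.  Stage 2 trains on cohorts
C1–C2, stage 3 applies the locked model, stage 4 runs the associations on
cohorts C4–C6 (n = 3000).  Output from a run with the default seed:

```
scored 6000 samples; scores written to scratch/workspace/scores.tsv
  held-out cohort C3 (n=1000):
    AUC vs planted phenotype:        0.994
    call rate, genotype-loss group:  0.767
    call rate, no-genotype group:    0.411
clinical cohorts C4, C5, C6: n = 3000
  pCR all          phenocopy 34.5% vs 26.0%  (Fisher p = 4.69e-07)
  RCB classes 0-III trend: z = -13.26, p = 3.81e-40
  phenocopy proportion pre -> on -> post: 54% -> 44% -> 34% (trend p = 4.91e-17)
  adjusted pCR model: phenocopy log-OR = 0.400 (p = 5.79e-07), adjusted for grade/T/N stage
  per-drug phenocopy coefficients (negative = more sensitive):
    drug:cisplatin         coef = -0.775  p = 2.2e-22
```

Reading: the locked signature recovers the hidden phenotype state almost
perfectly (AUC 0.994); called phenocopies have a higher pCR rate (34.5% vs
26.0%), a lower residual-disease burden (negative trend z), are depleted
over the course of chemotherapy (54% → 34%), and are more drug-sensitive
(negative linear coefficients) — the planted causal structure, recovered
end to end.  Per-analysis TSVs land in `results/`.

The same stages are available as a CLI over a YAML config:

```bash
tp53phenocopy simulate --config config.yaml
tp53phenocopy train    --config config.yaml
tp53phenocopy score    --config config.yaml
tp53phenocopy validate --config config.yaml
```

## Layout

    src/tp53phenocopy/     library: synthetic data, genotype labels,
                           harmonization, signature, statistics, pipeline, CLI
    analysis/              numbered narrative drivers over the library
    scripts/acceptance.py  from-scratch recomputation of headline quantities
    tests/                 pytest suite (unit, property, acceptance)
    docs/methods.md        models, assumptions, parameter choices, limitations
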