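# Methods

This note documents the models and procedures the package implements, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions.

## Genotype labeling

A sample's *TP53* genotype class is derived from a MAF-like mutation table
and a gene-level copy-number table:

- **coding mutations** — `Variant_Classification` strings are mapped through
  a declared vocabulary (MAF-standard by default); coding categories are
  missense, nonsense, frameshift, splice, in-frame indel and other coding;
  `Silent` and other non-coding classes never count.  Identical
  (sample, gene, classification, protein-change) records are deduplicated,
  so the same variant reported twice counts once.
- **copy-number loss** — under a named threshold scheme, because public
  compendia discretize differently: `gistic_le_minus1` (loss at GISTIC
  ≤ −1), `gistic_lt_minus1` (only deep deletions, < −1), `log2_lt_minus1`
  (log2 ratio < −1).
- **classes** — `dual_loss` iff ≥ 2 coding mutations, or ≥ 1 coding
  mutation with CN loss; `single_alteration` for exactly one event; `none`
  otherwise.  The training label `tp53_loss` is true for `dual_loss`, and —
  under the default `mdm2_policy="any"` — also for samples with *MDM2*
  amplification (GISTIC ≥ +2 / log2 > 1) or an *MDM2* coding mutation,
  since MDM2 overactivity degrades wild-type p53.  Policies
  `amplification_only` and `ignore` are available because the precise MDM2
  rule is a judgment call; the choice is recorded in the model metadata.

The sample universe is the union of both tables; a sample absent from one
table is treated as unaltered there, which matches the uneven coverage of
public mutation/CN calls.

## Expression harmonization

Order: **dense ranks → cohort-mean imputation → reference-batch
correction**, enforced by a state flag (`raw → ranked → corrected`).

*Dense ranks.*  Within each sample, values are replaced by dense ranks
(smallest → 1, ties share a rank, next distinct value increments by one).
This discards platform-specific scale entirely — any strictly increasing
per-sample transform leaves the ranks unchanged — at the cost of
compressing distributional shape.  Ranks are used raw; an optional [0, 1]
rescaling is not enabled by default because the batch-correction step
already standardizes per gene.

*Imputation.*  A missing (gene, sample) cell is replaced by the mean of
that gene over the other samples of the same cohort.  Imputation runs on
the ranked scale, before batch correction: ranks are the working scale of
the whole pipeline, and correction requires complete data.  A gene with no
observed value in a cohort is a hard error — silently filling it would
corrupt locked-model inputs.

*Reference-batch correction.*  The parametric empirical-Bayes location/scale
model (the standard ComBat formulation, reference-batch variant).  Per
gene, data are standardized with the reference batch's mean and 1/n
residual variance; each non-reference batch's per-gene location γ and scale
δ² on that standardized scale are shrunk toward across-gene priors (normal
for γ, inverse-gamma for δ², hyperparameters by method of moments, joint
posterior by the usual fixed-point iteration, convergence 1e-4); adjusted
values are destandardized.  The reference batch is returned numerically
unchanged — the property that keeps a locked classifier valid when new
cohorts are corrected against the same reference.  An optional
reference-sample mask restricts the standardization to a subset of the
reference batch (e.g. only one disease type of a pan-cancer reference).
The implementation is validated to machine precision against the reference
R implementation (`sva::ComBat` with `ref.batch`) on a frozen synthetic
fixture.

Nonparametric priors and covariate-preserving designs are out of scope.

## Phenocopy signature

Features are the expression rows of a declared pathway gene set (GMT), in
gene-set order, from harmonized data.  The classifier is an XGBoost
binary-logistic booster.  Defaults: `max_depth 3`, `eta 0.1`,
`subsample 0.8`, `colsample_bytree 0.8`, `min_child_weight 5`, up to 300
rounds with early stopping (25 rounds) on an internal stratified 20%
validation split; positives weighted by `scale_pos_weight = n_neg/n_pos`.
These are deliberately conservative settings — shallow trees and early
stopping — because the scientific claims are about the pipeline, not a
specific tuning.  Training is single-threaded and fully seeded, so the
same data + seed reproduce a byte-identical serialized model.  Reported
alongside the locked model: stratified k-fold cross-validated AUC against
the genotype labels.

*Locking.*  The model file (JSON) embeds the ordered feature genes, the
booster dump, hyperparameters, the binarization threshold and the per-gene
training mean ranks.  Scoring never refits; a cohort missing a feature
gene is an error unless the explicit fill-with-training-mean override is
given.  The default cutoff is a fixed posterior probability of 0.5 (the
minimal-assumption choice); a training-prevalence-quantile rule is
available.

*Calibration under label contamination.*  The genotype label is a noisy
proxy for the phenotype of interest: at a phenocopy rate π among
genotype-negative samples, a perfectly informative profile has
`P(label = 1 | phenotype-positive profile) = q/(q + (1-q)π)` (q = genotype
prevalence), ≈ 0.43 at the reference q = 0.29, π = 0.55, pushed to ≈ 0.64
by the prevalence weighting.  Two consequences, both verified empirically:
(1) AUC measured against *genotype* labels is capped near
0.5 + (1 − π)/2 ≈ 0.72 even for a perfect phenotype detector, so
classifier accuracy is assessed against the generator's planted phenotype
truth (held-out AUC ≈ 0.99 at reference settings); (2) at the fixed 0.5
cutoff, finite-sample score spread around 0.64 leaves a minority of true
phenocopies below threshold (~70–77% detected); adding boosting capacity
lowers detection further because the contaminated labels get memorized.
Under lightly contaminated training labels (π = 0.1) detection at the same
cutoff exceeds 80%.  Binary call rates should therefore be read as
conservative; the continuous score carries the ranking information.

## Association statistics

- **Per-drug linear models** — OLS of sensitivity on intercept + phenocopy
  (score or call) + DNA genotype; t-tests on n − p degrees of freedom.
  All supported metrics (Z-scored IC50, negated activity area, negated
  AUC) are oriented so lower = more sensitive; a negative phenocopy
  coefficient means increased sensitivity.  No multiple-testing correction
  is applied across drugs, matching per-drug reporting practice; a
  Benjamini–Hochberg column is emitted alongside the raw p for the reader.
- **Fisher's exact test** (2×2) — two-sided p as the sum of hypergeometric
  probabilities ≤ the observed table's, with relative tolerance 1e-7 for
  ties (the dominant implementation convention); sample odds ratio ad/bc
  with ∞ when only the denominator has a zero; a zero margin returns
  p = 1.0 with a degenerate flag rather than raising.
- **Cochran–Armitage trend** (2×k ordered) — statistic T = Σ sᵢ r₁ᵢ with
  null moments given the margins; the variance uses Armitage's form
  R₁R₂/n³·(n Σ sᵢ²nᵢ − (Σ sᵢnᵢ)²), under which z² reduces *exactly* to the
  Pearson chi-square at k = 2; z is referred to the standard normal,
  two-sided, default scores 0..k−1 (affine-invariant).  On the integer
  lattice of achievable tables the continuous normal p approximates the
  conditional-permutation *mid-p*; tests compare against a permutation
  oracle with an explicit half-atom allowance.  Rows are treated as
  independent observations; repeated samples from the same patient are not
  modeled.
- **Adjusted pCR model** — maximum-likelihood logistic regression of pCR on
  phenocopy + grade + T stage + N stage (ordinal integer coding by
  default, indicator coding switchable); Wald z-tests.  Complete or
  quasi-complete separation raises a diagnostic error instead of returning
  diverged coefficients.
- **Rate summaries** — per-stratum phenocopy counts and proportions with
  exact (Clopper–Pearson) 95% intervals; empty strata are reported with
  n = 0.

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed:

| parameter | default | meaning |
|---|---|---|
| `genotype_loss_rate` | 0.29 | biallelic-loss genotype prevalence |
| `phenocopy_without_genotype_rate` (π) | 0.55 | phenotype rate among non-genotype samples |
| `pathway_effect_size` (δ) | 0.8 | per-pathway-gene mean shift (expression units; gene SDs ~ U(0.8, 1.2)) |
| `batch_location_sd` / `batch_scale_sd` | 0.5 / 0.15 | per-gene per-cohort shift SD / log-scale SD |
| `drug_effect` (β) | −0.5 | sensitivity shift for phenotype-positive lines (noise SD 1) |
| `pcr_logit_intercept` / `_phenocopy_beta` | −1.32 / 0.62 | pCR ≈ 21% (non-phenotype) vs ≈ 33% (phenotype) |
| `rcb_effect` | 0.9 | downward latent residual-burden shift for phenotypes |
| `timepoint_depletion_on` / `_post` | 0.4 / 0.7 | phenotype depletion at on-/post-treatment timepoints |

The prevalence, π, and the pCR logit mirror the magnitudes of the modeled
tumor compendia; δ and β have no published expression-scale analogues and
were chosen once for adequate test power at the simulated sample sizes.

Generation order: per-gene Gaussian background (gene-specific mean and
spread) → additive ±δ shift of the pathway genes in phenotype-positive
samples (fixed per-gene direction, half up / half down) → per-cohort
location/scale batch effects → optional missingness mask.  Mutation and CN
records are emitted *consistently with the labeling rules* (two coding
mutations, one mutation + CN loss under the configured scheme, or MDM2
amplification), so calling genotypes on the synthetic tables recovers the
planted genotype exactly.  RCB classes discretize a latent residual-burden
variable whose mean decreases with phenotype; timepoints are assigned with
phenotype-dependent weights so the phenocopy proportion declines
pre → on → post.  pCR is drawn from the stated logit independently of the
RCB latent, so RCB-0 and pCR do not exactly coincide — each response
annotation has its own planted mechanism.

What the generator does **not** emulate: realistic RNA-seq count
distributions (backgrounds are Gaussian), segment-level copy number, tumor
purity and subclonality, gene–gene correlation beyond the planted pathway
shift, cohort-specific gene panels, or patient-level repeated-measures
structure.  Passing tests therefore demonstrate that the pipeline recovers
a planted phenocopy structure under batch effects and label contamination —
not that the signature generalizes to real tumors.

## Problem sizes

Simulated studies use cohorts of 150–1000 samples with 200–1000 genes
(25–50 pathway genes); the end-to-end recovery check runs 20 replicates at
2000 training / 1000 held-out samples, and the clinical association
analyses run at n = 3000 — the scale of the pooled neoadjuvant compendium
being emulated.  The acceptance script uses one six-cohort compendium
(n = 6000) per run.

## Numerical conventions and edge cases

- Fisher p sums that include every table (i.e. total probability 1 up to
  float error) are snapped to exactly 1.0.
- Trend p-values are floored at the smallest positive normal float so the
  "p ∈ (0, 1]" contract holds even for overwhelming trends.
- Zero-variance features are retained in training (trees ignore them) but
  listed in the model metadata.
- Batch correction requires ≥ 2 batches with ≥ 2 samples each and complete
  data; a zero-variance gene in the reference batch is an error.
- All pipeline randomness derives from one master seed expanded per stage
  via a CRC-based named sub-seed (always < 2³¹).
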