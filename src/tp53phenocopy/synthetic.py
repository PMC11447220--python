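"""Synthetic multi-cohort datasets with a planted TP53-loss phenocopy structure.

The generator emulates the joint shape of the study's real inputs — a
multi-batch expression compendium, MAF-like mutation calls, gene-level
copy-number calls, cell-line drug response, and neoadjuvant clinical
annotation (pCR, ER status, RCB class, serial timepoints) — with a known
causal chain:

    genotype (biallelic TP53 loss)  ==>  expression phenotype
    non-genotype samples carry the phenotype at rate pi (the *phenocopies*)
    phenotype  ==>  shifted pathway-gene expression (effect delta, before
                    batch effects)
    phenotype  ==>  greater drug sensitivity (shift beta, lower = sensitive)
    phenotype  ==>  higher pCR log-odds (stated logit model)
    phenotype  ==>  lower latent residual-cancer burden (ordinal RCB class)
    phenotype  ==>  depletion at later treatment timepoints

Hidden truth labels are written to a separate TSV never read by the
analysis stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .genomic import SCHEMES, AlterationTables, ThresholdScheme
from .matrix import NA_TOKEN, ExpressionMatrix
from .signature import GeneSet, read_gmt, write_gmt

DEFAULT_DRUGS = ("cisplatin", "paclitaxel", "doxorubicin", "gemcitabine", "5-fluorouracil")

FIXTURE_FILES = {
    "expression": "expression.tsv",
    "mutations": "mutations.tsv",
    "copy_number": "copy_number.tsv",
    "clinical": "clinical.tsv",
    "drug_response": "drug_response.tsv",
    "geneset": "pathway.gmt",
    "truth": "truth.tsv",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic compendium.

    Defaults mirror the magnitudes of the modeled cohorts: a ~29% biallelic
    TP53-loss genotype prevalence, a 55% phenocopy rate among non-genotype
    samples, and a pCR logit placing non-phenocopy samples at ~21% and
    phenocopy samples at ~33% pCR.
    """

    n_samples_per_cohort: int = 500
    n_cohorts: int = 3
    n_genes_total: int = 1000
    n_pathway_genes: int = 50
    genotype_loss_rate: float = 0.29
    phenocopy_without_genotype_rate: float = 0.55  # pi
    pathway_effect_size: float = 0.8  # delta, mean shift per pathway gene
    batch_location_sd: float = 0.5
    batch_scale_sd: float = 0.15
    drug_effect: float = -0.5  # beta, sensitivity shift (lower = more sensitive)
    drug_noise_sd: float = 1.0
    pcr_logit_intercept: float = -1.32  # logit(0.21)
    pcr_logit_phenocopy_beta: float = 0.62  # logit(0.33) - logit(0.21)
    seed: int = 0
    # secondary knobs
    missing_rate: float = 0.0
    rcb_effect: float = 0.9  # downward shift of latent residual burden for phenotypes
    timepoint_depletion_on: float = 0.4
    timepoint_depletion_post: float = 0.7
    er_positive_rate: float = 0.55
    scheme_name: str = "tcga"
    drugs: tuple = DEFAULT_DRUGS

    def __post_init__(self) -> None:
        for name in ("n_samples_per_cohort", "n_cohorts", "n_genes_total", "n_pathway_genes"):
            if getattr(self, name) < 0 or (name != "n_samples_per_cohort"
                                           and getattr(self, name) < 1):
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("genotype_loss_rate", "phenocopy_without_genotype_rate",
                     "missing_rate", "timepoint_depletion_on", "timepoint_depletion_post",
                     "er_positive_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be a probability in [0, 1], got {v}")
        if self.n_pathway_genes > self.n_genes_total:
            raise ConfigurationError("n_pathway_genes cannot exceed n_genes_total")
        for name in ("batch_location_sd", "batch_scale_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.drug_noise_sd <= 0:
            raise ConfigurationError("drug_noise_sd must be positive")
        if self.scheme_name not in SCHEMES:
            raise ConfigurationError(f"unknown scheme_name {self.scheme_name!r}")

    @property
    def scheme(self) -> ThresholdScheme:
        return SCHEMES[self.scheme_name]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drugs"] = list(d["drugs"])
        return d


@dataclass
class SyntheticCohort:
    """One simulated compendium: observables plus hidden truth."""

    expression: ExpressionMatrix
    alterations: AlterationTables
    clinical: pd.DataFrame
    drug_response: pd.DataFrame
    truth: pd.DataFrame  # sample, genotype_loss, phenotype
    geneset: GeneSet
    config: SimulationConfig
    #: per-pathway-gene planted shift direction (+1/-1), generator metadata
    pathway_directions: np.ndarray | None = None

    @property
    def pathway_genes(self) -> list[str]:
        return list(self.geneset.genes)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohorts(config: SimulationConfig) -> SyntheticCohort:
    """Draw one synthetic compendium under the planted causal structure.

    Background expression is i.i.d. Gaussian per gene (gene-specific mean
    and spread); phenotype-positive samples have each pathway gene shifted
    by +/- delta (a fixed per-gene direction, half up / half down) *before*
    per-cohort batch effects (gene-wise location shifts and scale
    perturbations) are applied.  Identical config + seed gives byte-identical
    outputs.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_samples_per_cohort * config.n_cohorts
    samples = [f"S{i:05d}" for i in range(n_total)]
    cohorts = [f"C{j + 1}" for j in range(config.n_cohorts)]
    sample_cohort = np.repeat(cohorts, config.n_samples_per_cohort)

    n_pw = config.n_pathway_genes
    genes = [f"PWG{i:04d}" for i in range(n_pw)] + \
            [f"BGG{i:04d}" for i in range(config.n_genes_total - n_pw)]

    # hidden states
    genotype = rng.random(n_total) < config.genotype_loss_rate
    phenotype = genotype | (rng.random(n_total) < config.phenocopy_without_genotype_rate)

    # expression: baseline + planted pathway shift, then batch effects
    gene_mean = rng.normal(8.0, 2.0, size=config.n_genes_total)
    gene_sd = rng.uniform(0.8, 1.2, size=config.n_genes_total)
    direction = np.where(np.arange(n_pw) % 2 == 0, 1.0, -1.0)
    values = gene_mean[:, None] + gene_sd[:, None] * rng.standard_normal(
        (config.n_genes_total, n_total))
    values[:n_pw, :] += config.pathway_effect_size * direction[:, None] * phenotype[None, :]

    for j, cohort in enumerate(cohorts):
        cols = sample_cohort == cohort
        loc = rng.normal(0.0, config.batch_location_sd, size=config.n_genes_total) \
            if config.batch_location_sd > 0 else np.zeros(config.n_genes_total)
        scale = np.exp(rng.normal(0.0, config.batch_scale_sd, size=config.n_genes_total)) \
            if config.batch_scale_sd > 0 else np.ones(config.n_genes_total)
        centered = values[:, cols] - gene_mean[:, None]
        values[:, cols] = gene_mean[:, None] + loc[:, None] + scale[:, None] * centered

    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)

    expression = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        batches=pd.Series(sample_cohort, index=samples),
        state="raw",
    )

    alterations = _simulate_alterations(rng, samples, genotype, config)
    clinical = _simulate_clinical(rng, samples, sample_cohort, phenotype, config)
    drug_response = _simulate_drug_response(rng, samples, phenotype, config)

    truth = pd.DataFrame({
        "sample": samples,
        "genotype_loss": genotype,
        "phenotype": phenotype,
    })
    geneset = GeneSet(name="synthetic_p53_pathway",
                      description="planted pathway genes of the synthetic generator",
                      genes=tuple(genes[:n_pw])) if n_pw else None
    return SyntheticCohort(expression=expression, alterations=alterations,
                           clinical=clinical, drug_response=drug_response,
                           truth=truth, geneset=geneset, config=config,
                           pathway_directions=direction.copy())


def _simulate_alterations(rng, samples, genotype, config) -> AlterationTables:
    """Emit mutation and copy-number records consistent with the labeling rules,
    so that calling genotypes on the synthetic tables recovers the truth exactly."""
    scheme = config.scheme
    gistic = scheme.value_kind == "gistic_discrete"
    cn_neutral = 0 if gistic else 0.0
    if scheme.cn_loss_rule == "gistic_le_minus1":
        loss_values = (-1, -2)
    elif scheme.cn_loss_rule == "gistic_lt_minus1":
        loss_values = (-2,)
    else:
        loss_values = (-1.5,)
    amp_value = 2 if gistic else 1.8

    coding_pool = ["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
                   "Splice_Site", "In_Frame_Del"]
    mut_rows, tp53_cn, mdm2_cn = [], {}, {}
    for i, s in enumerate(samples):
        tp53_cn[s] = cn_neutral
        mdm2_cn[s] = cn_neutral
        if genotype[i]:
            mech = rng.choice(("two_mutations", "mutation_plus_cn", "mdm2"),
                              p=(0.45, 0.35, 0.2))
            if mech == "two_mutations":
                c1, c2 = rng.choice(coding_pool, size=2, replace=True)
                mut_rows.append((s, "TP53", c1, f"p.A{100 + i}B"))
                mut_rows.append((s, "TP53", c2, f"p.C{200 + i}D"))
            elif mech == "mutation_plus_cn":
                mut_rows.append((s, "TP53", rng.choice(coding_pool), f"p.A{100 + i}B"))
                tp53_cn[s] = loss_values[int(rng.integers(len(loss_values)))]
            else:
                mdm2_cn[s] = amp_value
        else:
            u = rng.random()
            if u < 0.25:  # mono-allelic coding mutation, no CN loss
                mut_rows.append((s, "TP53", rng.choice(coding_pool), f"p.A{100 + i}B"))
            elif u < 0.35:  # silent-only
                mut_rows.append((s, "TP53", "Silent", f"p.E{300 + i}E"))
    mutations = pd.DataFrame(mut_rows,
                             columns=["sample", "gene", "variant_classification",
                                      "protein_change"])
    cn_rows = [(s, "TP53", tp53_cn[s]) for s in samples] + \
              [(s, "MDM2", mdm2_cn[s]) for s in samples]
    copy_number = pd.DataFrame(cn_rows, columns=["sample", "gene", "value"])
    return AlterationTables(mutations=mutations, copy_number=copy_number,
                            value_kind=scheme.value_kind)


def _simulate_clinical(rng, samples, sample_cohort, phenotype, config) -> pd.DataFrame:
    n = len(samples)
    pcr_prob = _sigmoid(config.pcr_logit_intercept
                        + config.pcr_logit_phenocopy_beta * phenotype.astype(float))
    pcr = rng.random(n) < pcr_prob
    er = np.where(rng.random(n) < config.er_positive_rate, "positive", "negative")

    # latent residual burden decreases with phenotype; fixed bin edges
    latent = 1.5 - config.rcb_effect * phenotype.astype(float) + rng.standard_normal(n)
    rcb = np.digitize(latent, bins=[0.4, 1.3, 2.2])  # 0..3

    # timepoints: phenotype-positive samples preferentially pre-treatment
    w_pos = np.array([1.0, 1.0 - config.timepoint_depletion_on,
                      1.0 - config.timepoint_depletion_post])
    w_neg = np.ones(3)
    w_pos /= w_pos.sum()
    w_neg /= w_neg.sum()
    tp_labels = np.array(["pre", "on", "post"])
    idx = np.where(phenotype[:, None],
                   rng.choice(3, size=(n, 1), p=w_pos),
                   rng.choice(3, size=(n, 1), p=w_neg)).ravel()
    timepoint = tp_labels[idx]

    grade = rng.choice([1, 2, 3], size=n, p=[0.2, 0.5, 0.3])
    t_stage = rng.choice([1, 2, 3, 4], size=n, p=[0.3, 0.4, 0.2, 0.1])
    n_stage = rng.choice([0, 1, 2, 3], size=n, p=[0.45, 0.3, 0.15, 0.1])

    return pd.DataFrame({
        "sample": samples,
        "cohort": sample_cohort,
        "er_status": er,
        "pcr": pcr.astype(int),
        "rcb_class": rcb.astype(int),
        "timepoint": timepoint,
        "grade": grade,
        "t_stage": t_stage,
        "n_stage": n_stage,
    })


def _simulate_drug_response(rng, samples, phenotype, config) -> pd.DataFrame:
    rows = []
    for drug in config.drugs:
        vals = (config.drug_effect * phenotype.astype(float)
                + rng.normal(0.0, config.drug_noise_sd, size=len(samples)))
        rows.append(pd.DataFrame({"sample": samples, "drug": drug, "value": vals,
                                  "metric_kind": "z_ic50"}))
    if not rows:
        return pd.DataFrame(columns=["sample", "drug", "value", "metric_kind"])
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write the seven-file fixture set and return a manifest of paths and
    checksums.  Truth labels go to a separate TSV the analysis stages never
    read.  Rerunning with the same cohort produces byte-identical files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in FIXTURE_FILES.items()}

    cohort.expression.to_tsv(paths["expression"])
    mut = cohort.alterations.mutations.rename(columns={
        "sample": "Tumor_Sample_Barcode", "gene": "Hugo_Symbol",
        "variant_classification": "Variant_Classification",
        "protein_change": "Protein_Change"})
    mut.to_csv(paths["mutations"], sep="\t", index=False)
    cn_wide = cohort.alterations.copy_number.pivot(index="gene", columns="sample",
                                                   values="value")
    cn_wide = cn_wide.reindex(columns=list(cohort.expression.samples))
    cn_wide.index.name = "gene"
    cn_wide.to_csv(paths["copy_number"], sep="\t", na_rep=NA_TOKEN)
    cohort.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    cohort.drug_response.to_csv(paths["drug_response"], sep="\t", index=False)
    if cohort.geneset is not None:
        write_gmt([cohort.geneset], paths["geneset"])
    else:
        paths["geneset"].write_text("")
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)

    manifest = {
        "value_kind": cohort.alterations.value_kind,
        "config": cohort.config.to_dict() if cohort.config is not None else None,
        "files": {k: p.name for k, p in paths.items()},
        "sha256": {k: _sha256(p) for k, p in paths.items()},
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_fixture(directory: str | Path) -> SyntheticCohort:
    """Round-trip reader for :func:`write_fixture` output."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    paths = {k: directory / v for k, v in manifest["files"].items()}
    clinical = pd.read_csv(paths["clinical"], sep="\t")
    batches = pd.Series(clinical["cohort"].values, index=clinical["sample"].values) \
        if len(clinical) else pd.Series(dtype=object)
    expression = ExpressionMatrix.from_tsv(paths["expression"], batches=batches)
    alterations = AlterationTables.from_tsv(paths["mutations"], paths["copy_number"],
                                            value_kind=manifest["value_kind"])
    drug_response = pd.read_csv(paths["drug_response"], sep="\t")
    truth = pd.read_csv(paths["truth"], sep="\t")
    genesets = read_gmt(paths["geneset"]) if paths["geneset"].stat().st_size else []
    cfg = manifest.get("config")
    config = SimulationConfig(**{**cfg, "drugs": tuple(cfg["drugs"])}) if cfg else None
    return SyntheticCohort(expression=expression, alterations=alterations,
                           clinical=clinical, drug_response=drug_response, truth=truth,
                           geneset=genesets[0] if genesets else None, config=config)
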