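"""Stage orchestration: simulate, train, score, validate.

Each command is a plain function over the library modules, driven by a
single YAML-serializable :class:`PipelineConfig`.  All randomness flows from
one declared seed expanded per stage by a named sub-seed derivation, so each
stage is independently reproducible; logs record the config hash, input
checksums, seed and stage timings.
"""

from __future__ import annotations

import hashlib
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import genomic, harmonize, signature, stats, synthetic
from .errors import ConfigurationError
from .matrix import ExpressionMatrix

log = logging.getLogger("tp53phenocopy")


def subseed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    return (int(seed) * 100003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """All paths, parameters and analysis specs for a pipeline run."""

    workdir: str = "."
    seed: int = 0
    # inputs (relative to workdir unless absolute)
    expression: str = "expression.tsv"
    mutations: str = "mutations.tsv"
    copy_number: str = "copy_number.tsv"
    clinical: str = "clinical.tsv"
    drug_response: str = "drug_response.tsv"
    geneset: str = "pathway.gmt"
    # genotype labeling
    scheme: str = "tcga"
    mdm2_policy: str = "any"
    # harmonization
    reference_batch: str = "C1"
    reference_samples: list | None = None
    # model
    hyperparameters: dict = field(default_factory=dict)
    threshold_rule: str | float = 0.5
    # outputs
    model_file: str = "model.json"
    scores_file: str = "scores.tsv"
    # simulation parameters (cmd_simulate only)
    simulation: dict = field(default_factory=dict)
    # analysis specs for cmd_validate
    analyses: list = field(default_factory=lambda: [
        {"kind": "fisher_pcr"},
        {"kind": "trend_rcb"},
        {"kind": "trend_timepoint"},
        {"kind": "rates_by_genotype"},
        {"kind": "drug_panel"},
    ])

    def path(self, name: str) -> Path:
        p = Path(getattr(self, name))
        return p if p.is_absolute() else Path(self.workdir) / p

    # -- (de)serialization: load -> dump -> load is a fixed point ---------
    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


class _stage:
    """Context manager logging a stage's wall time."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        log.info("stage %s: done in %.2fs", self.name, time.perf_counter() - self.t0)
        return False


# ---------------------------------------------------------------------------
# commands
# ---------------------------------------------------------------------------

def cmd_simulate(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Generate a synthetic fixture directory; returns the file manifest."""
    out_dir = Path(out_dir) if out_dir is not None else Path(config.workdir)
    sim_kwargs = dict(config.simulation)
    sim_kwargs.setdefault("seed", subseed(config.seed, "simulate"))
    if "drugs" in sim_kwargs:
        sim_kwargs["drugs"] = tuple(sim_kwargs["drugs"])
    sim_config = synthetic.SimulationConfig(**sim_kwargs)
    log.info("simulate: config hash %s, seed %d", config.config_hash(), sim_config.seed)
    with _stage("simulate"):
        cohort = synthetic.simulate_cohorts(sim_config)
        manifest = synthetic.write_fixture(cohort, out_dir)
    return manifest


def _load_inputs(config: PipelineConfig):
    for name in ("expression", "mutations", "copy_number", "clinical"):
        p = config.path(name)
        if not p.exists():
            raise ConfigurationError(f"input file missing: {p}")
        log.info("input %s: %s (sha256 %s)", name, p, _checksum(p))
    clinical = pd.read_csv(config.path("clinical"), sep="\t")
    batches = pd.Series(clinical["cohort"].values, index=clinical["sample"].values)
    expression = ExpressionMatrix.from_tsv(config.path("expression"), batches=batches)
    scheme = genomic.SCHEMES[config.scheme]
    tables = genomic.AlterationTables.from_tsv(
        config.path("mutations"), config.path("copy_number"),
        value_kind=scheme.value_kind)
    return expression, tables, clinical, scheme


def _harmonize(config: PipelineConfig, expression: ExpressionMatrix) -> ExpressionMatrix:
    ranked = harmonize.dense_rank_normalize(expression)
    ranked = harmonize.impute_missing(ranked)
    if len(expression.batch_ids()) < 2:
        log.info("single cohort: skipping batch correction, using ranked data")
        return ranked
    corrected, _ = harmonize.combat_correct(ranked, config.reference_batch,
                                            reference_samples=config.reference_samples)
    return corrected


def cmd_train(config: PipelineConfig) -> signature.PhenocopyModel:
    """Label genotypes, harmonize expression, train and lock the model.

    Writes the model JSON and a training report (cross-validated AUC and
    phenocopy rates by genotype class, both in-sample and thresholded)."""
    expression, tables, clinical, scheme = _load_inputs(config)
    with _stage("label"):
        labels = genomic.call_tp53_loss(tables, scheme, mdm2_policy=config.mdm2_policy)
    with _stage("harmonize"):
        working = _harmonize(config, expression)
    with _stage("train"):
        genesets = signature.read_gmt(config.path("geneset"))
        features, dropped = signature.select_features(working, genesets[0])
        if dropped:
            log.info("gene-set genes absent from the matrix: %s", dropped)
        label_series = labels["tp53_loss"].reindex(features.samples)
        model = signature.train_model(features, label_series,
                                      hyperparameters=config.hyperparameters,
                                      seed=subseed(config.seed, "train"))
        rule = config.threshold_rule
        model = signature.set_threshold(model, rule)
    calls = signature.score_samples(model, features)
    rates = stats.summarize_phenocopy_rates(
        calls.phenocopy, labels["allele_class"].reindex(features.samples))
    model.metadata["training_report"] = {
        "cv_auc": model.cv_auc,
        "phenocopy_rates_by_allele_class": rates.to_dict(orient="records"),
        "config_hash": config.config_hash(),
    }
    model.save(config.path("model_file"))
    log.info("train: cv AUC %.3f, model written to %s", model.cv_auc,
             config.path("model_file"))
    return model


def cmd_score(config: PipelineConfig, model_path: str | Path | None = None
              ) -> signature.PhenocopyCalls:
    """Harmonize a cohort and apply the locked model without modification."""
    expression, _tables, _clinical, _scheme = _load_inputs(config)
    model = signature.PhenocopyModel.load(model_path or config.path("model_file"))
    with _stage("score"):
        working = _harmonize(config, expression)
        calls = signature.score_samples(model, working)
    calls.to_tsv(config.path("scores_file"))
    return calls


def cmd_validate(config: PipelineConfig, calls: signature.PhenocopyCalls | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Run every analysis spec; one results TSV per spec.

    Specs (``config.analyses``): ``fisher_pcr`` (pCR vs phenocopy, 2x2
    Fisher, optionally per ER stratum), ``trend_rcb`` (Cochran-Armitage over
    RCB classes), ``trend_timepoint`` (trend over pre/on/post), ``rates_by_*``
    summaries, ``drug_panel`` (per-drug linear models)."""
    out_dir = Path(out_dir) if out_dir is not None else Path(config.workdir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clinical = pd.read_csv(config.path("clinical"), sep="\t")
    if calls is None:
        model = signature.PhenocopyModel.load(config.path("model_file"))
        calls = signature.PhenocopyCalls.from_tsv(config.path("scores_file"),
                                                  model.threshold)
    produced: dict[str, Path] = {}
    if clinical.empty:
        log.warning("empty clinical table: writing headers-only results")
    clin = clinical.set_index("sample") if "sample" in clinical.columns else clinical

    for spec in config.analyses:
        kind = spec["kind"]
        path = out_dir / f"results_{spec.get('name', kind)}.tsv"
        with _stage(f"validate:{kind}"):
            if kind == "fisher_pcr":
                results = []
                if not clin.empty:
                    table = stats.pcr_contingency(calls.phenocopy.reindex(clin.index),
                                                  clin["pcr"].astype(bool))
                    results.append(stats.fisher_exact_2x2(table))
                    results[-1].model_id = "fisher_pcr:all"
                    for er, group in clin.groupby("er_status"):
                        sub = stats.fisher_exact_2x2(stats.pcr_contingency(
                            calls.phenocopy.reindex(group.index), group["pcr"].astype(bool)))
                        sub.model_id = f"fisher_pcr:er_{er}"
                        results.append(sub)
                stats.results_to_tsv(results, path)
            elif kind == "trend_rcb":
                results = []
                if not clin.empty:
                    table = stats.ordered_contingency(
                        calls.phenocopy.reindex(clin.index), clin["rcb_class"],
                        order=[0, 1, 2, 3])
                    res = stats.cochran_armitage_trend(table)
                    res.model_id = "trend_rcb"
                    results.append(res)
                stats.results_to_tsv(results, path)
            elif kind == "trend_timepoint":
                results = []
                if not clin.empty:
                    table = stats.ordered_contingency(
                        calls.phenocopy.reindex(clin.index), clin["timepoint"],
                        order=["pre", "on", "post"])
                    res = stats.cochran_armitage_trend(table)
                    res.model_id = "trend_timepoint"
                    results.append(res)
                stats.results_to_tsv(results, path)
            elif kind == "rates_by_genotype":
                scheme = genomic.SCHEMES[config.scheme]
                tables = genomic.AlterationTables.from_tsv(
                    config.path("mutations"), config.path("copy_number"),
                    value_kind=scheme.value_kind)
                labels = genomic.call_tp53_loss(tables, scheme,
                                                mdm2_policy=config.mdm2_policy)
                rates = stats.summarize_phenocopy_rates(
                    calls.phenocopy,
                    labels["allele_class"].reindex(calls.phenocopy.index))
                rates.to_csv(path, sep="\t", index=False, na_rep="NA")
            elif kind == "rates_by_timepoint":
                rates = stats.summarize_phenocopy_rates(
                    calls.phenocopy.reindex(clin.index),
                    clin["timepoint"], order=["pre", "on", "post"]) if not clin.empty \
                    else pd.DataFrame(columns=["stratum", "n", "n_phenocopy",
                                               "proportion", "ci_low", "ci_high"])
                rates.to_csv(path, sep="\t", index=False, na_rep="NA")
            elif kind == "adjusted_pcr":
                results = []
                if not clin.empty:
                    res = stats.adjusted_pcr_model(clinical, calls.phenocopy.astype(float))
                    results.append(res)
                stats.results_to_tsv(results, path)
            elif kind == "drug_panel":
                response = pd.read_csv(config.path("drug_response"), sep="\t")
                if response.empty:
                    panel = pd.DataFrame(columns=["model", "covariate", "coef", "se",
                                                  "stat", "p", "n", "p_bh"])
                else:
                    scheme = genomic.SCHEMES[config.scheme]
                    tables = genomic.AlterationTables.from_tsv(
                        config.path("mutations"), config.path("copy_number"),
                        value_kind=scheme.value_kind)
                    labels = genomic.call_tp53_loss(tables, scheme,
                                                    mdm2_policy=config.mdm2_policy)
                    panel = stats.drug_panel(response, calls.scores,
                                             labels["tp53_loss"])
                panel.to_csv(path, sep="\t", index=False, na_rep="NA")
            else:
                raise ConfigurationError(f"unknown analysis kind {kind!r}")
        produced[kind] = path
    return produced


def cmd_all(config: PipelineConfig) -> dict:
    """simulate -> train -> score -> validate in one call."""
    cmd_simulate(config)
    cmd_train(config)
    calls = cmd_score(config)
    return cmd_validate(config, calls=calls)
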