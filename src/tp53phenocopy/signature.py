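"""Pathway-restricted gradient-boosted phenocopy classifier.

The classifier is trained on harmonized expression of a p53-relevant gene
set (e.g. the cell-cycle transcriptional targets of p53), with the
biallelic-loss genotype as the label, then *locked*: the serialized model —
ordered feature genes, booster dump, hyperparameters and binarization
threshold — is applied without modification to every validation cohort.
A sample scoring above the threshold is called a TP53-loss *phenocopy*
whether or not it carries the DNA alteration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import ConfigurationError, ValidationError
from .matrix import ExpressionMatrix

MODEL_FORMAT_VERSION = 1

DEFAULT_HYPERPARAMETERS: dict = {
    "max_depth": 3,
    "eta": 0.1,
    "subsample": 0.8,
    "colsample_bytree": 0.8,
    "num_boost_round": 300,
    "early_stopping_rounds": 25,
    "min_child_weight": 5,
}


@dataclass(frozen=True)
class GeneSet:
    """Named, ordered, duplicate-free list of gene symbols."""

    name: str
    genes: tuple
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} contains duplicates")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file (name <tab> description <tab> gene symbols...)."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(f"malformed GMT line: {line[:80]!r}")
        sets.append(GeneSet(name=fields[0], description=fields[1],
                            genes=tuple(g for g in fields[2:] if g)))
    return sets


def write_gmt(genesets: list[GeneSet], path: str | Path) -> None:
    lines = ["\t".join([gs.name, gs.description or "na", *gs.genes]) for gs in genesets]
    Path(path).write_text("\n".join(lines) + "\n")


def select_features(matrix: ExpressionMatrix, geneset: GeneSet
                    ) -> tuple[ExpressionMatrix, list[str]]:
    """Restrict the matrix to the pathway genes, in gene-set order.

    Returns the restricted matrix and the list of gene-set genes absent from
    the matrix (dropped).  Raises if the intersection is empty.
    """
    if matrix.state not in ("ranked", "corrected"):
        raise ValidationError(
            f"feature selection expects ranked or corrected data, got {matrix.state!r}")
    present = [g for g in geneset.genes if g in matrix.genes]
    dropped = [g for g in geneset.genes if g not in matrix.genes]
    if not present:
        raise ValidationError(
            f"no overlap between gene set {geneset.name!r} and the expression matrix")
    return matrix.with_values(matrix.values.loc[present]), dropped


@dataclass
class PhenocopyModel:
    """Locked phenocopy classifier.

    Scoring is deterministic given the serialized model and an input matrix;
    the binary call is ``score >= threshold``.
    """

    feature_genes: list[str]
    booster: xgb.Booster
    hyperparameters: dict
    threshold: float = 0.5
    metadata: dict = field(default_factory=dict)
    training_means: pd.Series | None = None  # mean training rank per feature
    cv_auc: float | None = None
    training_scores: pd.Series | None = None

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "feature_genes": list(self.feature_genes),
            "hyperparameters": self.hyperparameters,
            "threshold": self.threshold,
            "metadata": self.metadata,
            "cv_auc": self.cv_auc,
            "training_means": (None if self.training_means is None
                               else self.training_means.to_dict()),
            "booster": json.loads(bytes(self.booster.save_raw(raw_format="json"))),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PhenocopyModel":
        payload = json.loads(Path(path).read_text())
        booster = xgb.Booster()
        booster.load_model(bytearray(json.dumps(payload["booster"]), "utf-8"))
        means = payload.get("training_means")
        return cls(
            feature_genes=payload["feature_genes"],
            booster=booster,
            hyperparameters=payload["hyperparameters"],
            threshold=payload["threshold"],
            metadata=payload.get("metadata", {}),
            cv_auc=payload.get("cv_auc"),
            training_means=None if means is None else pd.Series(means),
        )


@dataclass
class PhenocopyCalls:
    """Per-sample continuous score in [0, 1] and thresholded binary call."""

    scores: pd.Series
    threshold: float

    @property
    def phenocopy(self) -> pd.Series:
        return self.scores.ge(self.threshold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"score": self.scores, "phenocopy": self.phenocopy})

    def to_tsv(self, path: str | Path) -> None:
        out = self.to_frame().reset_index()
        out.columns = ["sample", "score", "phenocopy"]
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, threshold: float) -> "PhenocopyCalls":
        tab = pd.read_csv(path, sep="\t")
        return cls(pd.Series(tab["score"].values, index=tab["sample"].values), threshold)


def _xgb_params(hyper: dict, scale_pos_weight: float, seed: int) -> dict:
    params = {k: v for k, v in hyper.items()
              if k not in ("num_boost_round", "early_stopping_rounds")}
    params.update(objective="binary:logistic", eval_metric="auc",
                  tree_method="hist", nthread=1, seed=int(seed) % (2**31),
                  scale_pos_weight=scale_pos_weight)
    return params


def train_model(features: ExpressionMatrix, labels: pd.Series,
                hyperparameters: dict | None = None, seed: int = 0,
                n_cv_folds: int = 5) -> PhenocopyModel:
    """Train and lock the gradient-boosted phenocopy classifier.

    Positives are weighted to the class ratio (``scale_pos_weight``);
    an internal stratified 20% validation split drives early stopping;
    the reported ``cv_auc`` comes from stratified k-fold models trained on
    the remaining folds.  Training is fully reproducible given the seed.

    Parameters
    ----------
    features
        Pathway-restricted matrix (genes x samples) from
        :func:`select_features`.
    labels
        Boolean biallelic-loss genotype per sample; every training sample
        must be labeled and both classes present.
    """
    hyper = dict(DEFAULT_HYPERPARAMETERS)
    if hyperparameters:
        hyper.update(hyperparameters)

    unlabeled = features.samples.difference(labels.index)
    if len(unlabeled):
        raise ValidationError(f"unlabeled training samples: {list(unlabeled[:5])}")
    y = labels.reindex(features.samples).astype(bool)
    if y.nunique() < 2:
        raise ValidationError("training labels contain a single class")

    X = features.values.T  # samples x genes
    zero_var = X.columns[X.var(axis=0) == 0].tolist()
    # zero-variance features are retained (trees ignore them) but recorded
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    spw = n_neg / n_pos

    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=int)
    feature_names = list(X.columns)
    params = _xgb_params(hyper, spw, seed)
    nrounds = int(hyper["num_boost_round"])
    esr = hyper.get("early_stopping_rounds")

    def _fit(train_idx, val_idx=None):
        dtrain = xgb.DMatrix(Xv[train_idx], label=yv[train_idx], feature_names=feature_names)
        evals, kwargs = [], {}
        if val_idx is not None and esr:
            dval = xgb.DMatrix(Xv[val_idx], label=yv[val_idx], feature_names=feature_names)
            evals = [(dval, "val")]
            kwargs = dict(early_stopping_rounds=int(esr), verbose_eval=False)
        return xgb.train(params, dtrain, num_boost_round=nrounds, evals=evals, **kwargs)

    idx = np.arange(len(yv))
    # cross-validated AUC on the training cohort
    cv_aucs = []
    skf = StratifiedKFold(n_splits=n_cv_folds, shuffle=True, random_state=int(seed) % (2**31))
    for tr, te in skf.split(idx, yv):
        tr_fit, tr_val = train_test_split(tr, test_size=0.2, stratify=yv[tr],
                                          random_state=int(seed) % (2**31))
        bst = _fit(tr_fit, tr_val)
        pred = bst.predict(xgb.DMatrix(Xv[te], feature_names=feature_names))
        cv_aucs.append(roc_auc_score(yv[te], pred))

    # final locked model with an internal early-stopping split
    tr_fit, tr_val = train_test_split(idx, test_size=0.2, stratify=yv,
                                      random_state=int(seed) % (2**31))
    booster = _fit(tr_fit, tr_val)
    training_scores = pd.Series(
        booster.predict(xgb.DMatrix(Xv, feature_names=feature_names)), index=features.samples)

    model = PhenocopyModel(
        feature_genes=feature_names,
        booster=booster,
        hyperparameters=hyper,
        metadata={
            "label_definition": "tp53_biallelic_loss",
            "normalization_state": features.state,
            "seed": int(seed),
            "n_train": int(len(yv)),
            "n_positive": n_pos,
            "scale_pos_weight": spw,
            "zero_variance_features": zero_var,
        },
        training_means=X.mean(axis=0),
        cv_auc=float(np.mean(cv_aucs)),
        training_scores=training_scores,
    )
    return model


def score_samples(model: PhenocopyModel, matrix: ExpressionMatrix,
                  fill_missing_with_training_mean: bool = False) -> PhenocopyCalls:
    """Apply the locked model to a cohort; never refits.

    Raises if any feature gene is absent from the matrix, unless the
    explicit ``fill_missing_with_training_mean`` override substitutes the
    stored training mean rank for the missing genes.
    """
    if matrix.state not in ("ranked", "corrected"):
        raise ValidationError(
            f"scoring expects ranked or corrected data, got {matrix.state!r}")
    expected = model.metadata.get("normalization_state")
    if expected is not None and matrix.state != expected:
        raise ValidationError(
            f"model was locked on {expected!r} data but matrix state is {matrix.state!r}")
    missing = [g for g in model.feature_genes if g not in matrix.genes]
    if missing and not fill_missing_with_training_mean:
        raise ValidationError(f"cohort lacks feature genes: {missing}")
    if missing and model.training_means is None:
        raise ValidationError("model carries no training means; cannot fill missing genes")

    X = pd.DataFrame(index=matrix.samples, columns=model.feature_genes, dtype=float)
    present = [g for g in model.feature_genes if g not in missing]
    X[present] = matrix.values.loc[present].T
    for g in missing:
        X[g] = model.training_means[g]
    scores = model.booster.predict(xgb.DMatrix(X.to_numpy(dtype=float),
                                               feature_names=model.feature_genes))
    return PhenocopyCalls(pd.Series(scores.astype(float), index=matrix.samples),
                          model.threshold)


def set_threshold(model: PhenocopyModel, rule: float | str = 0.5,
                  prevalence: float | None = None) -> PhenocopyModel:
    """Record the binarization cutoff in the locked model.

    ``rule`` is either a fixed probability in (0, 1), or the string
    ``"training_prevalence_quantile"``: the cutoff is placed at the
    (1 - prevalence) quantile of the training scores so that, up to ties,
    a ``prevalence`` fraction of training samples is called positive.
    """
    if rule == "training_prevalence_quantile":
        if model.training_scores is None:
            raise ConfigurationError("quantile rule requires training scores on the model")
        if prevalence is None:
            prevalence = model.metadata.get("n_positive", 0) / model.metadata.get("n_train", 1)
        if not 0 < prevalence < 1:
            raise ConfigurationError(f"prevalence {prevalence} outside (0, 1)")
        threshold = float(model.training_scores.quantile(1 - prevalence))
    else:
        threshold = float(rule)
    if not 0 < threshold < 1:
        raise ConfigurationError(f"threshold {threshold} outside the open interval (0, 1)")
    model.threshold = threshold
    return model
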