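"""Stage 3 — apply the locked signature to the held-out and clinical cohorts.

The model is applied without modification.  Held-out cohort C3 measures how
well the signature recovers the planted phenotype; cohorts C4-C6 are scored
for the downstream clinical association analyses.
"""

import importlib.util
import logging
from pathlib import Path

import pandas as pd
from sklearn.metrics import roc_auc_score

import tp53phenocopy as tp

spec = importlib.util.spec_from_file_location("cfg", Path(__file__).parent / "00_config.py")
cfg = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg)

logging.basicConfig(level=logging.INFO, format="%(message)s")


def main() -> None:
    config = cfg.pipeline_config()
    ws = cfg.WORKSPACE
    clinical = pd.read_csv(ws / "clinical.tsv", sep="\t")
    batches = pd.Series(clinical["cohort"].values, index=clinical["sample"].values)
    expression = tp.ExpressionMatrix.from_tsv(ws / "expression.tsv", batches=batches)
    corrected, _ = tp.combat_correct(
        tp.impute_missing(tp.dense_rank_normalize(expression)), config.reference_batch)
    model = tp.PhenocopyModel.load(ws / "model.json")
    geneset = tp.read_gmt(ws / "pathway.gmt")[0]
    features, _ = tp.select_features(corrected, geneset)

    calls = tp.score_samples(model, features)
    calls.to_tsv(ws / "scores.tsv")

    truth = pd.read_csv(ws / "truth.tsv", sep="\t").set_index("sample")
    held = clinical.loc[clinical["cohort"] == cfg.HELDOUT_COHORT, "sample"]
    auc = roc_auc_score(truth["phenotype"].reindex(held),
                        calls.scores.reindex(held))
    loss = truth["genotype_loss"].reindex(held).astype(bool)
    ph = calls.phenocopy.reindex(held)
    print(f"scored {calls.scores.size} samples; scores written to {ws / 'scores.tsv'}")
    print(f"  held-out cohort {cfg.HELDOUT_COHORT} (n={len(held)}):")
    print(f"    AUC vs planted phenotype:        {auc:.3f}")
    print(f"    call rate, genotype-loss group:  {ph[loss].mean():.3f}")
    print(f"    call rate, no-genotype group:    {ph[~loss].mean():.3f}")


if __name__ == "__main__":
    main()
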