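"""Stage 4 — association analyses on the scored clinical cohorts (C4-C6).

Mirrors the validation battery: Fisher's exact test of pCR vs phenocopy
(overall and by ER status), the Cochran-Armitage trend over
residual-cancer-burden classes and over treatment timepoints, the
covariate-adjusted logistic pCR model, and per-drug linear sensitivity
models.  One TSV per analysis lands in results/.
"""

import importlib.util
import logging
from pathlib import Path

import pandas as pd

import tp53phenocopy as tp

spec = importlib.util.spec_from_file_location("cfg", Path(__file__).parent / "00_config.py")
cfg = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg)

logging.basicConfig(level=logging.INFO, format="%(message)s")


def main() -> None:
    ws = cfg.WORKSPACE
    clinical = pd.read_csv(ws / "clinical.tsv", sep="\t")
    clin = clinical[clinical["cohort"].isin(cfg.CLINICAL_COHORTS)].set_index("sample")
    model = tp.PhenocopyModel.load(ws / "model.json")
    calls = tp.PhenocopyCalls.from_tsv(ws / "scores.tsv", model.threshold)
    called = calls.phenocopy.reindex(clin.index)
    scores = calls.scores.reindex(clin.index)

    print(f"clinical cohorts {', '.join(cfg.CLINICAL_COHORTS)}: n = {len(clin)}")

    # pCR: overall and by ER status
    rows = []
    pcr = clin["pcr"].astype(bool)
    overall = tp.fisher_exact_2x2(tp.pcr_contingency(called, pcr))
    rows.append(("all", pcr[called].mean(), pcr[~called].mean(), overall.pvalue()))
    for er, group in clin.groupby("er_status"):
        sub_calls = called.reindex(group.index)
        sub_pcr = group["pcr"].astype(bool)
        res = tp.fisher_exact_2x2(tp.pcr_contingency(sub_calls, sub_pcr))
        rows.append((f"er_{er}", sub_pcr[sub_calls].mean(), sub_pcr[~sub_calls].mean(),
                     res.pvalue()))
    pcr_tab = pd.DataFrame(rows, columns=["stratum", "pcr_rate_phenocopy",
                                          "pcr_rate_not_phenocopy", "fisher_p"])
    pcr_tab.to_csv(cfg.RESULTS / "pcr_association.tsv", sep="\t", index=False)
    for _, r in pcr_tab.iterrows():
        print(f"  pCR {r['stratum']:<12} phenocopy {100 * r['pcr_rate_phenocopy']:.1f}% "
              f"vs {100 * r['pcr_rate_not_phenocopy']:.1f}%  (Fisher p = {r['fisher_p']:.3g})")

    # RCB trend
    rcb = tp.cochran_armitage_trend(
        tp.ordered_contingency(called, clin["rcb_class"], order=[0, 1, 2, 3]))
    print(f"  RCB classes 0-III trend: z = {rcb.extra['z']:.2f}, p = {rcb.pvalue():.3g}")

    # timepoint depletion
    rates = tp.summarize_phenocopy_rates(called, clin["timepoint"],
                                         order=["pre", "on", "post"])
    rates.to_csv(cfg.RESULTS / "timepoint_phenocopy_rates.tsv", sep="\t", index=False)
    trend = tp.cochran_armitage_trend(
        tp.ordered_contingency(called, clin["timepoint"], order=["pre", "on", "post"]))
    pretty = " -> ".join(f"{100 * p:.0f}%" for p in rates["proportion"])
    print(f"  phenocopy proportion pre -> on -> post: {pretty} "
          f"(trend p = {trend.pvalue():.3g})")

    # adjusted logistic model
    adj = tp.adjusted_pcr_model(clin.reset_index(), called.astype(float))
    row = adj.table.set_index("covariate").loc["phenocopy"]
    print(f"  adjusted pCR model: phenocopy log-OR = {row['coef']:.3f} "
          f"(p = {row['p']:.3g}), adjusted for grade/T/N stage")

    # drug panel
    tables = tp.AlterationTables.from_tsv(ws / "mutations.tsv", ws / "copy_number.tsv")
    labels = tp.call_tp53_loss(tables, tp.TCGA_SCHEME)
    response = pd.read_csv(ws / "drug_response.tsv", sep="\t")
    response = response[response["sample"].isin(clin.index)]
    panel = tp.drug_panel(response, scores, labels["tp53_loss"])
    panel.to_csv(cfg.RESULTS / "drug_sensitivity_models.tsv", sep="\t", index=False)
    pheno_rows = panel[panel["covariate"] == "phenocopy"]
    print("  per-drug phenocopy coefficients (negative = more sensitive):")
    for _, r in pheno_rows.iterrows():
        print(f"    {r['model']:<22} coef = {r['coef']:.3f}  p = {r['p']:.3g}")

    stats_results = [overall, rcb, trend, adj]
    tp.results_to_tsv(stats_results, cfg.RESULTS / "association_models.tsv")
    print(f"results written under {cfg.RESULTS}")


if __name__ == "__main__":
    main()
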