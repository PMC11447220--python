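import pandas as pd
import pytest

import tp53phenocopy as tp


@pytest.fixture(scope="session")
def small_cohort() -> tp.SyntheticCohort:
    """Small multi-batch compendium shared across read-only tests."""
    config = tp.SimulationConfig(n_samples_per_cohort=150, n_cohorts=2,
                                 n_genes_total=300, n_pathway_genes=30, seed=123)
    return tp.simulate_cohorts(config)


@pytest.fixture(scope="session")
def small_labels(small_cohort) -> pd.DataFrame:
    return tp.call_tp53_loss(small_cohort.alterations, tp.TCGA_SCHEME)


@pytest.fixture(scope="session")
def harmonized_small(small_cohort) -> tp.ExpressionMatrix:
    ranked = tp.impute_missing(tp.dense_rank_normalize(small_cohort.expression))
    corrected, _ = tp.combat_correct(ranked, "C1")
    return corrected


@pytest.fixture(scope="session")
def trained_setup():
    """Medium-size simulate -> label -> harmonize -> train -> score run.

    Training uses the first two cohorts (n = 1400); the third cohort
    (n = 700) is held out.  Shared by signature and pipeline tests.
    """
    config = tp.SimulationConfig(n_samples_per_cohort=700, n_cohorts=3, seed=2024)
    cohort = tp.simulate_cohorts(config)
    labels = tp.call_tp53_loss(cohort.alterations, tp.TCGA_SCHEME)
    ranked = tp.impute_missing(tp.dense_rank_normalize(cohort.expression))
    corrected, _ = tp.combat_correct(ranked, "C1")
    features, _ = tp.select_features(corrected, cohort.geneset)
    train_samples = features.samples[:1400]
    held_samples = features.samples[1400:]
    model = tp.train_model(features.subset_samples(train_samples),
                           labels["tp53_loss"].reindex(train_samples), seed=7)
    calls = tp.score_samples(model, features.subset_samples(held_samples))
    truth = cohort.truth.set_index("sample")
    return dict(cohort=cohort, labels=labels, features=features, model=model,
                calls=calls, truth=truth,
                train_samples=train_samples, held_samples=held_samples)
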