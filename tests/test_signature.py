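"""Gene sets, training determinism, locked-model scoring, thresholding."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import tp53phenocopy as tp
from tp53phenocopy.errors import ConfigurationError, ValidationError
from tp53phenocopy.matrix import ExpressionMatrix


def make_matrix(values, state="corrected"):
    df = pd.DataFrame(values)
    df.index = [f"g{i}" for i in range(df.shape[0])]
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df, pd.Series("B1", index=df.columns), state=state)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def test_gmt_round_trip(tmp_path):
    gs = tp.GeneSet("p53_cell_cycle", ("TP53", "CDKN1A", "CCNB1"), "demo")
    tp.write_gmt([gs], tmp_path / "x.gmt")
    back = tp.read_gmt(tmp_path / "x.gmt")
    assert len(back) == 1 and back[0].name == gs.name and back[0].genes == gs.genes


def test_gmt_rejects_malformed_line(tmp_path):
    (tmp_path / "bad.gmt").write_text("only_name\tdesc\n")
    with pytest.raises(ValidationError, match="malformed"):
        tp.read_gmt(tmp_path / "bad.gmt")


def test_geneset_invariants():
    with pytest.raises(ValidationError):
        tp.GeneSet("empty", ())
    with pytest.raises(ValidationError):
        tp.GeneSet("dup", ("A", "A"))


def test_select_features_intersection_order_and_dropped():
    m = make_matrix(np.zeros((3, 2)))
    m.values.index = ["B", "C", "D"]
    restricted, dropped = tp.select_features(m, tp.GeneSet("gs", ("A", "B", "C")))
    assert list(restricted.genes) == ["B", "C"]
    assert dropped == ["A"]


def test_select_features_identity_and_empty():
    m = make_matrix(np.zeros((2, 2)))
    same, dropped = tp.select_features(m, tp.GeneSet("gs", ("g0", "g1")))
    assert list(same.genes) == ["g0", "g1"] and dropped == []
    with pytest.raises(ValidationError):
        tp.select_features(m, tp.GeneSet("gs", ("X", "Y")))


def test_select_features_retains_planted_signal_genes(harmonized_small, small_cohort):
    restricted, dropped = tp.select_features(harmonized_small, small_cohort.geneset)
    assert list(restricted.genes) == list(small_cohort.geneset.genes)
    assert dropped == []


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def test_training_is_deterministic_given_seed(trained_setup):
    features = trained_setup["features"]
    labels = trained_setup["labels"]["tp53_loss"]
    tr = trained_setup["train_samples"][:400]
    a = tp.train_model(features.subset_samples(tr), labels.reindex(tr), seed=5, n_cv_folds=3)
    b = tp.train_model(features.subset_samples(tr), labels.reindex(tr), seed=5, n_cv_folds=3)
    assert bytes(a.booster.save_raw(raw_format="json")) == \
        bytes(b.booster.save_raw(raw_format="json"))
    assert a.cv_auc == b.cv_auc


def test_single_class_labels_rejected():
    m = make_matrix(np.random.default_rng(0).normal(size=(5, 30)))
    labels = pd.Series(False, index=m.samples)
    with pytest.raises(ValidationError, match="single class"):
        tp.train_model(m, labels, seed=0)


def test_unlabeled_samples_rejected():
    m = make_matrix(np.random.default_rng(0).normal(size=(5, 10)))
    labels = pd.Series([True] * 5, index=m.samples[:5])
    with pytest.raises(ValidationError, match="unlabeled"):
        tp.train_model(m, labels, seed=0)


def test_permuted_labels_give_chance_level_cv_auc(trained_setup):
    features = trained_setup["features"]
    tr = trained_setup["train_samples"][:600]
    rng = np.random.default_rng(1)
    labels = trained_setup["labels"]["tp53_loss"].reindex(tr)
    permuted = pd.Series(rng.permutation(labels.to_numpy()), index=tr)
    model = tp.train_model(features.subset_samples(tr), permuted, seed=2, n_cv_folds=3)
    assert 0.40 < model.cv_auc < 0.60


def test_zero_effect_size_gives_chance_level_heldout_auc():
    config = tp.SimulationConfig(n_samples_per_cohort=400, n_cohorts=2,
                                 n_genes_total=200, n_pathway_genes=20,
                                 pathway_effect_size=0.0, seed=55)
    cohort = tp.simulate_cohorts(config)
    labels = tp.call_tp53_loss(cohort.alterations, tp.TCGA_SCHEME)
    corrected, _ = tp.combat_correct(
        tp.impute_missing(tp.dense_rank_normalize(cohort.expression)), "C1")
    features, _ = tp.select_features(corrected, cohort.geneset)
    tr, ho = features.samples[:600], features.samples[600:]
    model = tp.train_model(features.subset_samples(tr), labels["tp53_loss"].reindex(tr),
                           seed=3, n_cv_folds=3)
    calls = tp.score_samples(model, features.subset_samples(ho))
    truth = cohort.truth.set_index("sample")["phenotype"].reindex(ho)
    assert abs(roc_auc_score(truth, calls.scores) - 0.5) < 0.12


def test_heldout_auc_monotone_in_effect_size():
    aucs = []
    for delta in (0.0, 0.4, 0.8):
        config = tp.SimulationConfig(n_samples_per_cohort=500, n_cohorts=2,
                                     n_genes_total=200, n_pathway_genes=30,
                                     pathway_effect_size=delta, seed=77)
        cohort = tp.simulate_cohorts(config)
        labels = tp.call_tp53_loss(cohort.alterations, tp.TCGA_SCHEME)
        corrected, _ = tp.combat_correct(
            tp.impute_missing(tp.dense_rank_normalize(cohort.expression)), "C1")
        features, _ = tp.select_features(corrected, cohort.geneset)
        tr, ho = features.samples[:700], features.samples[700:]
        model = tp.train_model(features.subset_samples(tr),
                               labels["tp53_loss"].reindex(tr), seed=4, n_cv_folds=3)
        calls = tp.score_samples(model, features.subset_samples(ho))
        truth = cohort.truth.set_index("sample")["phenotype"].reindex(ho)
        aucs.append(roc_auc_score(truth, calls.scores))
    assert aucs[1] >= aucs[0] - 0.03 and aucs[2] >= aucs[1] - 0.03


# ---------------------------------------------------------------------------
# scoring and locking
# ---------------------------------------------------------------------------

def test_scoring_training_matrix_reproduces_training_predictions(trained_setup):
    features = trained_setup["features"]
    model = trained_setup["model"]
    tr = trained_setup["train_samples"]
    calls = tp.score_samples(model, features.subset_samples(tr))
    np.testing.assert_array_equal(calls.scores.to_numpy(),
                                  model.training_scores.to_numpy())


def test_save_load_score_bit_identical(trained_setup, tmp_path):
    model = trained_setup["model"]
    features = trained_setup["features"]
    ho = trained_setup["held_samples"]
    model.save(tmp_path / "model.json")
    loaded = tp.PhenocopyModel.load(tmp_path / "model.json")
    a = tp.score_samples(model, features.subset_samples(ho)).scores
    b = tp.score_samples(loaded, features.subset_samples(ho)).scores
    np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())
    assert loaded.feature_genes == model.feature_genes
    assert loaded.threshold == model.threshold


def test_scores_in_unit_interval_and_calls_match_threshold(trained_setup):
    calls = trained_setup["calls"]
    assert calls.scores.between(0, 1).all()
    pd.testing.assert_series_equal(calls.phenocopy,
                                   calls.scores.ge(calls.threshold), check_names=False)


def test_missing_feature_gene_errors_unless_override(trained_setup):
    features = trained_setup["features"]
    model = trained_setup["model"]
    ho = trained_setup["held_samples"]
    crippled = features.subset_samples(ho)
    dropped_gene = model.feature_genes[0]
    crippled = crippled.with_values(crippled.values.drop(index=dropped_gene))
    with pytest.raises(ValidationError, match=dropped_gene):
        tp.score_samples(model, crippled)
    filled = tp.score_samples(model, crippled, fill_missing_with_training_mean=True)
    assert filled.scores.between(0, 1).all()


def test_reference_mean_input_scores_identically_across_calls(trained_setup):
    model = trained_setup["model"]
    vals = pd.DataFrame({f"s{i}": model.training_means for i in range(3)})
    m = ExpressionMatrix(vals, pd.Series("B1", index=vals.columns), state="corrected")
    first = tp.score_samples(model, m).scores
    second = tp.score_samples(model, m).scores
    assert first.nunique() == 1
    np.testing.assert_array_equal(first.to_numpy(), second.to_numpy())


def test_phenocopies_without_genotype_detected_under_clean_labels():
    """Trained on lightly contaminated labels (pi = 0.1), at the reference
    pathway effect size, the fixed 0.5 cutoff recovers >= 80% of held-out
    phenotype-positive samples that lack the genotype."""
    config = tp.SimulationConfig(n_samples_per_cohort=600, n_cohorts=3,
                                 phenocopy_without_genotype_rate=0.1, seed=91)
    cohort = tp.simulate_cohorts(config)
    labels = tp.call_tp53_loss(cohort.alterations, tp.TCGA_SCHEME)
    corrected, _ = tp.combat_correct(
        tp.impute_missing(tp.dense_rank_normalize(cohort.expression)), "C1")
    features, _ = tp.select_features(corrected, cohort.geneset)
    tr, ho = features.samples[:1200], features.samples[1200:]
    model = tp.train_model(features.subset_samples(tr),
                           labels["tp53_loss"].reindex(tr), seed=6, n_cv_folds=3)
    calls = tp.score_samples(model, features.subset_samples(ho))
    truth = cohort.truth.set_index("sample").reindex(ho)
    planted = truth["phenotype"] & ~truth["genotype_loss"]
    assert calls.phenocopy[planted].mean() >= 0.8


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def test_fixed_threshold_binarization(trained_setup):
    model = trained_setup["model"]
    tp.set_threshold(model, 0.5)
    calls = tp.PhenocopyCalls(pd.Series([0.4, 0.6], index=["a", "b"]), model.threshold)
    assert calls.phenocopy.tolist() == [False, True]


def test_prevalence_quantile_threshold(trained_setup):
    model = trained_setup["model"]
    old = model.threshold
    try:
        tp.set_threshold(model, "training_prevalence_quantile", prevalence=0.3)
        called = model.training_scores.ge(model.threshold).mean()
        assert abs(called - 0.3) < 0.02  # up to ties
    finally:
        model.threshold = old


@pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
def test_degenerate_cutoffs_rejected(trained_setup, bad):
    with pytest.raises(ConfigurationError):
        tp.set_threshold(trained_setup["model"], bad)
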