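"""Association statistics: Fisher, trend, linear and logistic models, rates."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import tp53phenocopy as tp
from tp53phenocopy.errors import (ConfigurationError, SeparationError,
                                  SingularDesignError, ValidationError)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def test_fisher_two_sided_enumeration_example():
    # margins (2,2)/(2,2) admit 3 tables with probabilities 1/6, 4/6, 1/6;
    # the observed diagonal table has p = 1/6, two-sided sum = 2/6 = 1/3
    res = tp.fisher_exact_2x2([[2, 0], [0, 2]])
    assert res.pvalue() == pytest.approx(1 / 3, rel=1e-12)


def test_fisher_balanced_table():
    res = tp.fisher_exact_2x2([[1, 1], [1, 1]])
    assert res.pvalue() == 1.0
    assert res.extra["odds_ratio"] == pytest.approx(1.0)


def test_fisher_degenerate_margin_flagged_not_raised():
    res = tp.fisher_exact_2x2([[5, 0], [0, 0]])
    assert res.extra["degenerate"] and res.pvalue() == 1.0


def test_fisher_zero_cell_odds_ratio_convention():
    assert np.isinf(tp.fisher_exact_2x2([[3, 0], [1, 2]]).extra["odds_ratio"])


def test_fisher_agrees_with_scipy_on_random_tables():
    rng = np.random.default_rng(8)
    for _ in range(25):
        table = rng.integers(0, 30, size=(2, 2))
        if 0 in table.sum(axis=0) or 0 in table.sum(axis=1):
            continue
        ours = tp.fisher_exact_2x2(table).pvalue()
        ref = sps.fisher_exact(table).pvalue
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)


def test_fisher_rejects_non_integer_or_wrong_shape():
    with pytest.raises(ValidationError):
        tp.fisher_exact_2x2([[1.5, 2], [3, 4]])
    with pytest.raises(ValidationError):
        tp.fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])


# ---------------------------------------------------------------------------
# Cochran-Armitage trend test
# ---------------------------------------------------------------------------

def test_trend_zero_statistic_when_proportions_equal():
    res = tp.cochran_armitage_trend([[10, 20, 30], [10, 20, 30]])
    assert res.extra["z"] == pytest.approx(0.0, abs=1e-12)
    assert res.pvalue() == 1.0


def test_trend_k2_squares_to_chi2_statistic():
    table = np.array([[12, 30], [25, 14]])
    z = tp.cochran_armitage_trend(table).extra["z"]
    chi2 = sps.chi2_contingency(table, correction=False).statistic
    assert z**2 == pytest.approx(chi2, abs=1e-10)


@pytest.mark.parametrize("a,b", [(2.0, 3.0), (-1.0, 10.0), (0.5, 0.0)])
def test_trend_invariant_under_affine_score_transform(a, b):
    table = [[5, 9, 14, 22], [20, 16, 11, 8]]
    base = tp.cochran_armitage_trend(table, scores=[0, 1, 2, 3])
    scaled = tp.cochran_armitage_trend(table, scores=[a * s + b for s in range(4)])
    assert scaled.extra["z"] == pytest.approx(math.copysign(base.extra["z"], a * base.extra["z"]),
                                              abs=1e-10)
    assert scaled.pvalue() == pytest.approx(base.pvalue(), abs=1e-12)


def test_trend_agrees_with_permutation_null():
    table = np.array([[40, 52, 61, 75], [60, 48, 39, 25]])
    res = tp.cochran_armitage_trend(table)
    rng = np.random.default_rng(3)
    ni = table.sum(axis=0)
    R1 = table[0].sum()
    n_draws = 30_000
    draws = rng.multivariate_hypergeometric(ni, R1, size=n_draws)
    s = np.arange(4.0)
    T = draws @ s
    ET = R1 * (s @ ni) / table.sum()
    T_obs = table[0] @ s
    d, d_obs = np.abs(T - ET), abs(T_obs - ET)
    # the continuous normal p targets the mid-p of the lattice-valued null;
    # residual disagreement is bounded by half the boundary atom
    atom = np.mean(np.abs(d - d_obs) <= 1e-9)
    p_mid = np.mean(d > d_obs + 1e-9) + 0.5 * atom
    se = np.sqrt(max(p_mid * (1 - p_mid), 1e-12) / n_draws)
    # rule-of-three floor: a p below ~3/n_draws is indistinguishable from 0
    assert abs(res.pvalue() - p_mid) < max(3 * se + 0.5 * atom, 3.0 / n_draws)


def test_trend_degenerate_single_row():
    res = tp.cochran_armitage_trend([[5, 6, 7], [0, 0, 0]])
    assert res.extra["degenerate"] and res.pvalue() == 1.0


# ---------------------------------------------------------------------------
# drug sensitivity linear models
# ---------------------------------------------------------------------------

def _balanced_design(n=40):
    samples = [f"s{i}" for i in range(n)]
    pheno = pd.Series([i % 2 == 0 for i in range(n)], index=samples).astype(float)
    geno = pd.Series([(i // 2) % 2 == 0 for i in range(n)], index=samples).astype(float)
    return samples, pheno, geno


def test_noiseless_coefficients_recovered_exactly():
    samples, pheno, geno = _balanced_design()
    y = -1.0 * pheno + 0.0 * geno
    response = pd.DataFrame({"sample": samples, "drug": "cisplatin", "value": y.values})
    res = tp.drug_sensitivity_lm(response, pheno, geno.astype(bool), "cisplatin")
    assert res.coef("phenocopy") == pytest.approx(-1.0, abs=1e-10)
    assert res.coef("tp53_loss") == pytest.approx(0.0, abs=1e-10)


def test_orthogonal_predictors_match_univariate_fits():
    samples, pheno, geno = _balanced_design(200)
    # centered, exactly orthogonal in-sample by construction
    p = pheno - pheno.mean()
    g = geno - geno.mean()
    assert (p * g).sum() == pytest.approx(0.0, abs=1e-12)
    rng = np.random.default_rng(5)
    y = pd.Series(-0.7 * p + 0.3 * g + rng.normal(0, 1, len(samples)), index=samples)
    response = pd.DataFrame({"sample": samples, "drug": "d", "value": y.values})
    multi = tp.drug_sensitivity_lm(response, p, g, "d")
    uni_p = np.polyfit(p.values, y.values, 1)[0]
    uni_g = np.polyfit(g.values, y.values, 1)[0]
    assert multi.coef("phenocopy") == pytest.approx(uni_p, abs=1e-10)
    assert multi.coef("tp53_loss") == pytest.approx(uni_g, abs=1e-10)


def test_response_sign_flip_negates_coefficients_keeps_pvalues():
    samples, pheno, geno = _balanced_design(100)
    rng = np.random.default_rng(6)
    y = -0.5 * pheno + rng.normal(0, 1, 100)
    resp = pd.DataFrame({"sample": samples, "drug": "d", "value": y})
    flipped = resp.assign(value=-resp["value"])
    a = tp.drug_sensitivity_lm(resp, pheno, geno.astype(bool), "d")
    b = tp.drug_sensitivity_lm(flipped, pheno, geno.astype(bool), "d")
    assert a.coef("phenocopy") == pytest.approx(-b.coef("phenocopy"), abs=1e-12)
    assert a.pvalue("phenocopy") == pytest.approx(b.pvalue("phenocopy"), abs=1e-12)


def test_collinear_design_rejected():
    samples, pheno, _ = _balanced_design(30)
    resp = pd.DataFrame({"sample": samples, "drug": "d", "value": np.arange(30.0)})
    with pytest.raises(SingularDesignError):
        tp.drug_sensitivity_lm(resp, pheno, pheno.astype(bool), "d")


def test_too_few_samples_rejected():
    samples = ["a", "b", "c", "d"]
    pheno = pd.Series([0.0, 1, 0, 1], index=samples)
    geno = pd.Series([False, False, True, True], index=samples)
    resp = pd.DataFrame({"sample": samples, "drug": "d", "value": [1.0, 2, 3, 4]})
    with pytest.raises(ValidationError):
        tp.drug_sensitivity_lm(resp, pheno, geno, "d")


def test_drug_panel_emits_bh_column(small_cohort, small_labels):
    truth = small_cohort.truth.set_index("sample")
    panel = tp.drug_panel(small_cohort.drug_response,
                          truth["phenotype"].astype(float),
                          small_labels["tp53_loss"])
    assert {"model", "covariate", "coef", "se", "stat", "p", "n", "p_bh"} <= set(panel.columns)
    non_int = panel[panel["covariate"] != "intercept"]
    assert non_int["p_bh"].notna().all()
    # BH never decreases a raw p-value
    assert (non_int["p_bh"] >= non_int["p"] - 1e-12).all()


# ---------------------------------------------------------------------------
# adjusted pCR logistic model
# ---------------------------------------------------------------------------

def _clinical_frame(n, beta, seed):
    rng = np.random.default_rng(seed)
    pheno = rng.random(n) < 0.5
    grade = rng.integers(1, 4, n)
    t_stage = rng.integers(1, 5, n)
    n_stage = rng.integers(0, 4, n)
    logit = -1.0 + beta * pheno + 0.2 * (grade - 2)
    pcr = rng.random(n) < 1 / (1 + np.exp(-logit))
    clinical = pd.DataFrame({"sample": [f"s{i}" for i in range(n)], "pcr": pcr.astype(int),
                             "grade": grade, "t_stage": t_stage, "n_stage": n_stage})
    calls = pd.Series(pheno.astype(float), index=clinical["sample"].values)
    return clinical, calls


def test_adjusted_model_recovers_planted_log_odds():
    clinical, calls = _clinical_frame(2000, beta=1.0, seed=11)
    res = tp.adjusted_pcr_model(clinical, calls)
    est = res.coef("phenocopy")
    se = float(res.table.set_index("covariate").loc["phenocopy", "se"])
    assert est - 1.96 * se < 1.0 < est + 1.96 * se
    assert res.pvalue("phenocopy") < 1e-6


def test_adjusted_model_null_pvalues_uniform():
    pvals = []
    for rep in range(60):
        clinical, calls = _clinical_frame(400, beta=0.0, seed=100 + rep)
        pvals.append(tp.adjusted_pcr_model(clinical, calls).pvalue("phenocopy"))
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


def test_perfect_separation_raises():
    clinical, calls = _clinical_frame(200, beta=0.0, seed=13)
    clinical = clinical.assign(pcr=(calls.values > 0.5).astype(int))
    with pytest.raises(SeparationError):
        tp.adjusted_pcr_model(clinical, calls)


def test_indicator_coding_expands_covariates():
    clinical, calls = _clinical_frame(500, beta=0.5, seed=17)
    res = tp.adjusted_pcr_model(clinical, calls, coding="indicator")
    assert any(c.startswith("grade_") for c in res.table["covariate"])
    with pytest.raises(ConfigurationError):
        tp.adjusted_pcr_model(clinical, calls, coding="nonsense")


# ---------------------------------------------------------------------------
# rate summaries
# ---------------------------------------------------------------------------

def test_rates_clopper_pearson_example():
    calls = pd.Series([True] * 8 + [False] * 2, index=[f"s{i}" for i in range(10)])
    strata = pd.Series("A", index=calls.index)
    out = tp.summarize_phenocopy_rates(calls, strata)
    row = out.iloc[0]
    assert row["proportion"] == pytest.approx(0.8)
    assert row["ci_low"] == pytest.approx(0.444, abs=5e-4)
    assert row["ci_high"] == pytest.approx(0.975, abs=5e-4)


def test_rates_single_stratum_equals_overall():
    calls = pd.Series([True, False, True], index=list("abc"))
    out = tp.summarize_phenocopy_rates(calls, pd.Series("all", index=calls.index))
    assert out.iloc[0]["proportion"] == pytest.approx(calls.mean())


def test_rates_empty_stratum_reported_without_error():
    calls = pd.Series([True, False], index=list("ab"))
    out = tp.summarize_phenocopy_rates(calls, pd.Series(["x", "x"], index=calls.index),
                                       order=["x", "y"])
    empty = out[out["stratum"] == "y"].iloc[0]
    assert empty["n"] == 0 and np.isnan(empty["proportion"])


def test_timepoint_depletion_monotone_on_planted_truth(small_cohort):
    clin = small_cohort.clinical.set_index("sample")
    truth = small_cohort.truth.set_index("sample")["phenotype"]
    out = tp.summarize_phenocopy_rates(truth, clin["timepoint"],
                                       order=["pre", "on", "post"])
    props = out["proportion"].tolist()
    assert props[0] > props[1] > props[2]


def test_contingency_builders():
    calls = pd.Series([True, True, False, False], index=list("abcd"))
    pcr = pd.Series([1, 0, 1, 0], index=list("abcd")).astype(bool)
    table = tp.pcr_contingency(calls, pcr)
    assert table.tolist() == [[1, 1], [1, 1]]
    rcb = pd.Series([0, 1, 0, 3], index=list("abcd"))
    ordered = tp.ordered_contingency(calls, rcb, order=[0, 1, 2, 3])
    assert ordered.shape == (2, 4)
    assert ordered.sum() == 4
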