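"""Validation statistics for the phenocopy signature.

Per-drug multivariable linear models (sensitivity ~ phenocopy + genotype),
Fisher's exact test on pathologic-complete-response (pCR) contingency
tables, the Cochran-Armitage trend test over ordered categories
(residual-cancer-burden classes, treatment timepoints), covariate-adjusted
logistic pCR models, and stratified phenocopy-rate summaries with exact
binomial intervals.

All drug-sensitivity metrics are oriented so that lower values mean greater
sensitivity (Z-scored IC50, negated activity area, negated dose-response
AUC); a negative phenocopy coefficient therefore means the phenocopy group
is more chemosensitive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import ConfigurationError, SeparationError, SingularDesignError, ValidationError

METRIC_KINDS = ("z_ic50", "neg_actarea", "neg_auc")

#: relative tolerance when comparing table probabilities to the observed one
FISHER_REL_TOL = 1e-7


@dataclass
class AssociationResult:
    """One fitted model or test: per-covariate records plus metadata."""

    model_id: str
    kind: str  # linear | logistic | fisher | trend
    table: pd.DataFrame  # columns: covariate, coef, se, stat, p
    n: int
    extra: dict = field(default_factory=dict)

    def pvalue(self, covariate: str | None = None) -> float:
        if covariate is None:
            return float(self.table["p"].iloc[0])
        row = self.table[self.table["covariate"] == covariate]
        if row.empty:
            raise KeyError(covariate)
        return float(row["p"].iloc[0])

    def coef(self, covariate: str) -> float:
        row = self.table[self.table["covariate"] == covariate]
        if row.empty:
            raise KeyError(covariate)
        return float(row["coef"].iloc[0])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "model", self.model_id)
        out["n"] = self.n
        return out


def results_to_tsv(results: list[AssociationResult], path: str | Path) -> None:
    if results:
        out = pd.concat([r.to_frame() for r in results], ignore_index=True)
    else:
        out = pd.DataFrame(columns=["model", "covariate", "coef", "se", "stat", "p", "n"])
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# drug sensitivity linear models
# ---------------------------------------------------------------------------

def drug_sensitivity_lm(response: pd.DataFrame, calls: pd.Series,
                        genotype: pd.Series, drug: str,
                        metric_kind: str | None = None) -> AssociationResult:
    """OLS of drug sensitivity on intercept + phenocopy + DNA genotype.

    Parameters
    ----------
    response
        Long table with columns (sample, drug, value[, metric_kind]);
        lower value = more sensitive.
    calls
        Per-sample phenocopy score (continuous) or binary call.
    genotype
        Per-sample boolean biallelic TP53-loss status.

    Inference: two-sided t tests on n - p degrees of freedom.  A negative
    phenocopy coefficient means phenocopy samples are more sensitive.
    """
    rows = response[response["drug"] == drug]
    if metric_kind is not None:
        if metric_kind not in METRIC_KINDS:
            raise ConfigurationError(f"unknown metric_kind {metric_kind!r}")
        if "metric_kind" in rows.columns:
            rows = rows[rows["metric_kind"] == metric_kind]
    if rows.empty:
        raise ValidationError(f"no response rows for drug {drug!r}")
    dat = pd.DataFrame({
        "y": pd.Series(rows["value"].values, index=rows["sample"].values),
    })
    dat["phenocopy"] = calls.reindex(dat.index).astype(float)
    dat["tp53_loss"] = genotype.reindex(dat.index).astype(float)
    dat = dat.dropna()
    n, p = len(dat), 3
    if n < p + 3:
        raise ValidationError(f"only {n} usable samples for drug {drug!r}; need >= {p + 3}")
    X = sm.add_constant(dat[["phenocopy", "tp53_loss"]], has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SingularDesignError(f"collinear design for drug {drug!r}")
    fit = sm.OLS(dat["y"], X).fit()
    table = pd.DataFrame({
        "covariate": ["intercept", "phenocopy", "tp53_loss"],
        "coef": fit.params.values,
        "se": fit.bse.values,
        "stat": fit.tvalues.values,
        "p": fit.pvalues.values,
    })
    return AssociationResult(model_id=f"drug:{drug}", kind="linear", table=table, n=n,
                             extra={"r_squared": float(fit.rsquared)})


def drug_panel(response: pd.DataFrame, calls: pd.Series, genotype: pd.Series,
               metric_kind: str | None = None) -> pd.DataFrame:
    """Fit one linear model per drug; emit raw p and a Benjamini-Hochberg
    column alongside (the per-drug models themselves are uncorrected)."""
    results = []
    for drug in pd.unique(response["drug"]):
        res = drug_sensitivity_lm(response, calls, genotype, drug, metric_kind)
        results.append(res.to_frame())
    out = pd.concat(results, ignore_index=True)
    mask = out["covariate"] != "intercept"
    out["p_bh"] = np.nan
    out.loc[mask, "p_bh"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# contingency-table tests
# ---------------------------------------------------------------------------

def _as_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.ndim != 2 or arr.shape[0] != 2:
        raise ValidationError(f"expected a 2 x k table, got shape {arr.shape}")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValidationError("contingency counts must be nonnegative integers")
    return arr.astype(np.int64)


def fisher_exact_2x2(table) -> AssociationResult:
    """Two-sided Fisher's exact test on a 2 x 2 table.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins whose probability is <= the observed table's (relative
    tolerance 1e-7 for ties).  The sample odds ratio is ad/bc with inf when
    only the denominator has a zero.  A zero row or column margin is flagged
    (``degenerate=True``) and returns p = 1.0 rather than raising.
    """
    arr = _as_table(table)
    if arr.shape != (2, 2):
        raise ValidationError(f"fisher_exact_2x2 needs a 2 x 2 table, got {arr.shape}")
    a, b = arr[0]
    c, d = arr[1]
    n = arr.sum()
    row1, col1 = a + b, a + c
    degenerate = 0 in (row1, n - row1, col1, n - col1)
    if degenerate:
        p = 1.0
    else:
        rv = sps.hypergeom(n, row1, col1)
        support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
        probs = rv.pmf(support)
        p = float(min(1.0, probs[probs <= rv.pmf(a) * (1 + FISHER_REL_TOL)].sum()))
        if p > 1 - 1e-9:  # every table qualified; the sum is 1 up to float error
            p = 1.0
    if b * c > 0:
        odds_ratio = (a * d) / (b * c)
    elif a * d > 0:
        odds_ratio = np.inf
    else:
        odds_ratio = np.nan
    table_out = pd.DataFrame({"covariate": ["association"], "coef": [np.log(odds_ratio)
                              if np.isfinite(odds_ratio) and odds_ratio > 0 else np.nan],
                              "se": [np.nan], "stat": [np.nan], "p": [p]})
    return AssociationResult(model_id="fisher_2x2", kind="fisher", table=table_out,
                             n=int(n), extra={"odds_ratio": float(odds_ratio),
                                              "degenerate": bool(degenerate)})


def cochran_armitage_trend(table, scores=None) -> AssociationResult:
    """Cochran-Armitage test for trend in a 2 x k table with ordered columns.

    The statistic is T = sum_i s_i * r_1i compared with its null moments
    given the margins; the variance uses Armitage's form
    R1*R2/n^3 * (n * sum s_i^2 n_i - (sum s_i n_i)^2), under which the
    squared statistic reduces exactly to the 2 x 2 Pearson chi-square when
    k = 2.  Z is referenced to the standard normal, two-sided.  Default
    scores are 0..k-1; the statistic is invariant under affine rescaling of
    the scores.  On the lattice of achievable tables the continuous normal
    p approximates the conditional-permutation mid-p.
    """
    arr = _as_table(table)
    k = arr.shape[1]
    if k < 2:
        raise ValidationError("trend test needs >= 2 ordered columns")
    s = np.arange(k, dtype=float) if scores is None else np.asarray(scores, dtype=float)
    if s.shape != (k,):
        raise ValidationError(f"need {k} column scores, got {s.shape}")
    n = arr.sum()
    r1 = arr[0].astype(float)
    ni = arr.sum(axis=0).astype(float)
    R1, R2 = r1.sum(), arr[1].sum()
    degenerate = R1 == 0 or R2 == 0 or np.count_nonzero(ni) < 2
    if degenerate:
        table_out = pd.DataFrame({"covariate": ["trend"], "coef": [np.nan], "se": [np.nan],
                                  "stat": [0.0], "p": [1.0]})
        return AssociationResult("cochran_armitage", "trend", table_out, int(n),
                                 extra={"degenerate": True})
    T = float(s @ r1)
    ET = R1 * float(s @ ni) / n
    var = (R1 * R2 / float(n)**3) * (n * float((s**2) @ ni) - float(s @ ni) ** 2)
    if var <= 0:  # all mass in one column after scoring
        z, p = 0.0, 1.0
    else:
        z = (T - ET) / np.sqrt(var)
        p = max(float(2 * sps.norm.sf(abs(z))), float(np.finfo(float).tiny))
    table_out = pd.DataFrame({"covariate": ["trend"], "coef": [np.nan], "se": [np.nan],
                              "stat": [z], "p": [min(p, 1.0)]})
    return AssociationResult("cochran_armitage", "trend", table_out, int(n),
                             extra={"degenerate": False, "z": float(z)})


# ---------------------------------------------------------------------------
# covariate-adjusted pCR model
# ---------------------------------------------------------------------------

def adjusted_pcr_model(clinical: pd.DataFrame, calls: pd.Series,
                       covariates: tuple = ("grade", "t_stage", "n_stage"),
                       coding: str = "ordinal") -> AssociationResult:
    """Logistic regression of pCR on phenocopy plus clinical covariates.

    Covariates default to ordinal-integer coding (``coding='ordinal'``);
    ``coding='indicator'`` expands each into level dummies.  Wald z-tests.

    Raises
    ------
    SeparationError
        On complete or quasi-complete separation (the likelihood has no
        finite maximizer; coefficients would diverge).
    """
    if coding not in ("ordinal", "indicator"):
        raise ConfigurationError(f"unknown covariate coding {coding!r}")
    dat = clinical.set_index("sample") if "sample" in clinical.columns else clinical.copy()
    y = dat["pcr"].astype(float)
    X = pd.DataFrame(index=dat.index)
    X["phenocopy"] = calls.reindex(dat.index).astype(float)
    for cov in covariates:
        if coding == "ordinal":
            X[cov] = dat[cov].astype(float)
        else:
            dummies = pd.get_dummies(dat[cov], prefix=cov, drop_first=True).astype(float)
            X = pd.concat([X, dummies], axis=1)
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep], X[keep]
    X = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(f"separation in adjusted pCR model: {exc}") from exc
    if np.abs(fit.params).max() > 30:
        raise SeparationError(
            "quasi-separation in adjusted pCR model: diverging coefficient "
            f"{fit.params.abs().idxmax()} = {fit.params.abs().max():.1f}")
    table = pd.DataFrame({
        "covariate": ["intercept" if c == "const" else c for c in X.columns],
        "coef": fit.params.values,
        "se": fit.bse.values,
        "stat": fit.tvalues.values,
        "p": fit.pvalues.values,
    })
    return AssociationResult("adjusted_pcr", "logistic", table, int(len(y)),
                             extra={"converged": bool(fit.mle_retvals.get("converged", True))})


# ---------------------------------------------------------------------------
# phenocopy-rate summaries
# ---------------------------------------------------------------------------

def summarize_phenocopy_rates(calls: pd.Series, strata: pd.Series,
                              order: list | None = None) -> pd.DataFrame:
    """Phenocopy counts and proportions per stratum with exact
    (Clopper-Pearson) binomial 95% intervals.

    Empty strata are reported with n = 0 and missing proportions.
    """
    calls = calls.astype(bool)
    missing = calls.index.difference(strata.index)
    if len(missing):
        raise ValidationError(f"samples without a stratum label: {list(missing[:5])}")
    strata = strata.reindex(calls.index)
    levels = order if order is not None else sorted(pd.unique(strata.dropna()))
    rows = []
    for level in levels:
        members = calls[strata == level]
        n = int(len(members))
        k = int(members.sum())
        if n == 0:
            rows.append((level, 0, 0, np.nan, np.nan, np.nan))
            continue
        lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
        rows.append((level, n, k, k / n, float(lo), float(hi)))
    return pd.DataFrame(rows, columns=["stratum", "n", "n_phenocopy", "proportion",
                                       "ci_low", "ci_high"])


def pcr_contingency(calls: pd.Series, pcr: pd.Series) -> np.ndarray:
    """2 x 2 table rows (phenocopy, not phenocopy) x columns (no pCR, pCR)."""
    calls = calls.astype(bool)
    pcr = pcr.reindex(calls.index).astype(bool)
    return np.array([
        [int((calls & ~pcr).sum()), int((calls & pcr).sum())],
        [int((~calls & ~pcr).sum()), int((~calls & pcr).sum())],
    ])


def ordered_contingency(calls: pd.Series, categories: pd.Series,
                        order: list) -> np.ndarray:
    """2 x k table: rows (phenocopy, not) x ordered category columns."""
    calls = calls.astype(bool)
    categories = categories.reindex(calls.index)
    cols = []
    for level in order:
        members = calls[categories == level]
        cols.append([int(members.sum()), int((~members).sum())])
    return np.array(cols).T
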