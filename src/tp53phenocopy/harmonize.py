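"""Cross-platform expression harmonization.

Three stages, applied in this order:

1. :func:`dense_rank_normalize` — within each sample, expression values are
   replaced by dense ranks (ties share a rank, the next distinct value
   increments the rank by one).  Dense ranking is invariant under any strictly
   increasing per-sample transform, which is what makes microarray and RNA-seq
   cohorts comparable on a common scale.
2. :func:`impute_missing` — a missing (gene, sample) cell is replaced by the
   mean of that gene over the other samples of the same cohort.
3. :func:`combat_correct` — reference-batch empirical-Bayes location/scale
   batch correction (the parametric ComBat model).  All batches are aligned to
   a designated reference batch, whose values are returned numerically
   unchanged, so a classifier locked on reference-scaled data stays valid when
   new cohorts are corrected against the same reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .matrix import ExpressionMatrix


def dense_rank_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each sample's values by dense ranks (smallest value -> 1).

    Missing entries are excluded from ranking and stay missing.

    Raises
    ------
    ValidationError
        If the matrix is not in the ``raw`` state, or a sample has no
        non-missing values.
    """
    if matrix.state != "raw":
        raise ValidationError(f"dense_rank_normalize expects state 'raw', got {matrix.state!r}")
    empty = matrix.values.columns[matrix.values.isna().all(axis=0)].tolist()
    if empty:
        raise ValidationError(f"samples with zero non-missing values: {empty}")
    ranked = matrix.values.rank(axis=0, method="dense", na_option="keep")
    return matrix.with_values(ranked, state="ranked")


def impute_missing(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Fill each missing cell with the gene's mean over its cohort's other samples.

    Imputation is cohort-local: the mean is taken over the non-missing values
    of the same gene among samples sharing the batch label.

    Raises
    ------
    ValidationError
        If some gene is entirely missing within a cohort that needs a value
        for it.
    """
    if not matrix.values.isna().any().any():
        return matrix
    values = matrix.values.copy()
    for batch in matrix.batch_ids():
        cols = matrix.samples[matrix.batches.values == batch]
        block = values[cols]
        if not block.isna().any().any():
            continue
        gene_means = block.mean(axis=1)  # skips NaN
        dead = block.index[block.isna().all(axis=1)]
        if len(dead):
            raise ValidationError(
                f"genes entirely missing in cohort {batch!r}: {list(dead[:10])}")
        values[cols] = block.T.fillna(gene_means).T
    return matrix.with_values(values, state=matrix.state)


@dataclass
class BatchModel:
    """Fitted parameters of the reference-batch empirical-Bayes correction.

    Attributes
    ----------
    reference_batch
        Batch left numerically unchanged; its per-gene mean/variance define
        the standardization.
    grand_mean, pooled_var
        Per-gene standardization parameters estimated from the reference
        samples (variance with the 1/n normalization of the reference
        residuals).
    gamma_hat, delta_hat
        Per-batch x per-gene raw location / scale estimates on the
        standardized scale (non-reference batches only).
    gamma_star, delta_star
        Empirical-Bayes shrunken posterior location / scale values.
    hyperparameters
        Per-batch method-of-moments prior parameters:
        ``gamma_bar``/``tau2`` (normal prior on locations) and
        ``a_prior``/``b_prior`` (inverse-gamma prior on scales).
    """

    reference_batch: object
    grand_mean: pd.Series
    pooled_var: pd.Series
    gamma_hat: pd.DataFrame
    delta_hat: pd.DataFrame
    gamma_star: pd.DataFrame
    delta_star: pd.DataFrame
    hyperparameters: pd.DataFrame
    reference_samples: list = field(default_factory=list)


def _shrink_batch(gamma_hat: np.ndarray, delta_hat: np.ndarray, sdat: np.ndarray,
                  conv: float = 1e-4, max_iter: int = 500):
    """Iterative joint posterior solution for one batch's location/scale.

    ``sdat`` is the standardized data block (genes x batch samples).
    Hyperparameters by method of moments: a normal prior on the per-gene
    locations and an inverse-gamma prior on the per-gene variances.
    """
    n = sdat.shape[1]
    gamma_bar = gamma_hat.mean()
    tau2 = gamma_hat.var(ddof=1)
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    a_prior = (2.0 * s2 + m**2) / s2
    b_prior = (m * s2 + m**3) / s2

    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    for _ in range(max_iter):
        g_new = (tau2 * n * gamma_hat + d_old * gamma_bar) / (tau2 * n + d_old)
        sum2 = ((sdat - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
        eps = 1e-30
        change = max(np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), eps),
                     np.abs(d_new - d_old).max() / max(np.abs(d_old).max(), eps))
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    hyper = dict(gamma_bar=gamma_bar, tau2=tau2, a_prior=a_prior, b_prior=b_prior)
    return g_old, d_old, hyper


def combat_correct(matrix: ExpressionMatrix, reference_batch,
                   reference_samples: list | None = None) -> tuple[ExpressionMatrix, BatchModel]:
    """Reference-batch parametric empirical-Bayes batch correction.

    Per gene, values are standardized with the reference batch's mean and
    residual variance; each non-reference batch's location and scale on the
    standardized scale are shrunk toward their across-gene priors (normal for
    locations, inverse-gamma for scales, hyperparameters by method of
    moments); the adjusted values are then destandardized.  The reference
    batch is returned numerically unchanged.

    Parameters
    ----------
    matrix
        Ranked (and imputed — no missing values) expression matrix.
    reference_batch
        Batch label to anchor the correction.
    reference_samples
        Optional subset of reference-batch samples whose mean/variance define
        the standardization (e.g. only the breast-invasive-carcinoma samples
        of a pan-cancer reference).  Defaults to the whole reference batch.

    Raises
    ------
    ConfigurationError
        Fewer than 2 batches, or unknown reference batch.
    ValidationError
        Wrong state, missing values, or a batch with a single sample.
    """
    if matrix.state != "ranked":
        raise ValidationError(f"combat_correct expects state 'ranked', got {matrix.state!r}")
    if matrix.values.isna().any().any():
        raise ValidationError("combat_correct requires complete data; impute first")
    batches = matrix.batch_ids()
    if len(batches) < 2:
        raise ConfigurationError(f"need >= 2 batches, got {len(batches)}")
    if reference_batch not in batches:
        raise ConfigurationError(f"reference batch {reference_batch!r} not among {batches}")
    counts = matrix.batches.value_counts()
    tiny = counts[counts < 2].index.tolist()
    if tiny:
        raise ValidationError(f"batches with a single sample (variance undefined): {tiny}")

    dat = matrix.values.to_numpy(dtype=float)
    genes = matrix.genes
    sample_batch = matrix.batches.to_numpy()

    ref_cols = np.flatnonzero(sample_batch == reference_batch)
    if reference_samples is not None:
        wanted = set(reference_samples)
        std_cols = np.array([i for i in ref_cols if matrix.samples[i] in wanted])
        if len(std_cols) < 2:
            raise ConfigurationError(
                "reference-sample mask must select >= 2 samples of the reference batch")
    else:
        std_cols = ref_cols

    ref_block = dat[:, std_cols]
    grand_mean = ref_block.mean(axis=1)
    # 1/n residual variance of the reference samples about their own mean
    pooled_var = ref_block.var(axis=1, ddof=0)
    if np.any(pooled_var <= 0):
        flat = genes[pooled_var <= 0].tolist()
        raise ValidationError(f"zero-variance genes in the reference batch: {flat[:10]}")

    scale = np.sqrt(pooled_var)
    sdat = (dat - grand_mean[:, None]) / scale[:, None]

    adjusted = dat.copy()
    gamma_hat_all, delta_hat_all, gamma_star_all, delta_star_all, hyper_rows = {}, {}, {}, {}, {}
    for batch in batches:
        if batch == reference_batch:
            continue
        cols = np.flatnonzero(sample_batch == batch)
        block = sdat[:, cols]
        gamma_hat = block.mean(axis=1)
        delta_hat = block.var(axis=1, ddof=1)
        gamma_star, delta_star, hyper = _shrink_batch(gamma_hat, delta_hat, block)
        adjusted[:, cols] = ((block - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]
                             * scale[:, None] + grand_mean[:, None])
        gamma_hat_all[batch] = gamma_hat
        delta_hat_all[batch] = delta_hat
        gamma_star_all[batch] = gamma_star
        delta_star_all[batch] = delta_star
        hyper_rows[batch] = hyper

    model = BatchModel(
        reference_batch=reference_batch,
        grand_mean=pd.Series(grand_mean, index=genes),
        pooled_var=pd.Series(pooled_var, index=genes),
        gamma_hat=pd.DataFrame(gamma_hat_all, index=genes),
        delta_hat=pd.DataFrame(delta_hat_all, index=genes),
        gamma_star=pd.DataFrame(gamma_star_all, index=genes),
        delta_star=pd.DataFrame(delta_star_all, index=genes),
        hyperparameters=pd.DataFrame(hyper_rows).T,
        reference_samples=[matrix.samples[i] for i in std_cols],
    )
    out = matrix.with_values(pd.DataFrame(adjusted, index=genes, columns=matrix.samples),
                             state="corrected")
    return out, model


def apply_batch_model(matrix: ExpressionMatrix, model: BatchModel) -> ExpressionMatrix:
    """Correct a new cohort against a previously fitted reference.

    Each batch of ``matrix`` absent from the fitted model is standardized
    with the model's reference parameters and shrunk with a fresh
    empirical-Bayes fit; the model's stored reference scale is reused so the
    output lives on the locked reference scale.
    """
    if matrix.state != "ranked":
        raise ValidationError(f"apply_batch_model expects state 'ranked', got {matrix.state!r}")
    genes = model.grand_mean.index
    missing = genes.difference(matrix.genes)
    if len(missing):
        raise ValidationError(f"cohort lacks genes required by the batch model: {list(missing[:10])}")
    dat = matrix.values.loc[genes].to_numpy(dtype=float)
    grand_mean = model.grand_mean.to_numpy()
    scale = np.sqrt(model.pooled_var.to_numpy())
    sdat = (dat - grand_mean[:, None]) / scale[:, None]
    adjusted = dat.copy()
    sample_batch = matrix.batches.to_numpy()
    for batch in pd.unique(sample_batch):
        cols = np.flatnonzero(sample_batch == batch)
        if len(cols) < 2:
            raise ValidationError(f"batch {batch!r} has a single sample")
        block = sdat[:, cols]
        gamma_star, delta_star, _ = _shrink_batch(block.mean(axis=1), block.var(axis=1, ddof=1),
                                                  block)
        adjusted[:, cols] = ((block - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]
                             * scale[:, None] + grand_mean[:, None])
    out = ExpressionMatrix(pd.DataFrame(adjusted, index=genes, columns=matrix.samples),
                           matrix.batches.copy(), state="corrected")
    return out
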