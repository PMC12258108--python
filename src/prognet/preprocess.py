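"""Batch-effect removal and per-gene standardization.

Batch removal fits, per gene, an ordinary least-squares model with an
intercept, the (protected) class covariate when available, and sum-to-zero
batch terms, then subtracts only the fitted batch contribution.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    PHENO_BATCH,
    PHENO_CLASS,
    ExpressionMatrix,
    PhenotypeTable,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class BatchModel:
    """Per-gene additive batch coefficients (sum to zero across levels)."""

    levels: tuple[str, ...]
    coefficients: pd.DataFrame  # genes x levels

    def __post_init__(self) -> None:
        sums = self.coefficients.to_numpy().sum(axis=1)
        if not np.allclose(sums, 0.0, atol=1e-8):
            raise ValidationError("batch coefficients do not sum to zero")


def remove_batch(expr: ExpressionMatrix,
                 pheno: PhenotypeTable) -> tuple[ExpressionMatrix, BatchModel]:
    """Subtract additive batch effects while preserving class-associated signal."""
    df = pheno.data.loc[expr.samples]
    if PHENO_BATCH not in df:
        raise ValidationError("remove_batch requires a batch column")
    batch = df[PHENO_BATCH].astype(str)
    levels = sorted(batch.unique())
    if len(levels) < 2:
        raise ValidationError("remove_batch requires >= 2 batch levels")
    counts = batch.value_counts()
    small = [lv for lv in levels if counts[lv] < 2]
    if small:
        raise ValidationError(f"batch level(s) with < 2 samples: {small}")

    n = expr.n_samples
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    if PHENO_CLASS in df and not df[PHENO_CLASS].isna().any():
        cols.append(df[PHENO_CLASS].to_numpy(dtype=float))
        names.append("class")
    # sum-to-zero (deviation) coding: last level = -sum of the others
    for lv in levels[:-1]:
        c = np.where(batch.to_numpy() == lv, 1.0, 0.0)
        c[batch.to_numpy() == levels[-1]] = -1.0
        cols.append(c)
        names.append(f"batch[{lv}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(
            "batch design is rank-deficient (batch aliased with class/intercept); "
            f"columns: {names}"
        )

    Y = expr.values  # genes x samples
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (n_cols, genes)
    n_batch = len(levels) - 1
    batch_beta = beta[-n_batch:, :]  # (levels-1, genes)
    batch_cols = X[:, -n_batch:]  # (samples, levels-1)
    fitted_batch = batch_cols @ batch_beta  # (samples, genes)
    corrected = ExpressionMatrix(
        pd.DataFrame(Y - fitted_batch.T, index=expr.genes, columns=expr.samples)
    )
    coef = np.vstack([batch_beta, -batch_beta.sum(axis=0, keepdims=True)]).T
    model = BatchModel(tuple(levels),
                       pd.DataFrame(coef, index=expr.genes, columns=levels))
    logger.info("remove_batch: corrected %d genes across %d batch levels",
                expr.n_genes, len(levels))
    return corrected, model


def standardize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each gene row to mean 0, sample SD 1 (n-1 denominator).

    Constant genes become all-zero rows with a warning.
    """
    if expr.n_samples < 2:
        raise ValidationError("standardize requires >= 2 samples")
    vals = expr.values
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    const = sd[:, 0] == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant gene(s) standardized to all-zero rows",
            UserWarning, stacklevel=2,
        )
    sd_safe = np.where(sd == 0, 1.0, sd)
    out = (vals - mu) / sd_safe
    out[const, :] = 0.0
    return ExpressionMatrix(pd.DataFrame(out, index=expr.genes, columns=expr.samples))


def standardize_array(vals: np.ndarray) -> np.ndarray:
    """Row-standardize a raw array (same rule as :func:`standardize`, no warning)."""
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    const = sd[:, 0] == 0
    sd_safe = np.where(sd == 0, 1.0, sd)
    out = (vals - mu) / sd_safe
    out[const, :] = 0.0
    return out
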