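"""Network-smoothed t-statistic feature selection.

Per-gene two-sample t-statistics are propagated over a gene network with a
p-step random-walk kernel ``K = (a*I - L)^p`` built from the symmetrically
normalized graph Laplacian ``L = I - D^{-1/2} A D^{-1/2}``.  Genes are
ranked by the smoothed absolute statistic and gated by absolute
log-fold-change before entering the classifier.

For ``a >= 2`` the kernel is symmetric positive semi-definite (the
Laplacian spectrum lies in [0, 2]) and entrywise non-negative, so raising a
gene's |t| can never lower its own smoothed score.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    PHENO_CLASS,
    ExpressionMatrix,
    GeneList,
    GeneNetwork,
    PhenotypeTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_A = 2.0
DEFAULT_P = 3
DEFAULT_TOP_FRAC = 0.1
DEFAULT_MIN_ABS_LOGFC = 0.5


def t_and_logfc(values: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t and class-mean difference per gene row.

    Sign convention: positive t / logfc = higher in the poor-prognosis
    (-1) class.  Genes with zero pooled variance get t = 0.
    """
    y = np.asarray(y)
    neg = y == -1
    pos = y == 1
    n1, n2 = int(neg.sum()), int(pos.sum())
    if n1 < 2 or n2 < 2:
        raise ValidationError(f"both classes need >= 2 samples (got {n1}, {n2})")
    m1 = values[:, neg].mean(axis=1)
    m2 = values[:, pos].mean(axis=1)
    v1 = values[:, neg].var(axis=1, ddof=1)
    v2 = values[:, pos].var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    logfc = m1 - m2
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    zero = denom == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} gene(s) with zero pooled variance: t set to 0",
                      UserWarning, stacklevel=2)
    t = np.where(zero, 0.0, logfc / np.where(zero, 1.0, denom))
    return t, logfc


def differential_stats(expr: ExpressionMatrix, pheno: PhenotypeTable) -> pd.DataFrame:
    """Per-gene t statistic and logFC; index = gene, columns = t, logfc."""
    y = pheno.class_vector(expr.samples)
    t, logfc = t_and_logfc(expr.values, y)
    return pd.DataFrame({"t": t, "logfc": logfc}, index=pd.Index(expr.genes, name="gene"))


@dataclass
class RandomWalkKernel:
    """Dense p-step random-walk kernel over a fixed gene order."""

    genes: tuple[str, ...]
    a: float
    p: int
    K: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.genes)
        if self.K.shape != (n, n):
            raise ValidationError("kernel shape does not match gene count")


def build_kernel(net: GeneNetwork, a: float = DEFAULT_A, p: int = DEFAULT_P) -> RandomWalkKernel:
    """Construct K = (a*I - L)^p on the network's (sorted) gene order.

    ``a < 2`` is rejected: the positive semi-definiteness guarantee would be
    lost.  Isolated nodes have a zero normalized-adjacency row, so their
    kernel diagonal is ``(a-1)^p`` and smoothing leaves them unmixed.
    """
    if a < 2:
        raise ValueError(f"kernel offset a must be >= 2 (got {a})")
    if p < 0 or int(p) != p:
        raise ValueError(f"step count p must be a non-negative integer (got {p})")
    genes = tuple(sorted(net.graph.nodes))
    A = nx.to_numpy_array(net.graph, nodelist=genes, weight="weight")
    deg = A.sum(axis=1)
    dinv = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    A_hat = A * dinv[:, None] * dinv[None, :]
    M = (a - 1.0) * np.eye(len(genes)) + A_hat  # a*I - L with L = I - A_hat
    K = np.linalg.matrix_power(M, int(p))
    return RandomWalkKernel(genes, float(a), int(p), K)


def smooth_scores(stats: pd.DataFrame, kernel: RandomWalkKernel,
                  min_abs_logfc: float | None = None) -> pd.DataFrame:
    """Smooth |t| with the kernel; rescale to [0, 1]; rank descending.

    Ties are broken alphabetically by gene symbol.  Returns a table indexed
    by gene with columns t, logfc, abs_t, smoothed, rank (and passed_logfc
    when ``min_abs_logfc`` is given).
    """
    if set(stats.index) != set(kernel.genes):
        extra = sorted(set(stats.index) ^ set(kernel.genes))
        raise ValidationError(f"stats/kernel gene sets differ (e.g. {extra[:5]})")
    stats = stats.loc[list(kernel.genes)]
    abs_t = stats["t"].abs().to_numpy()
    s = kernel.K @ abs_t
    smax = s.max() if len(s) else 0.0
    if smax > 0:
        s = s / smax
    else:
        warnings.warn("all-zero t vector: every smoothed score is 0 and ranks are tied",
                      UserWarning, stacklevel=2)
    genes = np.asarray(kernel.genes)
    order = np.lexsort((genes, -s))  # primary: -score, secondary: gene symbol
    rank = np.empty(len(genes), dtype=int)
    rank[order] = np.arange(1, len(genes) + 1)
    out = pd.DataFrame(
        {"t": stats["t"].to_numpy(), "logfc": stats["logfc"].to_numpy(),
         "abs_t": abs_t, "smoothed": s, "rank": rank},
        index=pd.Index(kernel.genes, name="gene"),
    )
    if min_abs_logfc is not None:
        out["passed_logfc"] = out["logfc"].abs() >= min_abs_logfc
    return out


def select_signature(scores: pd.DataFrame, top_frac: float = DEFAULT_TOP_FRAC,
                     min_abs_logfc: float = DEFAULT_MIN_ABS_LOGFC,
                     label: str = "signature") -> GeneList:
    """Top-ranked genes that also pass the |logFC| gate, ordered by rank."""
    if not 0 < top_frac <= 1:
        raise ValueError(f"top_frac must be in (0, 1] (got {top_frac})")
    if min_abs_logfc < 0:
        raise ValueError(f"min_abs_logfc must be >= 0 (got {min_abs_logfc})")
    cut = math.ceil(top_frac * len(scores))
    sel = scores[(scores["rank"] <= cut) & (scores["logfc"].abs() >= min_abs_logfc)]
    sel = sel.sort_values("rank")
    if sel.empty:
        warnings.warn("signature selection returned no genes", UserWarning, stacklevel=2)
    return GeneList(sel.index, label=label)


def rank_genes(abs_t: np.ndarray, genes: np.ndarray, K: np.ndarray | None = None) -> np.ndarray:
    """Indices of genes ordered best-first by (smoothed) |t|; K=None means raw.

    Internal fast path shared with cross-validation; ties alphabetical.
    """
    s = abs_t if K is None else K @ abs_t
    return np.lexsort((genes, -s))
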