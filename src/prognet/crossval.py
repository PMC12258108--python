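"""Repeated stratified k-fold cross-validation of the selector + linear SVM.

Feature selection (t-statistics, kernel smoothing, logFC gate) happens
inside each training fold only; the held-out fold is scored with the
decision values of a linear maximum-margin classifier trained on the
selected genes, and performance is summarized as the median rank-based AUC
over all repeats x folds.
"""
from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datatypes import (
    ExpressionMatrix,
    GeneList,
    GeneNetwork,
    PhenotypeTable,
    ValidationError,
)
from .preprocess import standardize_array
from .smoothing import (
    DEFAULT_A,
    DEFAULT_MIN_ABS_LOGFC,
    DEFAULT_P,
    DEFAULT_TOP_FRAC,
    build_kernel,
    rank_genes,
    t_and_logfc,
)

logger = logging.getLogger(__name__)


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney U / (n+ * n-)); ties contribute 1/2.

    Positive class is +1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class SelectorParams:
    """Configuration of the in-fold selector and classifier."""

    a: float = DEFAULT_A
    p: int = DEFAULT_P
    top_frac: float = DEFAULT_TOP_FRAC
    min_abs_logfc: float = DEFAULT_MIN_ABS_LOGFC
    C: float = 1.0
    use_network: bool = True  # False = raw-|t| baseline


@dataclass
class FoldRecord:
    repeat: int
    fold: int
    genes: tuple[str, ...]
    auc: float


@dataclass
class CrossValResult:
    repeats: int
    folds: int
    seed: int
    params: SelectorParams
    per_fold: list[FoldRecord]

    @property
    def aucs(self) -> np.ndarray:
        return np.array([f.auc for f in self.per_fold])

    @property
    def median_auc(self) -> float:
        return float(np.median(self.aucs))

    def to_dict(self) -> dict:
        return {
            "repeats": self.repeats,
            "folds": self.folds,
            "seed": self.seed,
            "params": asdict(self.params),
            "median_auc": self.median_auc,
            "per_fold": [
                {"repeat": f.repeat, "fold": f.fold, "auc": f.auc,
                 "genes": list(f.genes)}
                for f in self.per_fold
            ],
        }

    def to_json(self, path, min_freq: float = 0.5) -> None:
        payload = self.to_dict()
        payload["consensus"] = {
            "min_freq": min_freq,
            "genes": list(consensus(self, min_freq)),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_cv(expr: ExpressionMatrix, pheno: PhenotypeTable, net: GeneNetwork,
           params: SelectorParams | None = None, repeats: int = 10,
           folds: int = 5, seed: int = 0) -> CrossValResult:
    """Nested CV: selection and training see only the training fold.

    Inputs are expected to be harmonized (same genes in ``expr`` and
    ``net``, samples aligned with ``pheno``).  Per-fold the training data
    are row-standardized with training-fold statistics, so the logFC gate
    operates in within-fold SD units.
    """
    params = params or SelectorParams()
    y = pheno.class_vector(expr.samples)
    n1, n2 = int((y == -1).sum()), int((y == 1).sum())
    if min(n1, n2) < folds:
        raise ValidationError(f"each class needs >= {folds} samples (got {n1}, {n2})")

    kernel = build_kernel(net, params.a, params.p) if params.use_network else None
    gene_order = tuple(sorted(net.graph.nodes)) if kernel is None else kernel.genes
    if set(gene_order) != set(expr.genes):
        raise ValidationError("expression and network gene sets differ; run harmonize first")
    X = expr.subset(genes=list(gene_order)).values
    genes_arr = np.asarray(gene_order)
    K = kernel.K if kernel is not None else None

    states = np.random.SeedSequence(seed).generate_state(repeats)
    per_fold: list[FoldRecord] = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(states[r]))
        for f, (tr, te) in enumerate(skf.split(X.T, y)):
            genes_sel, dec = fit_fold(X, y, tr, te, genes_arr, K, params)
            if dec is None:
                warnings.warn(f"repeat {r} fold {f}: empty signature, AUC set to 0.5",
                              UserWarning, stacklevel=2)
                per_fold.append(FoldRecord(r, f, (), 0.5))
            else:
                per_fold.append(FoldRecord(r, f, genes_sel, auc_score(dec, y[te])))
    return CrossValResult(repeats, folds, seed, params, per_fold)


def fit_fold(X: np.ndarray, y: np.ndarray, tr: np.ndarray, te: np.ndarray,
             genes_arr: np.ndarray, K: np.ndarray | None,
             params: SelectorParams) -> tuple[tuple[str, ...], np.ndarray | None]:
    """Select and train on the training fold only; score the held-out fold.

    Returns the selected gene tuple and the test-fold decision values
    (``None`` when the signature is empty).  Test-fold labels are never
    read, which the leak-freedom test asserts directly.
    """
    cut = math.ceil(params.top_frac * len(genes_arr))
    mu = X[:, tr].mean(axis=1, keepdims=True)
    sd = X[:, tr].std(axis=1, ddof=1, keepdims=True)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[(sd == 0)[:, 0], :] = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        t, logfc = t_and_logfc(Z[:, tr], y[tr])
    order = rank_genes(np.abs(t), genes_arr, K)
    top = order[:cut]
    sel = top[np.abs(logfc[top]) >= params.min_abs_logfc]
    if sel.size == 0:
        return (), None
    clf = SVC(kernel="linear", C=params.C)
    clf.fit(Z[sel][:, tr].T, y[tr])
    dec = clf.decision_function(Z[sel][:, te].T)
    return tuple(genes_arr[sel]), dec


def consensus(result: CrossValResult, min_freq: float = 0.5) -> GeneList:
    """Genes selected in >= ``min_freq`` of folds, by frequency then name."""
    if not 0 < min_freq <= 1:
        raise ValueError(f"min_freq must be in (0, 1] (got {min_freq})")
    n_folds = len(result.per_fold)
    counts: dict[str, int] = {}
    for rec in result.per_fold:
        for g in rec.genes:
            counts[g] = counts.get(g, 0) + 1
    kept = [(g, c) for g, c in counts.items() if c / n_folds >= min_freq]
    kept.sort(key=lambda gc: (-gc[1], gc[0]))
    if not kept:
        warnings.warn("consensus signature is empty", UserWarning, stacklevel=2)
    return GeneList([g for g, _ in kept], label=f"consensus>= {min_freq:g}")
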