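"""Co-expression modules: soft-threshold scan, topological overlap, clustering.

The adjacency is unsigned, ``a_ij = |cor(x_i, x_j)|^beta``.  The soft
threshold is the smallest power whose signed scale-free fit index reaches
the cut.  Modules come from average-linkage clustering of ``1 - TOM`` with
a static cut; labels follow the conventional color order (largest module =
turquoise, unassigned = grey).  Module eigengenes are the first principal
component of the standardized module submatrix, sign-oriented so the mean
correlation with member genes is non-negative.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .datatypes import ExpressionMatrix, GeneNetwork, PhenotypeTable, ValidationError
from .preprocess import standardize_array

logger = logging.getLogger(__name__)

GREY = "grey"
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white",
)

DEFAULT_BETAS = tuple(range(1, 21))
DEFAULT_R2_CUT = 0.85
DEFAULT_CUT_HEIGHT = 0.8
DEFAULT_MIN_SIZE = 10
N_BINS = 10


def _abs_cor(expr: ExpressionMatrix) -> np.ndarray:
    vals = expr.values
    if (vals.std(axis=1) == 0).any():
        bad = [g for g, s in zip(expr.genes, vals.std(axis=1)) if s == 0]
        raise ValidationError(f"constant gene rows (remove or standardize first): {bad[:5]}")
    C = np.corrcoef(vals)
    np.clip(np.abs(C), 0.0, 1.0, out=C)
    return C


def scale_free_fit(k: np.ndarray, n_bins: int = N_BINS) -> float:
    """Signed R^2 of log10 p(k) on log10 k over equal-width connectivity bins.

    Sign convention: a decreasing degree distribution (the scale-free law)
    yields a positive index, so the index is ``-sign(slope) * R^2``.
    """
    k = np.asarray(k, dtype=float)
    counts, edges = np.histogram(k, bins=n_bins)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        if counts[b] == 0:
            continue
        mean_k = k[which == b].mean()
        p = counts[b] / k.size
        if mean_k <= 0 or p <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(p))
    if len(xs) < 2:
        return 0.0
    fit = linregress(xs, ys)
    return float(-np.sign(fit.slope) * fit.rvalue ** 2)


@dataclass
class SoftThresholdScan:
    betas: tuple[int, ...]
    fit_r2: tuple[float, ...]
    mean_k: tuple[float, ...]
    chosen_beta: int


def scan_soft_threshold(expr: ExpressionMatrix,
                        betas: tuple[int, ...] = DEFAULT_BETAS,
                        r2_cut: float = DEFAULT_R2_CUT) -> SoftThresholdScan:
    """Pick the smallest power reaching the scale-free fit cut (else argmax)."""
    if expr.n_genes < 20:
        raise ValidationError("soft-threshold scan needs >= 20 genes")
    C = _abs_cor(expr)
    np.fill_diagonal(C, 0.0)
    fits, ks = [], []
    for beta in betas:
        A = C ** beta
        k = A.sum(axis=1)
        fits.append(scale_free_fit(k))
        ks.append(float(k.mean()))
    chosen = None
    for beta, fit in zip(betas, fits):
        if fit >= r2_cut:
            chosen = beta
            break
    if chosen is None:
        chosen = betas[int(np.argmax(fits))]
        warnings.warn(
            f"no power reached fit cut {r2_cut:g}; falling back to argmax beta={chosen}",
            UserWarning, stacklevel=2,
        )
    return SoftThresholdScan(tuple(betas), tuple(fits), tuple(ks), int(chosen))


def tom_matrix(expr: ExpressionMatrix, beta: int) -> tuple[list[str], np.ndarray]:
    """Unsigned topological overlap matrix over the matrix's gene order."""
    if beta < 1:
        raise ValueError(f"beta must be >= 1 (got {beta})")
    A = _abs_cor(expr) ** beta
    np.fill_diagonal(A, 0.0)
    L = A @ A  # l_ij = sum_u a_iu a_uj; u = i, j terms vanish with zero diagonal
    k = A.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - A
    T = (L + A) / denom
    np.fill_diagonal(T, 1.0)
    np.clip(T, 0.0, 1.0, out=T)
    return expr.genes, T


def tom(expr: ExpressionMatrix, beta: int) -> GeneNetwork:
    """TOM as a weighted gene network (zero-overlap pairs carry no edge)."""
    genes, T = tom_matrix(expr, beta)
    g = nx.Graph()
    g.add_nodes_from(genes)
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu, ju):
        w = T[i, j]
        if w > 0:
            g.add_edge(genes[i], genes[j], weight=float(w))
    return GeneNetwork(g)


@dataclass
class ModuleSet:
    """Gene -> module assignment with eigengenes and optional trait correlations."""

    assignment: pd.Series  # index gene, value module label
    eigengenes: pd.DataFrame  # samples x modules (unit-norm columns)
    trait_cor: pd.DataFrame | None = None  # modules x traits (Pearson r)
    trait_p: pd.DataFrame | None = None

    @property
    def modules(self) -> list[str]:
        return list(self.eigengenes.columns)

    def genes_in(self, module: str) -> list[str]:
        return list(self.assignment.index[self.assignment == module])


def module_eigengene(expr: ExpressionMatrix, genes: list[str]) -> pd.Series:
    """First principal component across a module's genes; unit norm, sign-oriented."""
    sub = standardize_array(expr.subset(genes=genes).values)
    _, _, vt = np.linalg.svd(sub, full_matrices=False)
    e = vt[0]
    # orient: mean correlation with member expression >= 0
    cors = []
    for row in sub:
        s = row.std()
        if s > 0:
            cors.append(np.corrcoef(e, row)[0, 1])
    if cors and np.mean(cors) < 0:
        e = -e
    return pd.Series(e, index=expr.samples)


def detect_modules(tomnet: GeneNetwork, expr: ExpressionMatrix,
                   cut_height: float = DEFAULT_CUT_HEIGHT,
                   min_size: int = DEFAULT_MIN_SIZE) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters below ``min_size`` are relabeled grey; surviving clusters get
    color labels by decreasing size.
    """
    if not 0 < cut_height < 1:
        raise ValueError(f"cut_height must be in (0, 1) (got {cut_height})")
    genes = sorted(tomnet.graph.nodes)
    T = nx.to_numpy_array(tomnet.graph, nodelist=genes, weight="weight")
    np.fill_diagonal(T, 1.0)
    D = 1.0 - T
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for g, c in zip(genes, raw):
        clusters.setdefault(int(c), []).append(g)
    big = [members for members in clusters.values() if len(members) >= min_size]
    big.sort(key=lambda m: (-len(m), min(m)))
    labels = {}
    for i, members in enumerate(big):
        color = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
        for g in members:
            labels[g] = color
    assignment = pd.Series([labels.get(g, GREY) for g in genes],
                           index=pd.Index(genes, name="gene"), name="module")
    eig = {}
    for i, members in enumerate(big):
        color = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
        eig[color] = module_eigengene(expr, members)
    eigengenes = pd.DataFrame(eig, index=pd.Index(expr.samples, name="sample"))
    logger.info("detect_modules: %d module(s), %d gene(s) grey",
                len(big), int((assignment == GREY).sum()))
    return ModuleSet(assignment, eigengenes)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided p from the t transform with n-2 df."""
    from scipy.stats import t as t_dist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValidationError("correlation needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("constant vector in correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    r_c = min(max(r, -1.0), 1.0)
    if abs(r_c) == 1.0:
        return r_c, 0.0
    stat = r_c * np.sqrt((n - 2) / (1.0 - r_c ** 2))
    p = float(2.0 * t_dist.sf(abs(stat), n - 2))
    return r_c, p


def module_trait(modules: ModuleSet, pheno: PhenotypeTable,
                 traits: list[str]) -> ModuleSet:
    """Pearson correlation of each eigengene with each (numeric) trait column."""
    samples = list(modules.eigengenes.index)
    df = pheno.data.loc[samples]
    r_tab = pd.DataFrame(index=modules.modules, columns=traits, dtype=float)
    p_tab = pd.DataFrame(index=modules.modules, columns=traits, dtype=float)
    for trait in traits:
        if trait not in df:
            raise ValidationError(f"trait {trait!r} not in phenotype table")
        vec = pd.to_numeric(df[trait], errors="raise").to_numpy(dtype=float)
        if np.std(vec) == 0:
            warnings.warn(f"trait {trait!r} is constant; correlation undefined",
                          UserWarning, stacklevel=2)
            continue
        for mod in modules.modules:
            r, p = pearson_with_p(modules.eigengenes[mod].to_numpy(), vec)
            r_tab.loc[mod, trait] = r
            p_tab.loc[mod, trait] = p
    return replace(modules, trait_cor=r_tab, trait_p=p_tab)
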