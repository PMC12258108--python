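"""Shared data model: expression matrices, phenotype tables, gene networks, gene lists.

All downstream stages consume these containers; the loaders in
:mod:`prognet.io` construct them and are the only place format quirks are
handled.  Construction validates invariants eagerly so pipeline code can
assume clean inputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input violates a data-model invariant."""


PHENO_CLASS = "class"
PHENO_TIME = "time"  # canonical unit: days
PHENO_EVENT = "event"
PHENO_BATCH = "batch"

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix with unique gene and sample identifiers."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        try:
            self.data = self.data.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric expression values: {exc}") from exc
        if self.data.isna().any().any():
            gene = self.data.index[self.data.isna().any(axis=1)][0]
            sample = self.data.columns[self.data.isna().any(axis=0)][0]
            raise ValidationError(
                f"missing expression value (first at gene {gene!r}, sample {sample!r})"
            )
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset(self, genes: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "ExpressionMatrix":
        df = self.data
        if genes is not None:
            missing = [g for g in genes if g not in df.index]
            if missing:
                raise ValidationError(f"genes not in matrix: {missing[:5]}")
            df = df.loc[list(genes)]
        if samples is not None:
            missing = [s for s in samples if s not in df.columns]
            if missing:
                raise ValidationError(f"samples not in matrix: {missing[:5]}")
            df = df[list(samples)]
        return ExpressionMatrix(df.copy())


@dataclass
class PhenotypeTable:
    """Per-sample class label, survival time (days), event indicator, batch.

    All columns except the sample index are optional; operations state their
    own column requirements.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = sorted(set(self.data.index[self.data.index.duplicated()]))
            raise ValidationError(f"duplicate sample ids in phenotype: {dups[:5]}")
        self.data.index = self.data.index.astype(str)
        df = self.data
        if PHENO_CLASS in df:
            cls = df[PHENO_CLASS].dropna()
            bad = set(cls.unique()) - {-1, 1, -1.0, 1.0}
            if bad:
                raise ValidationError(f"class labels must be -1/+1, got {sorted(bad)[:5]}")
            df[PHENO_CLASS] = df[PHENO_CLASS].astype("Int64")
        if PHENO_EVENT in df:
            ev = df[PHENO_EVENT].dropna()
            bad = set(ev.unique()) - {0, 1, 0.0, 1.0}
            if bad:
                raise ValidationError(f"event indicator must be 0/1, got {sorted(bad)[:5]}")
            df[PHENO_EVENT] = df[PHENO_EVENT].astype("Int64")
        if PHENO_TIME in df:
            t = pd.to_numeric(df[PHENO_TIME], errors="raise")
            if (t.dropna() < 0).any():
                raise ValidationError("negative survival time")
            df[PHENO_TIME] = t.astype(float)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def subset(self, samples: Sequence[str]) -> "PhenotypeTable":
        missing = [s for s in samples if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples not in phenotype: {missing[:5]}")
        return PhenotypeTable(self.data.loc[list(samples)].copy())

    def class_vector(self, samples: Sequence[str] | None = None) -> np.ndarray:
        if PHENO_CLASS not in self.data:
            raise ValidationError("phenotype has no class column")
        col = self.data[PHENO_CLASS]
        if samples is not None:
            col = col.loc[list(samples)]
        if col.isna().any():
            raise ValidationError("missing class labels")
        return col.to_numpy(dtype=int)


@dataclass
class GeneNetwork:
    """Undirected weighted graph on gene symbols (no self-loops, w >= 0)."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        g = self.graph
        loops = list(nx.selfloop_edges(g))
        if loops:
            raise ValidationError(f"self-loops present: {loops[:5]}")
        for u, v, w in g.edges(data="weight", default=1.0):
            if not np.isfinite(w) or w < 0:
                raise ValidationError(f"edge ({u},{v}) has invalid weight {w}")
            g[u][v]["weight"] = float(w)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_weights(self) -> list[tuple[str, str, float]]:
        """Edges as (u, v, w) with u < v, sorted lexicographically."""
        out = []
        for u, v, w in self.graph.edges(data="weight", default=1.0):
            a, b = sorted((u, v))
            out.append((a, b, float(w)))
        return sorted(out)

    def adjacency(self, nodelist: Sequence[str] | None = None) -> tuple[list[str], np.ndarray]:
        nodes = list(nodelist) if nodelist is not None else self.nodes
        A = nx.to_numpy_array(self.graph, nodelist=nodes, weight="weight")
        return nodes, A


@dataclass
class GeneList:
    """Ordered unique gene symbols with a free-text label."""

    genes: tuple[str, ...]
    label: str = ""

    def __init__(self, genes: Iterable[str], label: str = "") -> None:
        genes = tuple(str(g) for g in genes)
        seen = set()
        for g in genes:
            if g in seen:
                raise ValidationError(f"duplicate gene in list: {g!r}")
            seen.add(g)
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "label", label)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: object) -> bool:
        return gene in self.genes
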