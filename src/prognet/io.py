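"""Readers/writers plus sample/gene harmonization and survival dichotomization.

File conventions
----------------
* Expression: TSV/CSV with a header row; first column holds gene ids
  (``genes_rows`` orientation) or sample ids (``samples_rows``).
* Phenotype: TSV with a ``sample`` id column plus any of ``class``,
  ``time``/``time_days``/``time_months``/``time_years``, ``event``, ``batch``.
  Time is converted to days internally.
* Network: headerless edge-list TSV ``geneA<TAB>geneB[<TAB>weight]``.
* Gene lists: one symbol per line; GMT accepted for named sets.
"""
from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

from .datatypes import (
    DAYS_PER_MONTH,
    DAYS_PER_YEAR,
    PHENO_BATCH,
    PHENO_CLASS,
    PHENO_EVENT,
    PHENO_TIME,
    ExpressionMatrix,
    GeneList,
    GeneNetwork,
    PhenotypeTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


class ParseError(ValueError):
    """A file could not be parsed into the data model."""


def _sep_for(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path: str | Path, orientation: str = "genes_rows",
                    impute: str | None = None, sep: str | None = None) -> ExpressionMatrix:
    """Load an expression matrix.

    Duplicate gene rows are collapsed by keeping the row with the highest
    mean expression (logged).  Missing cells raise unless ``impute='mean'``
    (per-gene mean).  Duplicate sample ids are an error.
    """
    if orientation not in ("genes_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    use_sep = _sep_for(path, sep)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(use_sep)[1:]
    if len(header) != len(set(header)):  # pandas would mangle these to s1.1 etc.
        dups = sorted({h for h in header if header.count(h) > 1})
        what = "sample" if orientation == "genes_rows" else "gene"
        raise ParseError(f"duplicate {what} ids in header: {dups[:5]}")
    raw = pd.read_csv(path, sep=use_sep, index_col=0, dtype=str,
                      keep_default_na=False, na_values=["", "NA", "NaN", "nan"])
    probe = raw.apply(pd.to_numeric, errors="coerce")
    malformed = probe.isna() & raw.notna()
    if malformed.any().any():
        r = malformed.any(axis=1).idxmax()
        c = malformed.columns[malformed.loc[r].to_numpy().argmax()]
        raise ParseError(
            f"malformed numeric cell at row {r!r}, column {c!r}: {raw.loc[r, c]!r}"
        )
    # exact IEEE round-trip: Python's float() parses correctly-rounded,
    # pandas' fast path does not
    num = raw.apply(lambda col: col.map(
        lambda v: np.nan if pd.isna(v) else float(v)))
    if orientation == "samples_rows":
        num = num.T
    num.index = num.index.astype(str)
    num.columns = num.columns.astype(str)
    if num.columns.duplicated().any():
        dups = sorted(set(num.columns[num.columns.duplicated()]))
        raise ParseError(f"duplicate sample ids: {dups[:5]}")
    if num.isna().any().any():
        if impute == "mean":
            n_miss = int(num.isna().sum().sum())
            num = num.apply(lambda row: row.fillna(row.mean()), axis=1)
            logger.info("imputed %d missing cells with per-gene means", n_miss)
            if num.isna().any().any():
                raise ParseError("imputation failed: gene with all values missing")
        elif impute is None:
            mask = num.isna()
            r = mask.any(axis=1).idxmax()
            c = mask.columns[mask.loc[r].to_numpy().argmax()]
            raise ParseError(f"missing value at gene {r!r}, sample {c!r} and imputation is off")
        else:
            raise ValueError(f"unknown impute mode {impute!r}")
    if num.index.duplicated().any():
        dup_genes = sorted(set(num.index[num.index.duplicated()]))
        means = num.mean(axis=1)
        # stable: keep, per gene id, the row of highest mean expression
        order = np.argsort(-means.to_numpy(), kind="stable")
        keep = ~num.index[order].duplicated()
        kept_pos = np.sort(order[keep])
        num = num.iloc[kept_pos]
        msg = f"collapsed {len(dup_genes)} duplicate gene id(s) by max mean expression: {dup_genes[:5]}"
        logger.warning(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
    return ExpressionMatrix(num)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene")


_TIME_COLS = {
    "time": None,
    "time_days": "days",
    "time_months": "months",
    "time_years": "years",
}
_TO_DAYS = {"days": 1.0, "months": DAYS_PER_MONTH, "years": DAYS_PER_YEAR}


def read_phenotype(path: str | Path, time_unit: str | None = None,
                   sep: str | None = None) -> PhenotypeTable:
    """Load the per-sample phenotype table; survival time is canonicalized to days.

    The unit comes from the time column name (``time_days`` etc.); a bare
    ``time`` column uses ``time_unit`` (default days).
    """
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    df.columns = [c.strip().lower() for c in df.columns]
    if "sample" not in df.columns:
        raise ParseError("phenotype table needs a 'sample' column")
    df = df.set_index("sample")
    time_col = [c for c in df.columns if c in _TIME_COLS]
    if len(time_col) > 1:
        raise ParseError(f"multiple time columns: {time_col}")
    if time_col:
        col = time_col[0]
        unit = _TIME_COLS[col] or time_unit or "days"
        if unit not in _TO_DAYS:
            raise ValueError(f"unknown time unit {unit!r}")
        df[PHENO_TIME] = pd.to_numeric(df[col], errors="raise") * _TO_DAYS[unit]
        if col != PHENO_TIME:
            df = df.drop(columns=[col])
    return PhenotypeTable(df)


def write_phenotype(pheno: PhenotypeTable, path: str | Path) -> None:
    df = pheno.data.copy()
    if PHENO_TIME in df:
        df = df.rename(columns={PHENO_TIME: "time_days"})
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="sample")


def read_network(path: str | Path, sep: str | None = None) -> GeneNetwork:
    """Load an undirected edge list; self-loops dropped, duplicates merged by max weight."""
    df = pd.read_csv(path, sep=_sep_for(path, sep), header=None, dtype=str,
                     comment="#", skip_blank_lines=True)
    if df.shape[1] not in (2, 3):
        raise ParseError(f"edge list must have 2 or 3 columns, got {df.shape[1]}")
    g = nx.Graph()
    n_loops = 0
    for row in df.itertuples(index=False):
        u, v = str(row[0]).strip(), str(row[1]).strip()
        if df.shape[1] == 3:
            try:
                w = float(row[2])
            except ValueError as exc:
                raise ParseError(f"malformed weight on edge ({u},{v}): {row[2]!r}") from exc
        else:
            w = 1.0
        if not np.isfinite(w) or w < 0:
            raise ParseError(f"negative or non-finite weight on edge ({u},{v}): {w}")
        if u == v:
            n_loops += 1
            continue
        if g.has_edge(u, v):
            g[u][v]["weight"] = max(g[u][v]["weight"], w)
        else:
            g.add_edge(u, v, weight=w)
    if n_loops:
        logger.info("dropped %d self-loop(s)", n_loops)
    return GeneNetwork(g)


def write_network(net: GeneNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, w in net.edge_weights():
            fh.write(f"{u}\t{v}\t{FLOAT_FMT % w}\n")
        # isolated nodes are re-created by harmonize; edge lists cannot carry them


def read_gene_list(path: str | Path, label: str | None = None) -> GeneList:
    genes: list[str] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            g = line.strip()
            if not g or g.startswith("#"):
                continue
            if g not in seen:
                genes.append(g)
                seen.add(g)
    return GeneList(genes, label=label or Path(path).stem)


def write_gene_list(genes: GeneList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(g + "\n")


def read_gmt(path: str | Path) -> dict[str, GeneList]:
    """GMT: name<TAB>description<TAB>gene1<TAB>gene2..."""
    sets: dict[str, GeneList] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name = parts[0]
            genes = list(dict.fromkeys(g for g in parts[2:] if g))
            sets[name] = GeneList(genes, label=name)
    return sets


def harmonize(expr: ExpressionMatrix, pheno: PhenotypeTable,
              net: GeneNetwork) -> tuple[ExpressionMatrix, PhenotypeTable, GeneNetwork]:
    """Align samples (expr ∩ pheno) and restrict the network to measured genes.

    Genes measured but absent from the network are retained as isolated
    nodes, so smoothing degenerates to the raw statistic for them.
    """
    pheno_samples = set(pheno.samples)
    common = [s for s in expr.samples if s in pheno_samples]
    if not common:
        raise ValidationError("no samples shared between expression and phenotype")
    n_drop_expr = expr.n_samples - len(common)
    n_drop_pheno = len(pheno.samples) - len(common)
    expr2 = expr.subset(samples=common)
    pheno2 = pheno.subset(common)

    expr_genes = set(expr2.genes)
    g = nx.Graph()
    g.add_nodes_from(expr2.genes)
    n_drop_nodes = 0
    for u, v, w in net.graph.edges(data="weight", default=1.0):
        if u in expr_genes and v in expr_genes:
            g.add_edge(u, v, weight=w)
    n_drop_nodes = net.n_nodes - sum(1 for n in net.graph.nodes if n in expr_genes)
    n_isolated = sum(1 for n in g.nodes if g.degree(n) == 0)
    logger.info(
        "harmonize: kept %d samples (dropped %d expr / %d pheno); "
        "dropped %d network gene(s) not measured; %d measured gene(s) isolated",
        len(common), n_drop_expr, n_drop_pheno, n_drop_nodes, n_isolated,
    )
    return expr2, pheno2, GeneNetwork(g)


def dichotomize_survival(pheno: PhenotypeTable, cutoff_years: float = 5.0) -> PhenotypeTable:
    """Assign -1 (event before cutoff) / +1 (followed past cutoff) class labels.

    Samples censored before the cutoff are excluded: their class is
    unknowable.  The exclusion count is logged.
    """
    if cutoff_years <= 0:
        raise ValueError("cutoff_years must be positive")
    df = pheno.data
    if PHENO_TIME not in df or PHENO_EVENT not in df:
        raise ValidationError("dichotomize_survival requires time and event columns")
    cutoff = cutoff_years * DAYS_PER_YEAR
    time = df[PHENO_TIME].to_numpy(dtype=float)
    event = df[PHENO_EVENT].to_numpy(dtype=int)
    poor = (time < cutoff) & (event == 1)
    favorable = time >= cutoff
    excluded = ~(poor | favorable)
    out = df[~excluded].copy()
    out[PHENO_CLASS] = np.where(poor[~excluded], -1, 1)
    if excluded.any():
        logger.info("dichotomize: excluded %d sample(s) censored before the cutoff",
                    int(excluded.sum()))
    return PhenotypeTable(out)
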