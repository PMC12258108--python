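"""Kaplan-Meier curves, median-split grouping, weighted log-rank tests.

The two-group "Wilcoxon" survival test is the Gehan-Breslow-Wilcoxon
weighted log-rank: each distinct event time contributes with weight equal
to the total number at risk, the statistic is
``(sum w_j (O_j - E_j))^2 / sum w_j^2 V_j`` with the hypergeometric
variance ``V_j``, and the p-value comes from chi-square with 1 df.
``w = 1`` recovers the plain log-rank test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, pearsonr, spearmanr, false_discovery_control

from .datatypes import (
    PHENO_EVENT,
    PHENO_TIME,
    ExpressionMatrix,
    PhenotypeTable,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """Product-limit estimate at the ordered distinct event times."""

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function lookup S(t); 1.0 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_fit(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan-Meier estimator; subjects censored at t remain at risk at t."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValidationError("km_fit needs at least one observation")
    if time.shape != event.shape:
        raise ValidationError("time and event lengths differ")
    if (time < 0).any():
        raise ValidationError("negative survival time")
    ev_times = np.unique(time[event == 1])
    at_risk = np.array([(time >= t).sum() for t in ev_times], dtype=int)
    d = np.array([((time == t) & (event == 1)).sum() for t in ev_times], dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / at_risk) if ev_times.size else np.array([])
    return KMCurve(ev_times, at_risk, d, surv)


def median_split(expr: ExpressionMatrix, gene: str) -> pd.Series:
    """High/low sample grouping at the gene's median; ties go to the low group."""
    if gene not in expr.data.index:
        raise ValidationError(f"gene {gene!r} not in expression matrix")
    vals = expr.data.loc[gene]
    med = float(np.median(vals.to_numpy()))
    if vals.nunique() == 1:
        raise ValidationError(f"gene {gene!r} is constant: no median split")
    groups = pd.Series(np.where(vals.to_numpy() > med, "high", "low"),
                       index=vals.index, name=gene)
    logger.info("median_split %s: %d high / %d low", gene,
                int((groups == "high").sum()), int((groups == "low").sum()))
    return groups


@dataclass
class TwoGroupTest:
    statistic: float
    p_value: float
    method: str


def compare_survival(time_a: np.ndarray, event_a: np.ndarray,
                     time_b: np.ndarray, event_b: np.ndarray,
                     method: str = "gehan_wilcoxon") -> TwoGroupTest:
    """Weighted log-rank comparison of two survival samples."""
    if method not in ("gehan_wilcoxon", "logrank"):
        raise ValueError(f"unknown method {method!r}")
    ta = np.asarray(time_a, dtype=float)
    ea = np.asarray(event_a, dtype=int)
    tb = np.asarray(time_b, dtype=float)
    eb = np.asarray(event_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("both groups must be non-empty")
    if ea.sum() + eb.sum() < 1:
        raise ValidationError("at least one observed event is required")
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    group_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])

    num = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_j = int(at_risk.sum())
        n1_j = int((at_risk & group_a).sum())
        d_j = int(((times == t) & (events == 1)).sum())
        d1_j = int(((times == t) & (events == 1) & group_a).sum())
        if n_j == 0:
            continue
        e1_j = d_j * n1_j / n_j
        v_j = 0.0
        if n_j > 1:
            v_j = (d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1))
        w = float(n_j) if method == "gehan_wilcoxon" else 1.0
        num += w * (d1_j - e1_j)
        var += w * w * v_j
    if var <= 0:
        raise ValidationError("zero variance in weighted log-rank test")
    stat = num * num / var
    return TwoGroupTest(float(stat), float(chi2.sf(stat, df=1)), method)


def associate(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> tuple[float, float]:
    """Correlation (Pearson or Spearman) with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("associate needs equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("constant vector in correlation")
    if method == "pearson":
        res = pearsonr(x, y)
    elif method == "spearman":
        res = spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic if hasattr(res, "statistic") else res[0]), \
        float(res.pvalue if hasattr(res, "pvalue") else res[1])


def gene_survival_table(expr: ExpressionMatrix, pheno: PhenotypeTable,
                        genes: list[str], method: str = "gehan_wilcoxon") -> pd.DataFrame:
    """Per-gene median-split survival comparison with a BH-adjusted column."""
    df = pheno.data.loc[expr.samples]
    if PHENO_TIME not in df or PHENO_EVENT not in df:
        raise ValidationError("survival analysis requires time and event columns")
    time = df[PHENO_TIME].to_numpy(dtype=float)
    event = df[PHENO_EVENT].to_numpy(dtype=int)
    rows = []
    for gene in genes:
        groups = median_split(expr, gene)
        hi = (groups == "high").to_numpy()
        test = compare_survival(time[hi], event[hi], time[~hi], event[~hi], method)
        rows.append({"gene": gene, "n_high": int(hi.sum()), "n_low": int((~hi).sum()),
                     "statistic": test.statistic, "p": test.p_value})
    out = pd.DataFrame(rows).set_index("gene")
    out["p_bh"] = false_discovery_control(out["p"].to_numpy(), method="bh")
    return out
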