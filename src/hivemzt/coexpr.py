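"""Pearson-correlation machinery for lncRNA-host and co-expression analyses."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

RELATIONS = ("positive", "negative", "non_correlated")


def pcc(x, y) -> tuple[float, float]:
    """Pearson r and its t-transform p-value; (nan, nan) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need >= 3 paired samples")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def classify_relation(
    r: float, p: float, r_threshold: float = 0.5,
    p_threshold: float | None = 0.05
) -> str:
    """positive / negative / non_correlated from (r, p) thresholds.

    With ``p_threshold`` None the call uses correlation magnitude alone.
    """
    if math.isnan(r):
        return "non_correlated"
    significant = True if p_threshold is None else (p < p_threshold)
    if significant and r >= r_threshold:
        return "positive"
    if significant and r <= -r_threshold:
        return "negative"
    return "non_correlated"


def classify_host_relation(
    lncrna_expr,
    host_expr,
    r_threshold: float = 0.5,
    p_threshold: float | None = 0.05,
) -> str:
    """Relation of an intronic lncRNA's expression to its host gene's."""
    r, p = pcc(lncrna_expr, host_expr)
    return classify_relation(r, p, r_threshold, p_threshold)


def host_relation_table(
    pairs: list[tuple[str, str]],
    expression: pd.DataFrame,
    r_threshold: float = 0.5,
    p_threshold: float | None = 0.05,
) -> pd.DataFrame:
    """Classify a set of (lncRNA, host) feature pairs over one matrix."""
    rows = []
    for lnc, host in pairs:
        r, p = pcc(expression.loc[lnc], expression.loc[host])
        rows.append(
            (lnc, host, r, p, classify_relation(r, p, r_threshold, p_threshold))
        )
    df = pd.DataFrame(
        rows, columns=["lncrna", "host_gene", "r", "p_value", "relation"]
    )
    return df


def coexpression_partners(
    target: str,
    expression: pd.DataFrame,
    r_threshold: float = 0.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Features co-expressed with ``target`` (|r| > r_threshold, p < p_threshold).

    Returns one row per partner with its correlation sign; the negative
    fraction is ``(df.relation == 'negative').mean()``.
    """
    if target not in expression.index:
        raise ValueError(f"{target!r} not in expression matrix")
    tvec = expression.loc[target].values
    if np.ptp(tvec) == 0:
        raise ValueError("target has constant expression")
    rows = []
    for feat in expression.index:
        if feat == target:
            continue
        r, p = pcc(tvec, expression.loc[feat].values)
        if math.isnan(r) or p >= p_threshold or abs(r) <= r_threshold:
            continue
        rows.append((feat, r, p, "positive" if r > 0 else "negative"))
    return pd.DataFrame(rows, columns=["feature", "r", "p_value", "relation"])


def sample_similarity(
    expression: pd.DataFrame, log_transform: bool = True
) -> pd.DataFrame:
    """Sample x sample Pearson correlation matrix (unit diagonal).

    Columns are samples; ``log_transform`` applies log2(x + 1) first.
    Zero-variance samples yield missing off-diagonal values.
    """
    if expression.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    mat = expression.astype(float)
    if log_transform:
        mat = np.log2(mat + 1.0)
    corr = mat.corr(method="pearson")  # pandas leaves NaN for zero variance
    np.fill_diagonal(corr.values, 1.0)
    return corr
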