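"""Univariate association statistics between drug sensitivity and markers.

Welch's unequal-variance t-test compares score means between mutation
groups; Pearson correlations with t-based significance relate protein
readouts to scores (p-values are reported without multiple-testing
adjustment, matching their exploratory role; a Benjamini-Hochberg column is
available for completeness).  Cell-line columns of a score matrix are
clustered with Euclidean distance and Ward linkage, without row scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass(frozen=True)
class GroupComparison:
    label: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class CorrelationEntry:
    drug: str
    analyte: str
    r: float
    n: int
    p: float


def welch_test(a, b, label: str = "") -> GroupComparison:
    """Welch's two-sample t-test (two-sided, Welch-Satterthwaite df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return GroupComparison(label, a.size, b.size, float(a.mean()),
                                   float(b.mean()), 0.0, float(a.size + b.size - 2), 1.0)
        raise ValueError("both group variances are zero")
    se2 = va / a.size + vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = 2.0 * sps.t.sf(abs(t), df)
    return GroupComparison(
        label, int(a.size), int(b.size), float(a.mean()), float(b.mean()),
        float(t), float(df), float(p),
    )


def class_aggregate_test(
    dss_matrix: pd.DataFrame,
    drug_class: list[str],
    group_a: list[str],
    group_b: list[str],
    label: str = "",
    mode: str = "pooled",
) -> GroupComparison:
    """Compare scores between two cell-line groups over a drug class.

    ``mode='pooled'`` pools every drug × cell-line score of the class into
    the two groups (class members treated as exchangeable measurements);
    ``mode='cell-line-mean'`` first averages the class per cell line.
    """
    if not drug_class:
        raise ValueError("drug class is empty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"cell lines in both groups: {sorted(overlap)}")
    sub = dss_matrix.loc[drug_class]
    if mode == "pooled":
        a = sub[group_a].to_numpy().ravel()
        b = sub[group_b].to_numpy().ravel()
    elif mode == "cell-line-mean":
        a = sub[group_a].mean(axis=0).to_numpy()
        b = sub[group_b].mean(axis=0).to_numpy()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    return welch_test(a, b, label=label or "+".join(drug_class))


def pearson_with_p(x, y, drug: str = "", analyte: str = "") -> CorrelationEntry:
    """Pearson r with two-sided t-based p (n - 2 df), unadjusted."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has undefined correlation")
    r, p = sps.pearsonr(x, y)
    return CorrelationEntry(drug=drug, analyte=analyte, r=float(r),
                            n=int(x.size), p=float(p))


def correlation_table(
    readouts: pd.DataFrame, dss_matrix: pd.DataFrame, adjust: bool = False
) -> pd.DataFrame:
    """All analyte × drug Pearson correlations on shared cell lines.

    Optionally appends Benjamini-Hochberg adjusted q-values.
    """
    shared = [c for c in dss_matrix.columns if c in readouts.columns]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared cell lines")
    rows = []
    for analyte in readouts.index:
        x = readouts.loc[analyte, shared].to_numpy(dtype=float)
        for drug in dss_matrix.index:
            y = dss_matrix.loc[drug, shared].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                continue
            e = pearson_with_p(x[ok], y[ok], drug=drug, analyte=analyte)
            rows.append(dict(drug=e.drug, analyte=e.analyte, r=e.r, n=e.n,
                             p=e.p))
    table = pd.DataFrame(rows)
    if adjust and not table.empty:
        table["q_bh"] = _benjamini_hochberg(table["p"].to_numpy())
    return table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


def cluster_cell_lines(dss_matrix: pd.DataFrame):
    """Ward/Euclidean clustering of cell-line columns (no row scaling).

    Returns (ordered column labels, scipy linkage matrix).
    """
    if dss_matrix.shape[1] < 2:
        raise ValueError("need >= 2 columns to cluster")
    cols = dss_matrix.columns
    data = dss_matrix.to_numpy(dtype=float).T
    z = hierarchy.linkage(pdist(data), method="ward")
    order = hierarchy.leaves_list(z)
    return [cols[i] for i in order], z


def sign_consistency(B: pd.DataFrame, correlations: pd.DataFrame) -> float:
    """Fraction of nonzero coefficients matching the marginal correlation sign.

    ``correlations`` must share the index/columns of ``B`` (e.g. analyte ×
    drug Pearson r).  Zero coefficients are excluded.
    """
    B_aligned, r_aligned = B.align(correlations, join="inner")
    b = B_aligned.to_numpy(dtype=float)
    r = r_aligned.to_numpy(dtype=float)
    nz = b != 0
    if not nz.any():
        raise ValueError("no nonzero coefficients")
    return float(np.mean(np.sign(b[nz]) == np.sign(r[nz])))
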