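"""Methylation-expression association statistics.

The tissue-bias score of a gene for a tissue subset *s* (vs the
complement *o*) is

    bias = w_s E_s / (w_s E_s + w_o E_o),
    w_s = max(n_s, n_o)/n_s,  w_o = max(n_s, n_o)/n_o,

with E the summed (linear-scale) expression over each subset; a gene is
"biased" at bias >= 0.9.  Further tools: rank-based expression deciles,
Mann-Whitney comparisons of gene groups, exact two-sided sign tests of
cross-tissue consistency, box-plot summaries of expression by
methylation category, and hierarchical clustering of tissues on
1 - Pearson-correlation distance with complete linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .tissues import GENE_CATEGORIES, GeneMethylationCalls

BIAS_THRESHOLD = 0.9


@dataclass
class RankTestResult:
    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    method: str


def expression_bias(values: pd.Series | np.ndarray, subset_s, tissues=None,
                    ) -> float:
    """Weighted tissue-bias score in [0, 1]; NaN when total expression is 0."""
    if isinstance(values, pd.Series):
        tissues = list(values.index)
        values = values.to_numpy(dtype=float)
    else:
        values = np.asarray(values, dtype=float)
        if tissues is None:
            raise ValueError("tissues required for array input")
    subset_s = list(subset_s)
    if not subset_s or len(subset_s) >= len(tissues):
        raise ValueError("subset_s must be a non-empty proper subset")
    if np.any(values < 0):
        raise ValueError("expression must be non-negative")
    in_s = np.isin(tissues, subset_s)
    n_s, n_o = int(in_s.sum()), int((~in_s).sum())
    e_s, e_o = values[in_s].sum(), values[~in_s].sum()
    w_s = max(n_s, n_o) / n_s
    w_o = max(n_s, n_o) / n_o
    denom = w_s * e_s + w_o * e_o
    if denom == 0:
        return float("nan")
    return float(w_s * e_s / denom)


def bias_table(expr: pd.DataFrame, subsets: dict[str, list[str]] | None = None,
               threshold: float = BIAS_THRESHOLD) -> pd.DataFrame:
    """Bias score per gene per subset; by default one singleton per tissue.

    Returns a long frame (gene, subset, bias, biased).
    """
    if subsets is None:
        subsets = {t: [t] for t in expr.columns}
    rows = []
    for name, members in subsets.items():
        vals = expr.to_numpy(dtype=float)
        in_s = np.isin(expr.columns, members)
        n_s, n_o = int(in_s.sum()), int((~in_s).sum())
        w_s = max(n_s, n_o) / n_s
        w_o = max(n_s, n_o) / n_o
        e_s = vals[:, in_s].sum(axis=1)
        e_o = vals[:, ~in_s].sum(axis=1)
        denom = w_s * e_s + w_o * e_o
        with np.errstate(invalid="ignore"):
            bias = np.where(denom > 0, w_s * e_s / denom, np.nan)
        for gene, b in zip(expr.index, bias):
            rows.append({"gene": gene, "subset": name, "bias": b,
                         "biased": bool(b >= threshold) if not np.isnan(b) else False})
    return pd.DataFrame(rows)


def decile_bins(values: pd.Series | np.ndarray) -> np.ndarray:
    """Rank-based decile index (1 = lowest) per gene, stable under ties."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 10:
        raise ValueError("need >= 10 genes for deciles")
    order = np.argsort(values, kind="stable")
    bins = np.empty(n, dtype=int)
    edges = np.linspace(0, n, 11).round().astype(int)
    for d in range(10):
        bins[order[edges[d]:edges[d + 1]]] = d + 1
    return bins


def mann_whitney(values_a, values_b) -> RankTestResult:
    """Two-sided Mann-Whitney U test of two gene groups.

    Exact enumeration for small, tie-free groups (both n <= 20);
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankTestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                          a.size, b.size, method)


def sign_test(directions) -> float:
    """Exact two-sided sign test; ties (zeros) are dropped."""
    d = np.sign(np.asarray(directions, dtype=float))
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all pairs tied; sign test undefined")
    k = int((d > 0).sum())
    return float(stats.binomtest(k, d.size, 0.5).pvalue)


# ---------------------------------------------------------------------------
# category summaries

def _box_stats(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo = values[values >= q1 - 1.5 * iqr].min()
    hi = values[values <= q3 + 1.5 * iqr].max()
    return {"n": values.size, "median": med, "q1": q1, "q3": q3,
            "whisker_low": lo, "whisker_high": hi}


def category_expression_summary(calls: GeneMethylationCalls, expr: pd.DataFrame,
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Box-plot statistics of expression per methylation category per tissue.

    Returns (summary, tests): the summary has one row per tissue and
    category (empty categories reported as missing); the tests frame
    holds Mann-Whitney comparisons between categories within a tissue.
    """
    shared = calls.promoter.index.intersection(expr.index)
    if shared.empty:
        raise ValueError("calls and expression share no gene ids")
    summary_rows, test_rows = [], []
    for tissue in calls.tissues:
        if tissue not in expr.columns:
            continue
        cats = calls.categories(tissue).loc[shared]
        e = expr.loc[shared, tissue].to_numpy(dtype=float)
        groups = {}
        for cat in GENE_CATEGORIES:
            vals = e[(cats == cat).to_numpy()]
            groups[cat] = vals
            row = {"tissue": tissue, "category": cat}
            if vals.size:
                row.update(_box_stats(vals))
            else:
                row.update({"n": 0, "median": np.nan, "q1": np.nan, "q3": np.nan,
                            "whisker_low": np.nan, "whisker_high": np.nan})
            summary_rows.append(row)
        for ca, cb in (("unmethylated", "promoter_only"),
                       ("unmethylated", "body_only"),
                       ("unmethylated", "both"),
                       ("promoter_only", "body_only")):
            if groups[ca].size and groups[cb].size:
                res = mann_whitney(groups[ca], groups[cb])
                test_rows.append({
                    "tissue": tissue, "group_a": ca, "group_b": cb,
                    "median_a": float(np.median(groups[ca])),
                    "median_b": float(np.median(groups[cb])),
                    "U": res.statistic, "pvalue": res.pvalue,
                })
    return pd.DataFrame(summary_rows), pd.DataFrame(test_rows)


# ---------------------------------------------------------------------------
# tissue clustering

def cluster_tissues(matrix: pd.DataFrame, linkage_method: str = "complete",
                    ) -> str:
    """Complete-linkage clustering on 1 - Pearson r; newick string out."""
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 columns to cluster")
    X = matrix.to_numpy(dtype=float).T
    sd = X.std(axis=1)
    for name, s in zip(matrix.columns, sd):
        if s == 0:
            raise ValueError(f"zero-variance column {name!r}")
    dist = pdist(X, metric="correlation")  # 1 - r
    Z = hierarchy.linkage(dist, method=linkage_method)
    tree = hierarchy.to_tree(Z)
    labels = list(matrix.columns)

    def newick_node(node):
        if node.is_leaf():
            return labels[node.id], 0.0
        ln, lh = newick_node(node.left)
        rn, rh = newick_node(node.right)
        return (f"({ln}:{node.dist - lh:.6g},{rn}:{node.dist - rh:.6g})",
                node.dist)

    body, _ = newick_node(tree)
    return body + ";"
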