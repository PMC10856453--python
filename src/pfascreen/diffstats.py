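"""Liver-vs-muscle differential analysis of annotated PFAS abundances.

The abundance matrix holds compounds (rows) by samples (columns) of peak
areas.  The analysis mirrors the conventional metabolomics battery:
median normalization per sample, log2 transform with half-minimum
imputation of zeros, a two-sided Welch t-test per compound, volcano
classification at p < 0.05 and |log2 fold change| >= 1, PCA of samples,
and Ward hierarchical clustering of the significant compounds.

Compounds detected in only one tissue carry no testable contrast: they
bypass the Welch test and are reported through the exclusivity rule
(``exclusive_to``), classed as up in the tissue where they occur.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA as _PCA


@dataclass
class DiffResult:
    """Per-compound differential outcome (fold change is liver over muscle)."""

    compound: str
    log2fc: float
    p_value: float  # NaN when the compound bypasses testing
    volcano_class: str  # up_liver | up_muscle | ns
    exclusive_to: str | None = None


def check_matrix(matrix: pd.DataFrame, groups: pd.Series) -> None:
    if (matrix.values < 0).any():
        raise ValueError("abundance matrix has negative entries")
    if not set(matrix.columns) <= set(groups.index):
        missing = set(matrix.columns) - set(groups.index)
        raise ValueError(f"samples without group labels: {sorted(missing)[:5]}")


def normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Median-scale each sample so detected-compound medians agree globally.

    The per-sample median over detected (non-zero) compounds is scaled to
    the global median of all detected entries; zeros stay zero.
    """
    if (matrix.values < 0).any():
        raise ValueError("normalize expects a raw (non-negative) matrix")
    vals = matrix.values.astype(float)
    detected = vals > 0
    if not detected.any():
        raise ValueError("matrix has no detected compounds at all")
    global_med = np.median(vals[detected])
    out = vals.copy()
    for j in range(vals.shape[1]):
        col_det = detected[:, j]
        if not col_det.any():
            raise ValueError(f"sample {matrix.columns[j]!r} has no detected compounds")
        med = np.median(vals[col_det, j])
        out[:, j] = vals[:, j] * (global_med / med)
    res = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    res.attrs["transform"] = "normalized"
    return res


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2 with per-compound half-minimum imputation of zeros.

    A compound with no positive value anywhere stays all-zero on the log
    scale (it carries no information either way).
    """
    vals = matrix.values.astype(float)
    out = np.zeros_like(vals)
    for i in range(vals.shape[0]):
        row = vals[i]
        pos = row[row > 0]
        if len(pos) == 0:
            continue
        fill = pos.min() / 2.0
        out[i] = np.log2(np.where(row > 0, row, fill))
    res = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    res.attrs["transform"] = "log2"
    return res


def volcano(
    raw_matrix: pd.DataFrame,
    groups: pd.Series,
    p_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
    normalize_first: bool = True,
    fdr: bool = False,
) -> list[DiffResult]:
    """Welch-test every compound for a liver-vs-muscle difference.

    ``raw_matrix`` holds raw areas; it is median-normalized (optional) and
    log2-transformed internally.  Fold change is oriented liver/muscle.
    With ``fdr`` the p-values are Benjamini-Hochberg adjusted before
    classification.
    """
    check_matrix(raw_matrix, groups)
    liver_ids = [c for c in raw_matrix.columns if groups[c] == "liver"]
    muscle_ids = [c for c in raw_matrix.columns if groups[c] == "muscle"]
    if len(liver_ids) < 2 or len(muscle_ids) < 2:
        raise ValueError("need >= 2 samples per tissue group")

    norm = normalize(raw_matrix) if normalize_first else raw_matrix
    logm = log2_transform(norm)

    results: list[DiffResult] = []
    pvals: list[float] = []
    for comp in raw_matrix.index:
        raw_l = raw_matrix.loc[comp, liver_ids].values.astype(float)
        raw_m = raw_matrix.loc[comp, muscle_ids].values.astype(float)
        log_l = logm.loc[comp, liver_ids].values.astype(float)
        log_m = logm.loc[comp, muscle_ids].values.astype(float)
        lfc = float(log_l.mean() - log_m.mean())

        exclusive = None
        if (raw_l > 0).any() and not (raw_m > 0).any():
            exclusive = "liver"
        elif (raw_m > 0).any() and not (raw_l > 0).any():
            exclusive = "muscle"

        if exclusive is not None or (raw_l > 0).sum() < 2 or (raw_m > 0).sum() < 2:
            # no testable two-group contrast; the exclusivity rule decides
            cls = "ns"
            if exclusive == "liver":
                cls = "up_liver"
            elif exclusive == "muscle":
                cls = "up_muscle"
            results.append(DiffResult(str(comp), lfc, float("nan"), cls, exclusive))
            pvals.append(np.nan)
            continue

        p = float(stats.ttest_ind(log_l, log_m, equal_var=False).pvalue)
        results.append(DiffResult(str(comp), lfc, p, "ns", None))
        pvals.append(p)

    if fdr:
        from statsmodels.stats.multitest import multipletests

        mask = ~np.isnan(pvals)
        adj = np.full(len(pvals), np.nan)
        if mask.any():
            adj[mask] = multipletests(np.asarray(pvals)[mask], method="fdr_bh")[1]
        for r, q in zip(results, adj):
            if not np.isnan(q):
                r.p_value = float(q)

    for r in results:
        if r.exclusive_to is not None or np.isnan(r.p_value):
            continue
        if r.p_value < p_threshold and r.log2fc >= lfc_threshold:
            r.volcano_class = "up_liver"
        elif r.p_value < p_threshold and r.log2fc <= -lfc_threshold:
            r.volcano_class = "up_muscle"
        else:
            r.volcano_class = "ns"
    return results


def diff_table(results: list[DiffResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compound": [r.compound for r in results],
            "log2fc": [r.log2fc for r in results],
            "p_value": [r.p_value for r in results],
            "volcano_class": [r.volcano_class for r in results],
            "exclusive_to": [r.exclusive_to or "" for r in results],
        }
    )


def pca(
    log_matrix: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Column-centered PCA of samples over compounds.

    Input is the log2-normalized matrix (compounds x samples); samples are
    the observations.  Zero-variance compounds are dropped with a warning.
    Returns (scores samples x k, loadings compounds x k, explained-variance
    fractions).
    """
    if log_matrix.shape[1] < 2:
        raise ValueError("PCA needs at least two samples")
    X = log_matrix.T  # samples x compounds
    var = X.var(axis=0)
    keep = var > 0
    if (~keep).any():
        warnings.warn(f"dropping {(~keep).sum()} zero-variance compounds before PCA")
        X = X.loc[:, keep]
    if X.shape[1] == 0:
        # degenerate: identical columns carry no variance at all
        cols = [f"PC{i + 1}" for i in range(n_components)]
        return (
            pd.DataFrame(0.0, index=log_matrix.columns, columns=cols),
            pd.DataFrame(index=pd.Index([]), columns=cols, dtype=float),
            np.zeros(n_components),
        )
    k = min(n_components, min(X.shape) - 0)
    model = _PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X.values - X.values.mean(axis=0))
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores, index=X.index, columns=cols),
        pd.DataFrame(model.components_.T, index=X.columns, columns=cols),
        model.explained_variance_ratio_,
    )


def hclust_heatmap(
    log_matrix: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Ward hierarchical clustering of significant compounds and of samples.

    Rows are standardized (zero mean, unit variance; constant rows left at
    zero) before Euclidean/Ward linkage.  Leaf order is scipy's
    deterministic distance-then-index order.  Returns (compound linkage,
    sample linkage, matrix reordered to the dendrogram leaves).
    """
    if log_matrix.shape[0] < 2:
        raise ValueError(
            "need >= 2 significant compounds to cluster; relax the volcano thresholds"
        )
    vals = log_matrix.values.astype(float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - mu) / sd

    row_link = hierarchy.linkage(z, method="ward", metric="euclidean")
    col_link = hierarchy.linkage(z.T, method="ward", metric="euclidean")
    row_order = hierarchy.leaves_list(row_link)
    col_order = hierarchy.leaves_list(col_link)
    ordered = pd.DataFrame(
        z[np.ix_(row_order, col_order)],
        index=log_matrix.index[row_order],
        columns=log_matrix.columns[col_order],
    )
    return row_link, col_link, ordered


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string (branch lengths kept)."""
    tree = hierarchy.to_tree(link)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.left), walk(node.right)
        dl = node.dist - node.left.dist
        dr = node.dist - node.right.dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return walk(tree) + ";"
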