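"""Matrisome annotation and composition profiling.

Relative percent composition (RPC) expresses each protein's intensity as a
percentage of its sample's total intensity; category compositions, top-20
abundance lists and 90%-cumulative-coverage counts are derived from it.
Hierarchical clustering and PCA operate on the matrisome rows of the
normalized matrix.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import ttest_ind
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "annotate",
    "rpc",
    "category_composition",
    "cumulative_coverage",
    "top_abundant",
    "hcluster",
    "pca_embed",
]


def annotate(proteins: list[str], annotation: pd.DataFrame) -> pd.DataFrame:
    """Label proteins with matrisome division/category (exact symbol match).

    Unmatched proteins get division/category ``"none"``. Returns a DataFrame
    indexed by protein with columns ``division`` and ``category``; category
    counts are available via ``result["category"].value_counts()``.
    """
    if annotation.empty:
        raise ValueError("annotation is empty")
    out = annotation.reindex(proteins)[["division", "category"]].fillna("none")
    out.index.name = "gene"
    return out


def rpc(values: pd.DataFrame) -> pd.DataFrame:
    """Relative percent composition: 100 * intensity / column total."""
    totals = values.sum(axis=0, skipna=True)
    zero = totals <= 0
    if zero.any():
        raise ValueError(f"zero-total sample(s): {list(values.columns[zero])}")
    return values.div(totals, axis=1) * 100.0


def category_composition(
    rpc_table: pd.DataFrame,
    annotation: pd.DataFrame,
    groups: dict[str, list[str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample matrisome-category RPC, group means, and Welch p-values.

    The per-sample RPC of a category is the sum of its member proteins' RPC.
    Groups with fewer than two samples contribute means but no test (the
    Welch p is NaN, with a warning). With more than two groups, the p-value
    column compares the first two groups listed.
    """
    labels = annotate(list(rpc_table.index), annotation)
    cats = [c for c in labels["category"].unique() if c != "none"]
    per_sample = pd.DataFrame(
        {c: rpc_table.loc[labels["category"] == c].sum(axis=0) for c in sorted(cats)}
    ).T  # category x sample
    means = pd.DataFrame(
        {name: per_sample[cols].mean(axis=1) for name, cols in groups.items()}
    )
    names = list(groups)
    stats = pd.DataFrame(index=per_sample.index, columns=["t", "p"], dtype=float)
    if len(names) >= 2:
        a, b = groups[names[0]], groups[names[1]]
        if min(len(a), len(b)) < 2:
            logger.warning("group with <2 samples; Welch test skipped")
        else:
            res = ttest_ind(
                per_sample[a], per_sample[b], axis=1, equal_var=False
            )
            stats["t"], stats["p"] = res.statistic, res.pvalue
    return means.join(stats), per_sample


def cumulative_coverage(group_mean_rpc: pd.Series, threshold: float = 0.9) -> int:
    """Smallest k such that the top-k proteins by mean RPC reach the threshold.

    ``group_mean_rpc`` is a mean-RPC vector for one group (sums to 100).
    """
    v = group_mean_rpc.dropna()
    if v.empty:
        raise ValueError("empty RPC vector")
    cum = np.cumsum(np.sort(v.to_numpy())[::-1])
    return int(np.searchsorted(cum, threshold * 100.0 - 1e-9) + 1)


def top_abundant(
    rpc_table: pd.DataFrame,
    samples: list[str],
    annotation: pd.DataFrame,
    n: int = 20,
    matrisome_only: bool = True,
) -> pd.DataFrame:
    """Top-n proteins by group mean RPC, with per-sample values for spread.

    Ties on the mean are broken lexicographically by symbol. If fewer than
    ``n`` eligible proteins exist, all are returned with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sub = rpc_table[samples]
    if matrisome_only:
        labels = annotate(list(sub.index), annotation)
        sub = sub.loc[labels["category"] != "none"]
    if len(sub) < n:
        logger.warning("only %d proteins available for top-%d list", len(sub), n)
    mean = sub.mean(axis=1)
    order = sorted(sub.index, key=lambda g: (-mean[g], g))[:n]
    out = sub.loc[order].copy()
    out.insert(0, "mean_rpc", mean[order])
    return out


def hcluster(
    values: pd.DataFrame, method: str = "average"
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of samples on z-scored protein profiles.

    Each protein row is z-scored across samples (constant rows are dropped,
    logged); samples are clustered on Euclidean distance. Returns the SciPy
    linkage matrix and the dendrogram leaf order (sample names).
    """
    if values.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    sd = values.std(axis=1, ddof=0)
    const = sd == 0
    if const.any():
        logger.info("hcluster: dropping %d constant protein row(s)", int(const.sum()))
    v = values.loc[~const]
    z = v.sub(v.mean(axis=1), axis=0).div(v.std(axis=1, ddof=0), axis=0)
    link = linkage(z.T.to_numpy(), method=method, metric="euclidean")
    order = [values.columns[i] for i in leaves_list(link)]
    return link, order


def pca_embed(
    values: pd.DataFrame, n_components: int = 2, log2: bool = True
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on (log2) matrisome intensities.

    Components are ordered by decreasing explained variance; each
    component's sign is fixed by making its largest-magnitude loading
    positive. Returns sample coordinates and the explained-variance ratios.
    """
    if values.shape[1] < 3:
        raise ValueError("need at least three samples for PCA")
    max_comp = min(values.shape[1] - 1, values.shape[0])
    if n_components > max_comp:
        logger.warning("reducing n_components from %d to %d", n_components, max_comp)
        n_components = max_comp
    x = np.log2(values.T.to_numpy()) if log2 else values.T.to_numpy()
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    for k in range(n_components):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            coords[:, k] *= -1
            pca.components_[k] *= -1
    out = pd.DataFrame(
        coords,
        index=values.columns,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    return out, pca.explained_variance_ratio_
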