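"""Single-cell integration: cellular origins, fibroblast subclustering and
per-cell gene-set scoring.

The cellular origin of a protein is decided by two criteria: (1) the
encoding gene is cell-type-specific somewhere (one-vs-rest Wilcoxon
rank-sum, Benjamini-Hochberg adjusted p < 0.01 with positive log fold
change), and (2) among the cell types, the origin is the one with the
highest average expression of the gene.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

from pdecm.gsea import ssgsea_scores

logger = logging.getLogger(__name__)

__all__ = [
    "find_markers",
    "assign_origin",
    "origin_fractions",
    "fibroblast_subcluster",
    "sc_score",
    "correlate_with_score",
]


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense() if hasattr(x, "todense") else x, dtype=float)


def find_markers(
    adata: ad.AnnData,
    groupby: str = "cell_type",
    adj_p_threshold: float = 0.01,
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest cell-type markers by Wilcoxon rank-sum on the normalized layer.

    For every (cell type, gene) pair, a two-sided Mann-Whitney U test
    compares the type's cells against all other cells; p-values are BH
    adjusted across genes within each cell type. ``specific`` is True iff
    adjusted p < ``adj_p_threshold`` and the one-vs-rest log2 fold change is
    positive. All-zero genes are reported untested (p = NaN, not specific);
    cell types with fewer than ``min_cells`` cells are skipped with a warning.
    """
    labels = adata.obs[groupby].astype(str)
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need at least two cell types")
    x = _dense(adata.X)
    eps = 1e-9
    rows = []
    for ctype in types:
        in_mask = (labels == ctype).to_numpy()
        if in_mask.sum() < min_cells:
            logger.warning("find_markers: skipping %r (<%d cells)", ctype, min_cells)
            continue
        xin, xout = x[in_mask], x[~in_mask]
        tested = (xin.sum(axis=0) + xout.sum(axis=0)) > 0
        p = np.full(x.shape[1], np.nan)
        if tested.any():
            res = mannwhitneyu(
                xin[:, tested], xout[:, tested], axis=0, alternative="two-sided"
            )
            p[tested] = res.pvalue
        padj = np.full_like(p, np.nan)
        if tested.any():
            padj[tested] = multipletests(p[tested], method="fdr_bh")[1]
        lfc = np.log2((xin.mean(axis=0) + eps) / (xout.mean(axis=0) + eps))
        specific = tested & (padj < adj_p_threshold) & (lfc > 0)
        rows.append(
            pd.DataFrame(
                {
                    "gene": adata.var_names,
                    "cell_type": ctype,
                    "log2fc": lfc,
                    "p": p,
                    "p_adj": padj,
                    "specific": specific,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["gene", "cell_type", "log2fc", "p", "p_adj", "specific"]
        )
    return pd.concat(rows, ignore_index=True)


def assign_origin(
    genes: list[str], adata: ad.AnnData, markers: pd.DataFrame, groupby: str = "cell_type"
) -> dict[str, str | None]:
    """Cellular origin per gene: highest-average-expression type among specific genes.

    A gene is assigned only if it is specific for at least one cell type in
    *markers*; the origin is then the cell type with the highest mean
    normalized expression. Genes absent from the matrix, or specific
    nowhere, map to ``None`` (unassigned).
    """
    labels = adata.obs[groupby].astype(str)
    x = _dense(adata.X)
    type_means = pd.DataFrame(
        {t: x[(labels == t).to_numpy()].mean(axis=0) for t in sorted(labels.unique())},
        index=adata.var_names,
    )
    specific_genes = set(markers.loc[markers["specific"], "gene"])
    out: dict[str, str | None] = {}
    for g in genes:
        if g not in adata.var_names:
            logger.info("assign_origin: gene %r absent from matrix", g)
            out[g] = None
        elif g not in specific_genes:
            out[g] = None
        else:
            out[g] = type_means.loc[g].idxmax()
    return out


def origin_fractions(geneset: list[str], origins: dict[str, str | None]) -> pd.Series:
    """Fraction of the gene set assigned to each cell type (plus unassigned)."""
    if not geneset:
        raise ValueError("empty gene set")
    assigned = pd.Series(
        ["unassigned" if origins.get(g) is None else origins[g] for g in geneset]
    )
    return assigned.value_counts(normalize=True).sort_index()


def fibroblast_subcluster(
    adata: ad.AnnData,
    feature_genes: list[str],
    n_components: int = 20,
    resolution: float = 0.5,
    k_neighbors: int = 20,
    seed: int = 0,
) -> pd.Series:
    """Subcluster cells on a feature-gene panel (matrisome genes).

    Pipeline: z-score the normalized expression of the feature genes, PCA to
    ``n_components``, k-nearest-neighbor graph, Leiden community detection
    at the given resolution. Deterministic under the seed. Returns cluster
    labels indexed by cell.
    """
    import scanpy as sc

    present = [g for g in feature_genes if g in adata.var_names]
    if len(present) < 2:
        raise ValueError("fewer than two feature genes present in the matrix")
    if adata.n_obs < n_components + 1:
        raise ValueError("need more cells than PCA components")
    sub = adata[:, present].copy()
    sc.pp.scale(sub)
    n_comp = min(n_components, sub.n_obs - 1, len(present) - 1)
    sc.tl.pca(sub, n_comps=n_comp, svd_solver="arpack")
    sc.pp.neighbors(sub, n_neighbors=k_neighbors, random_state=seed)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(
            sub,
            resolution=resolution,
            random_state=seed,
            flavor="leidenalg",
            key_added="subcluster",
        )
    return sub.obs["subcluster"].astype(str)


def sc_score(
    adata: ad.AnnData, geneset: set[str], alpha: float = 0.25
) -> pd.Series:
    """Per-cell rank-based gene-set enrichment score (shared ssGSEA scorer)."""
    expr = pd.DataFrame(
        _dense(adata.X).T, index=adata.var_names, columns=adata.obs_names
    )
    return ssgsea_scores(expr, geneset, alpha=alpha)


def correlate_with_score(
    adata: ad.AnnData,
    scores: pd.Series,
    top_k: int = 20,
    log_tpm: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of each gene's TPM expression with a per-cell score.

    Counts are scaled to transcripts-per-million per cell (optionally
    log1p). Zero-variance genes are excluded from the ranking (reported).
    Returns a table sorted by descending r with the fraction of cells
    expressing each gene (nonzero raw count); the top-``top_k`` genes are
    flagged in the ``top`` column.
    """
    if adata.n_obs < 3:
        raise ValueError("need at least three cells")
    counts = _dense(adata.layers["counts"] if "counts" in adata.layers else adata.X)
    depth = counts.sum(axis=1, keepdims=True)
    depth[depth == 0] = 1.0
    tpm = counts / depth * 1e6
    if log_tpm:
        tpm = np.log1p(tpm)
    s = scores.loc[adata.obs_names].to_numpy(dtype=float)
    sd_g = tpm.std(axis=0)
    keep = sd_g > 0
    if not keep.any():
        raise ValueError("all genes have zero variance")
    if (~keep).any():
        logger.info("correlate_with_score: %d zero-variance gene(s) excluded", int((~keep).sum()))
    tc = tpm[:, keep] - tpm[:, keep].mean(axis=0)
    ss = s - s.mean()
    r = (tc * ss[:, None]).sum(axis=0) / (
        np.sqrt((tc**2).sum(axis=0)) * np.sqrt((ss**2).sum())
    )
    out = pd.DataFrame(
        {
            "r": r,
            "frac_positive": (counts[:, keep] > 0).mean(axis=0),
        },
        index=adata.var_names[keep],
    ).sort_values("r", ascending=False)
    out["top"] = False
    out.iloc[: int(top_k), out.columns.get_loc("top")] = True
    out.index.name = "gene"
    return out
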