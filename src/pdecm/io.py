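"""Reading and writing of the pipeline's plain-text formats.

All tabular files are tab-separated with a header row; intensity and TPM
matrices carry the gene symbol as the row index. Single-cell matrices are
written as an MTX triplet (matrix.mtx, genes.tsv, barcodes.tsv) plus a
celltypes.tsv.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_design",
    "read_samples",
    "read_annotation",
    "read_geneset",
    "write_geneset",
    "write_sc_dir",
    "read_sc_dir",
    "read_survival",
]


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(values: pd.DataFrame, path: str | Path) -> None:
    values.to_csv(path, sep="\t")


def read_design(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_annotation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_geneset(path: str | Path) -> list[str]:
    """One gene symbol per line."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_geneset(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def write_sc_dir(adata: ad.AnnData, outdir: str | Path) -> None:
    """MTX triplet (genes x cells) + cell-type labels."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = adata.layers.get("counts", adata.X)
    counts = scipy.sparse.csr_matrix(np.asarray(counts))
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), counts.T)  # genes x cells
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", index=False, header=False)
    adata.obs[["cell_type"]].to_csv(outdir / "celltypes.tsv", sep="\t")


def read_sc_dir(indir: str | Path) -> ad.AnnData:
    """Rebuild the AnnData (counts + depth-normalized log1p X) from an MTX dir."""
    indir = Path(indir)
    counts = np.asarray(scipy.io.mmread(str(indir / "matrix.mtx")).todense()).T
    genes = pd.read_csv(indir / "genes.tsv", header=None)[0].tolist()
    barcodes = pd.read_csv(indir / "barcodes.tsv", header=None)[0].tolist()
    obs = pd.read_csv(indir / "celltypes.tsv", sep="\t", index_col=0).loc[barcodes]
    adata = ad.AnnData(
        X=counts.astype(np.float32), obs=obs, var=pd.DataFrame(index=genes)
    )
    adata.layers["counts"] = adata.X.copy()
    depth = adata.layers["counts"].sum(axis=1, keepdims=True)
    depth[depth == 0] = 1.0
    adata.X = np.log1p(adata.layers["counts"] / depth * 1e4)
    return adata


def read_survival(path: str | Path) -> pd.DataFrame:
    out = pd.read_csv(path, sep="\t", index_col=0)
    if not {"time", "event"} <= set(out.columns):
        raise ValueError("survival table needs 'time' and 'event' columns")
    return out
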