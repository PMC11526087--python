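"""End-to-end pipeline: synthetic cohort -> normalization -> matrisome
profile -> DEP/PEM -> cellular origins -> gene-set scores -> survival.

`run_all` executes every stage on a synthetic cohort described by a
:class:`RunConfig`, writes stage artifacts to the output directory, and
returns a machine-readable report. All randomness flows from the single
seed, so two runs with the same config produce identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pdecm import differential, io, matrisome, singlecell, survival
from pdecm.normalize import normalize_pipeline
from pdecm.synthetic import (
    CohortConfig,
    generate_bulk_survival,
    generate_cohort,
    generate_sc_data,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "planted_cohort_config"]

CELL_TYPES = [
    "Fibroblast",
    "Epithelial",
    "Macrophage",
    "Endothelial",
    "T cell",
    "B cell",
    "Mast cell",
]


@dataclass
class RunConfig:
    """Thresholds and sizes for a full synthetic run.

    Threshold defaults follow the published analysis: DEP rule FC > sqrt(2)
    with p < 0.05, marker specificity at adjusted p < 0.01, fibroblast
    subclustering with 20 PCA dimensions at resolution 0.5, top-20
    correlated genes, top-30 CAF markers.
    """

    seed: int = 0
    n_proteins: int = 1000
    n_tumor_up: int = 20
    n_tumor_down: int = 20
    tumor_effect: float = 1.5
    n_pem: int = 27
    pem_effect: float = 2.0
    n_cells_per_type: int = 120
    n_bulk_patients: int = 375
    hazard_log_ratio: float = 1.0
    fc_threshold: float = differential.SQRT2
    p_threshold: float = 0.05
    adj_p_threshold: float = 0.01
    ssgsea_alpha: float = 0.25
    cluster_resolution: float = 0.5
    cluster_dims: int = 20
    top_k: int = 20
    top_n_markers: int = 30
    outdir: str = "pdecm_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def planted_cohort_config(run: RunConfig) -> CohortConfig:
    """Cohort config with effects planted on disjoint matrisome proteins."""
    cfg = CohortConfig(n_proteins=run.n_proteins, seed=run.seed)
    mat, _ = cfg.protein_symbols()
    need = run.n_tumor_up + run.n_tumor_down + run.n_pem
    if need > len(mat):
        raise ValueError("not enough matrisome proteins for the planted effects")
    up = mat[: run.n_tumor_up]
    down = mat[run.n_tumor_up : run.n_tumor_up + run.n_tumor_down]
    pem = mat[run.n_tumor_up + run.n_tumor_down : need]
    cfg.planted_tumor_effects = {
        **{g: run.tumor_effect for g in up},
        **{g: -run.tumor_effect for g in down},
    }
    cfg.planted_pccnos_effects = {g: run.pem_effect for g in pem}
    return cfg


def _checksum(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Run every stage; write artifacts under ``config.outdir``; return report."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": asdict(config)}

    def stage(name):
        logger.info("stage %s (t=%.1fs)", name, time.time() - t0)

    try:
        stage("synthetic cohort")
        cohort = generate_cohort(planted_cohort_config(config))
        io.write_matrix(cohort.values, outdir / "intensities.tsv")
        cohort.design.to_csv(outdir / "design.tsv", sep="\t", index=False)
        cohort.samples.to_csv(outdir / "samples.tsv", sep="\t")
        cohort.annotation.to_csv(outdir / "matrisome.tsv", sep="\t")

        stage("normalize")
        norm, qc = normalize_pipeline(cohort.values, cohort.design)
        io.write_matrix(norm, outdir / "normalized.tsv")
        (outdir / "normalize_qc.json").write_text(json.dumps(qc, indent=2))

        stage("matrisome profile")
        design = cohort.design.set_index("channel")
        sample_cols = design.index[design["role"] == "sample"]
        col_to_sample = design.loc[sample_cols, "sample_id"]
        norm_samples = norm[sample_cols].rename(columns=col_to_sample.to_dict())
        rpc_table = matrisome.rpc(norm_samples)
        io.write_matrix(rpc_table, outdir / "rpc.tsv")
        tissues = cohort.samples["tissue"]
        groups = {t: list(tissues.index[tissues == t]) for t in ("TUM", "NAT", "NN")}
        comp, _ = matrisome.category_composition(
            rpc_table, cohort.annotation, {"TUM": groups["TUM"], "NAT": groups["NAT"]}
        )
        comp.to_csv(outdir / "category_composition.tsv", sep="\t")
        coverage = {
            t: matrisome.cumulative_coverage(rpc_table[cols].mean(axis=1))
            for t, cols in groups.items()
            if cols
        }
        mat_rows = cohort.annotation.index[cohort.annotation["category"] != "none"]
        _, evr = matrisome.pca_embed(norm_samples.loc[mat_rows])

        stage("differential")
        dep_tumor = differential.welch_dep(
            norm_samples,
            groups["TUM"],
            groups["NAT"],
            fc_threshold=config.fc_threshold,
            p_threshold=config.p_threshold,
            annotation=cohort.annotation,
        )
        dep_tumor.to_csv(outdir / "dep_tumor_vs_nat.tsv", sep="\t")
        hist = cohort.samples["histology"]
        pccnos = list(tissues.index[(tissues == "TUM") & (hist == "PCC-NOS")])
        non_pccnos = list(tissues.index[(tissues == "TUM") & (hist == "non-PCC-NOS")])
        dep_pem = differential.welch_dep(
            norm_samples,
            pccnos,
            non_pccnos,
            fc_threshold=config.fc_threshold,
            p_threshold=config.p_threshold,
            annotation=cohort.annotation,
        )
        pem = differential.define_pem(dep_pem)
        io.write_geneset(pem, outdir / "pem.txt")

        stage("single cell")
        adata = generate_sc_data(
            config.n_cells_per_type,
            CELL_TYPES,
            cohort.truth,
            seed=config.seed + 1,
            genes=sorted(set(mat_rows) | set(pem)),
        )
        markers = singlecell.find_markers(
            adata, adj_p_threshold=config.adj_p_threshold
        )
        origins = singlecell.assign_origin(pem, adata, markers)
        fractions = singlecell.origin_fractions(pem, origins) if pem else pd.Series(dtype=float)
        fractions.to_csv(outdir / "origin_fractions.tsv", sep="\t", header=["fraction"])
        fib = adata[adata.obs["cell_type"] == "Fibroblast"].copy()
        subclusters = singlecell.fibroblast_subcluster(
            fib,
            list(mat_rows),
            n_components=config.cluster_dims,
            resolution=config.cluster_resolution,
            seed=config.seed,
        )
        cell_scores = singlecell.sc_score(fib, set(pem), alpha=config.ssgsea_alpha)
        corr = singlecell.correlate_with_score(fib, cell_scores, top_k=config.top_k)
        corr.to_csv(outdir / "pem_score_correlation.tsv", sep="\t")
        caf_markers = survival.select_top_markers(
            corr.reset_index().rename(columns={"r": "log2fc"}),
            n=config.top_n_markers,
            key="log2fc",
        )

        stage("bulk scoring and survival")
        bulk = generate_bulk_survival(
            config.n_bulk_patients,
            set(pem),
            config.hazard_log_ratio,
            seed=config.seed + 2,
            extra_genes=set(caf_markers),
        )
        pem_scores = survival.ssgsea_bulk(bulk.tpm, set(pem), alpha=config.ssgsea_alpha)
        caf_in_bulk = [g for g in caf_markers if g in bulk.tpm.index]
        caf_scores = (
            survival.ssgsea_bulk(bulk.tpm, set(caf_in_bulk), alpha=config.ssgsea_alpha)
            if len(caf_in_bulk) >= 1 and len(caf_in_bulk) < len(bulk.tpm)
            else None
        )
        r, p_corr = (
            survival.score_correlation(pem_scores, caf_scores)
            if caf_scores is not None
            else (float("nan"), float("nan"))
        )
        labels = survival.dichotomize(pem_scores, rule="mean")
        chi2, p_surv = survival.logrank_test(
            bulk.survival["time"], bulk.survival["event"], labels
        )
        km = {
            g: survival.km_estimate(
                bulk.survival.loc[labels == g, "time"],
                bulk.survival.loc[labels == g, "event"],
            )["S"].iloc[-1]
            for g in ("high", "low")
        }
    except Exception as exc:  # abort with the failing stage in the message
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    fib_frac = float(fractions.get("Fibroblast", 0.0)) if len(fractions) else 0.0
    report.update(
        {
            "n_channels": int(cohort.values.shape[1]),
            "n_sample_channels": int(len(sample_cols)),
            "normalize_qc": {k: qc[k] for k in ("n_proteins_bridged", "n_proteins_excluded")},
            "coverage_90pct": coverage,
            "pca_explained_variance": [float(v) for v in evr],
            "dep_tumor_enriched": int((dep_tumor["direction"] == "A-enriched").sum()),
            "dep_nat_enriched": int((dep_tumor["direction"] == "B-enriched").sum()),
            "pem_size": len(pem),
            "pem_recovered_exactly": set(pem) == cohort.truth.pem_true,
            "n_fibroblast_subclusters": int(subclusters.nunique()),
            "origin_fibroblast_fraction": fib_frac,
            "score_correlation_r": r,
            "score_correlation_p": p_corr,
            "logrank_chi2": chi2,
            "logrank_p": p_surv,
            "km_final_survival": {k: float(v) for k, v in km.items()},
        }
    )
    report["checksum"] = _checksum({k: v for k, v in report.items() if k != "parameters"})
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    logger.info("pipeline done in %.1fs", time.time() - t0)
    return report
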