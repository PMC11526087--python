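"""Differential matrisome protein (DEP) calling and PEM definition.

A protein is a DEP between two groups when its fold change exceeds sqrt(2)
(equivalently |log2FC| > 0.5) and the two-sided Welch t-test gives p < 0.05.
The fold change is the ratio of linear-scale group means (as in the source
convention, average group A / average group B); the Welch test runs on log2
intensities, which stabilizes the variance of log-normal MS intensities.
No multiple-testing correction is applied by default — DEP calling uses raw
p-values with the fold-change filter; a Benjamini-Hochberg mode is available.

PCC-NOS-enriched matrisome proteins (PEMs) are the DEPs of the PCC-NOS vs
non-PCC-NOS tumor contrast that fall on the PCC-NOS-enriched side.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["welch_dep", "paired_log2fc", "define_pem"]

SQRT2 = float(np.sqrt(2.0))


def welch_dep(
    values: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    fc_threshold: float = SQRT2,
    p_threshold: float = 0.05,
    annotation: pd.DataFrame | None = None,
    matrisome_only: bool = True,
    log_scale_test: bool = True,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Welch-test differential table between two sample groups.

    Fold change ``fc`` = mean(A) / mean(B) on the linear scale; the Welch
    statistic and two-sided p use log2 intensities (Welch-Satterthwaite
    degrees of freedom) unless ``log_scale_test=False``. ``dep`` is True iff
    |log2fc| > log2(fc_threshold) and p < p_threshold (BH-adjusted p when
    ``bh_adjust``); ``direction`` is ``A-enriched`` / ``B-enriched`` / ``none``.

    Proteins with fewer than two observed positive values in either group
    are excluded (logged). Zero/missing intensities are treated as missing.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if min(len(group_a), len(group_b)) < 2:
        raise ValueError("each group needs at least two samples")
    sub = values
    if matrisome_only:
        if annotation is None:
            raise ValueError("matrisome_only=True requires an annotation")
        keep = annotation.reindex(sub.index)["category"].fillna("none") != "none"
        sub = sub.loc[keep]

    a = sub[group_a].where(sub[group_a] > 0)
    b = sub[group_b].where(sub[group_b] > 0)
    ok = (a.notna().sum(axis=1) >= 2) & (b.notna().sum(axis=1) >= 2)
    if (~ok).any():
        logger.info("welch_dep: %d protein(s) excluded (<2 observations)", int((~ok).sum()))
    a, b = a.loc[ok], b.loc[ok]

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    fc = mean_a / mean_b
    xa, xb = (np.log2(a), np.log2(b)) if log_scale_test else (a, b)
    res = ttest_ind(xa, xb, axis=1, equal_var=False, nan_policy="omit")
    p = pd.Series(np.asarray(res.pvalue, dtype=float), index=a.index)
    p_eff = (
        pd.Series(multipletests(p.to_numpy(), method="fdr_bh")[1], index=p.index)
        if bh_adjust
        else p
    )
    log2fc = np.log2(fc)
    cut = np.log2(fc_threshold)
    dep = (log2fc.abs() > cut) & (p_eff < p_threshold)
    direction = pd.Series("none", index=a.index)
    direction[dep & (log2fc > cut)] = "A-enriched"
    direction[dep & (log2fc < -cut)] = "B-enriched"
    out = pd.DataFrame(
        {
            "fc": fc,
            "log2fc": log2fc,
            "t": np.asarray(res.statistic, dtype=float),
            "p": p,
            "dep": dep,
            "direction": direction,
        }
    )
    out.index.name = "gene"
    return out


def paired_log2fc(
    values: pd.DataFrame,
    pairs: dict[str, tuple[str, str]],
    proteins: list[str] | None = None,
    group_log2fc: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient paired tumor/NAT log2 ratios and per-protein medians.

    ``pairs`` maps patient id to (NAT sample, TUM sample); patients are used
    only when both columns are present in the matrix. Returns the patient x
    protein log2FC table and a per-protein summary with the median and, when
    ``group_log2fc`` is supplied, a concordance flag (median sign agrees
    with the group-level log2FC sign).
    """
    complete = {
        pt: (nat, tum)
        for pt, (nat, tum) in pairs.items()
        if nat in values.columns and tum in values.columns
    }
    if not complete:
        raise ValueError("no complete tumor/NAT pairs")
    sub = values.loc[list(proteins)] if proteins is not None else values
    table = pd.DataFrame(
        {
            pt: np.log2(sub[tum] / sub[nat])
            for pt, (nat, tum) in complete.items()
        }
    )  # protein x patient
    summary = pd.DataFrame({"median_log2fc": table.median(axis=1)})
    if group_log2fc is not None:
        summary["concordant"] = np.sign(summary["median_log2fc"]) == np.sign(
            group_log2fc.reindex(summary.index)
        )
    return table, summary


def define_pem(dep_table: pd.DataFrame) -> list[str]:
    """PEM set: DEPs enriched on the PCC-NOS side of the contrast.

    Expects a table from :func:`welch_dep` computed with group A = PCC-NOS
    tumors; returns the sorted symbols flagged DEP with direction
    ``A-enriched``. Empty input yields an empty set with a warning.
    """
    pems = sorted(dep_table.index[(dep_table["dep"]) & (dep_table["direction"] == "A-enriched")])
    if not pems:
        logger.warning("define_pem: empty PEM set")
    return pems
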