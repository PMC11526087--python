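"""Bulk cohort gene-set scoring and survival stratification.

Bulk samples are scored with the same rank-based single-sample enrichment
statistic used for cells; patients are dichotomized at the mean (or median)
score and compared with a Kaplan-Meier estimate and the log-rank test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import pearsonr

from pdecm.gsea import ssgsea_scores

logger = logging.getLogger(__name__)

__all__ = [
    "select_top_markers",
    "ssgsea_bulk",
    "score_correlation",
    "dichotomize",
    "km_estimate",
    "logrank_test",
]


def select_top_markers(
    marker_table: pd.DataFrame, n: int = 30, key: str = "log2fc"
) -> list[str]:
    """Top-n genes by descending *key* (ties broken lexicographically).

    Expects a table with a ``gene`` column (or gene index) and the ranking
    column; fewer than ``n`` rows returns all with a warning.
    """
    if key not in marker_table.columns:
        raise ValueError(f"marker table lacks column {key!r}")
    genes = (
        marker_table["gene"]
        if "gene" in marker_table.columns
        else marker_table.index.to_series()
    )
    order = sorted(zip(-marker_table[key].to_numpy(), genes))
    if len(order) < n:
        logger.warning("select_top_markers: only %d rows for top-%d", len(order), n)
    return [g for _, g in order[:n]]


def ssgsea_bulk(
    tpm: pd.DataFrame, geneset: set[str], alpha: float = 0.25
) -> pd.Series:
    """Per-sample enrichment score on a genes x samples TPM matrix."""
    return ssgsea_scores(tpm, geneset, alpha=alpha)


def score_correlation(a: pd.Series, b: pd.Series) -> tuple[float, float]:
    """Pearson r and two-sided p between two aligned score vectors."""
    b = b.loc[a.index]
    if len(a) < 3:
        raise ValueError("need at least three observations")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a score vector")
    r, p = pearsonr(a, b)
    return float(r), float(p)


def dichotomize(values: pd.Series, rule: str = "mean") -> pd.Series:
    """Split into 'high'/'low' at the mean or median; ties to 'high'."""
    if len(values) < 2:
        raise ValueError("need at least two values")
    if values.nunique() == 1:
        raise ValueError("all values equal; degenerate split")
    if rule not in {"mean", "median"}:
        raise ValueError(f"unknown rule {rule!r}")
    cut = values.mean() if rule == "mean" else values.median()
    out = pd.Series(np.where(values >= cut, "high", "low"), index=values.index)
    logger.info("dichotomize: %s", out.value_counts().to_dict())
    return out


def km_estimate(time: pd.Series, event: pd.Series) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate of the survival function.

    Returns a step function as a DataFrame indexed by time with column
    ``S``; S(0) = 1 and S is non-increasing. Censored subjects leave the
    risk set without contributing an event.
    """
    if (np.asarray(time) < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    out = kmf.survival_function_.rename(columns={"KM_estimate": "S"})
    out.index.name = "time"
    return out


def logrank_test(
    time: pd.Series, event: pd.Series, groups: pd.Series
) -> tuple[float, float]:
    """k-group log-rank test; returns (chi-square statistic, p-value).

    The statistic compares observed and expected events under the
    hypergeometric distribution at each distinct event time, with k-1
    degrees of freedom; tied event times share the same risk set.
    """
    if pd.Series(groups).nunique() < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(time, groups, event)
    return float(res.test_statistic), float(res.p_value)
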