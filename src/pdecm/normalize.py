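"""Two-stage normalization of multi-plex TMT protein abundance.

Stage 1 (within-channel median centering) removes channel-specific loading
and labeling biases: each channel's log2 intensities are recentered so that
every channel shares a common log2 median (the mean of the original channel
medians). Stage 2 (reference scaling) bridges plexes through the second
internal reference channel (R2), which carries the same pooled control in
every plex: each protein's intensity is divided by its R2 intensity within
the plex and rescaled by the protein's average R2 intensity across plexes,
so that after this stage every plex reports the protein on a common scale
and the R2 channels of a protein are identical across plexes.

All matrices stay on the linear intensity scale between stages; log2 is
taken only inside computations. Missing values propagate (medians are
computed over observed entries). A protein whose R2 intensity is missing or
non-positive in some plex cannot be bridged and is dropped from stage 2
output (counted in the QC report).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["validate_design", "median_center", "reference_scale", "normalize_pipeline"]


def validate_design(design: pd.DataFrame) -> None:
    """Check the channel design: every plex has exactly one R1 and one R2."""
    required = {"channel", "plex", "role"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table lacks columns: {sorted(missing)}")
    bad_roles = set(design["role"]) - {"sample", "R1", "R2"}
    if bad_roles:
        raise ValueError(f"unknown channel roles: {sorted(bad_roles)}")
    for plex, sub in design.groupby("plex"):
        for role in ("R1", "R2"):
            k = int((sub["role"] == role).sum())
            if k != 1:
                raise ValueError(f"plex {plex!r} has {k} {role} channels, expected 1")


def median_center(values: pd.DataFrame) -> pd.DataFrame:
    """Stage 1: recenter every channel to a common log2 median.

    For channel j with log2 median ``m_j``, the output is
    ``2**(log2(x) - m_j + mean_k(m_k))``. NaN entries are treated as missing
    and propagate; non-positive intensities are an error (mask them as NaN
    first if they denote missingness).
    """
    arr = values.to_numpy(dtype=float)
    if np.any(arr[~np.isnan(arr)] <= 0):
        raise ValueError("non-positive intensities; mask missing values as NaN")
    log2 = np.log2(arr)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns checked below
        med = np.nanmedian(log2, axis=0)
    empty = np.isnan(med)
    if empty.any():
        names = list(values.columns[empty])
        raise ValueError(f"channel(s) entirely missing: {names}")
    out = 2.0 ** (log2 - med + med.mean())
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def reference_scale(
    values: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Index]:
    """Stage 2: bridge plexes through the R2 reference channel.

    For protein i and channel j in plex p:
    ``out[i, j] = values[i, j] / values[i, R2_p] * a_i`` with ``a_i`` the
    arithmetic mean of the protein's R2 intensities across plexes. Proteins
    with a missing or non-positive R2 intensity in any plex are excluded.

    Returns the scaled matrix and the index of excluded proteins.
    """
    validate_design(design)
    design = design.set_index("channel").loc[values.columns]
    r2_by_plex = {
        plex: sub.index[sub["role"] == "R2"][0] for plex, sub in design.groupby("plex")
    }
    r2 = values[list(r2_by_plex.values())]
    ok = (r2 > 0).all(axis=1) & r2.notna().all(axis=1)
    excluded = values.index[~ok]
    if len(excluded):
        logger.info(
            "reference_scale: %d protein(s) excluded (missing/non-positive R2)",
            len(excluded),
        )
    kept = values.loc[ok]
    a = r2.loc[ok].mean(axis=1)
    out = kept.copy()
    for plex, r2_channel in r2_by_plex.items():
        cols = design.index[design["plex"] == plex]
        denom = kept[r2_channel]
        out[cols] = kept[cols].div(denom, axis=0).mul(a, axis=0)
    return out, excluded


def normalize_pipeline(
    values: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Median centering followed by reference scaling, with a QC report."""
    validate_design(design)
    medians_before = np.log2(values.where(values > 0)).median().to_dict()
    stage1 = median_center(values)
    stage2, excluded = reference_scale(stage1, design)
    medians_after = np.log2(stage1).median().to_dict()
    qc = {
        "channel_log2_median_before": medians_before,
        "channel_log2_median_after_stage1": medians_after,
        "n_proteins_in": int(values.shape[0]),
        "n_proteins_bridged": int(stage2.shape[0]),
        "n_proteins_excluded": int(len(excluded)),
        "excluded_proteins": [str(p) for p in excluded],
    }
    return stage2, qc
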