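"""Median-expression filtering and per-transcript z-score standardization."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import ValidationError


@dataclass
class FilterReport:
    """Kept/dropped bookkeeping of a median filter pass."""

    threshold: float
    n_total: int
    n_kept: int
    n_dropped: int
    table: pd.DataFrame  # transcript_id (index), median, kept


def filter_by_median(
    matrix: pd.DataFrame, threshold: float = 2.0
) -> tuple[pd.DataFrame, FilterReport]:
    """Retain transcripts whose median TPM across all tissues is >= threshold.

    The boundary is inclusive: a transcript sitting exactly at the threshold
    is kept.  Row order is preserved.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if matrix.shape[0] == 0:
        raise ValidationError("cannot filter an empty expression matrix")
    medians = matrix.median(axis=1)
    kept_mask = medians >= threshold
    report = FilterReport(
        threshold=threshold,
        n_total=int(matrix.shape[0]),
        n_kept=int(kept_mask.sum()),
        n_dropped=int((~kept_mask).sum()),
        table=pd.DataFrame({"median": medians, "kept": kept_mask}),
    )
    return matrix.loc[kept_mask], report


def zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each transcript across tissues: z = (x - mean) / sd.

    The sample standard deviation (denominator n - 1) is used.  The z-matrix
    is a heatmap-oriented export; tau is computed on TPM and the PCA
    standardizes per tissue, so neither consumes this output.

    Raises
    ------
    ValidationError
        If any transcript is constant across tissues (sd = 0), listing the
        offending ids.
    """
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        ids = matrix.index[constant].tolist()
        raise ValidationError(f"constant rows (sd = 0), z-score undefined: {ids[:10]}")
    return matrix.sub(mu, axis=0).div(sd, axis=0)
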