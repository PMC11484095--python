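"""The tau tissue-specificity index.

For a transcript with non-negative expression x_1..x_n over n tissues and
max-normalized profile x̂_i = x_i / max(x),

    tau = sum_i (1 - x̂_i) / (n - 1)

tau is 0 for uniform expression, 1 for expression confined to a single
tissue, and invariant to rescaling the whole vector.  Transcripts are binned
as low (tau < 0.5), intermediate (0.5 <= tau < 0.8) or high (tau >= 0.8).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import tau_bin_label
from .io import ValidationError


def tau(expression) -> float:
    """Tissue-specificity index of one expression vector (TPM scale).

    Parameters
    ----------
    expression
        Sequence of >= 2 non-negative finite values with a positive maximum.
    """
    x = np.asarray(expression, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError(f"tau requires a 1-d vector of length >= 2, got shape {x.shape}")
    if not np.isfinite(x).all():
        raise ValueError("tau requires finite values")
    if (x < 0).any():
        raise ValueError("tau is undefined for negative expression values")
    m = x.max()
    if m == 0:
        raise ValueError("tau is undefined for an all-zero expression vector")
    xhat = x / m
    return float((1.0 - xhat).sum() / (x.size - 1))


def tau_bin(value: float, bins: tuple[float, float] = (0.5, 0.8)) -> str:
    """Specificity bin of a tau value: low, intermediate or high."""
    return tau_bin_label(value, bins)


def tau_table(
    matrix: pd.DataFrame, bins: tuple[float, float] = (0.5, 0.8)
) -> pd.DataFrame:
    """Per-transcript tau, max-normalized profile, argmax tissue and bin.

    Returns a DataFrame indexed like ``matrix`` with columns ``tau``,
    ``tau_bin``, ``argmax_tissue`` and one ``xhat_<tissue>`` column per
    tissue.  Argmax ties resolve to the first tissue in column order.

    Raises
    ------
    ValidationError
        If any transcript is all-zero (tau undefined), listing the ids.
    """
    values = matrix.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValidationError("tau requires at least 2 tissues")
    maxima = values.max(axis=1)
    zero = maxima == 0
    if zero.any():
        ids = matrix.index[zero].tolist()
        raise ValidationError(f"tau undefined for all-zero transcripts: {ids[:10]}")
    xhat = values / maxima[:, None]
    n = values.shape[1]
    taus = (1.0 - xhat).sum(axis=1) / (n - 1)
    argmax = matrix.columns[values.argmax(axis=1)]
    out = pd.DataFrame(
        {
            "tau": taus,
            "tau_bin": [tau_bin_label(t, bins) for t in taus],
            "argmax_tissue": argmax,
        },
        index=matrix.index,
    )
    for i, tissue in enumerate(matrix.columns):
        out[f"xhat_{tissue}"] = xhat[:, i]
    return out


def profile_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Extract the max-normalized profile columns of a tau table.

    Returns a transcripts x tissues DataFrame of x̂ values with the
    ``xhat_`` prefix stripped from the column names.
    """
    cols = [c for c in table.columns if c.startswith("xhat_")]
    profile = table[cols].copy()
    profile.columns = [c[len("xhat_"):] for c in cols]
    return profile
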