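"""Correlation-based PCA and per-family confidence ellipses.

Transcripts are the observations and tissues the variables: each tissue
column is centered and scaled to unit sample variance, the tissue correlation
matrix is eigendecomposed, transcript scores are the projections of the
standardized data onto the eigenvectors, and tissue loadings are the
eigenvectors themselves (the biplot's tissue arrows).

For each gene family, a confidence ellipse in a chosen PC pair is built from
the family's score mean and sample covariance; a point is inside the ellipse
iff its squared Mahalanobis distance does not exceed the coverage radius
(chi-square(2) quantile by default, Hotelling-style F radius optionally).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError


@dataclass
class PcaResult:
    """Loadings (tissues x PCs), scores (transcripts x PCs), eigenvalues and
    per-PC variance fractions of a correlation-based PCA."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class EllipseModel:
    """A per-family coverage ellipse in one PC-pair plane."""

    family: str
    pc_pair: tuple[int, int]
    center: np.ndarray
    covariance: np.ndarray
    prob: float
    r2: float
    n_members: int
    mode: str = "chisq"


def correlation_pca(matrix: pd.DataFrame) -> PcaResult:
    """PCA of the tissue correlation matrix (center and scale both true).

    Parameters
    ----------
    matrix
        Transcripts x tissues expression DataFrame with >= 3 transcripts and
        >= 2 tissues, each tissue showing nonzero variance across transcripts.

    Notes
    -----
    Eigenvector sign is fixed deterministically: each loading column is
    flipped so that its largest-absolute entry is positive.  Scores are the
    unstandardized projections of the standardized data, so the score
    covariance reproduces the eigenvalues (up to the n-1 sample convention).
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValidationError(f"correlation PCA requires >= 3 transcripts, got {n}")
    if p < 2:
        raise ValidationError(f"correlation PCA requires >= 2 tissues, got {p}")
    sd = X.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        names = matrix.columns[zero_var].tolist()
        raise ValidationError(f"tissues with zero variance across transcripts: {names}")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-absolute loading entry positive per column
    for j in range(p):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    scores = Z @ eigvecs
    pc_names = [f"PC{i + 1}" for i in range(p)]
    return PcaResult(
        loadings=pd.DataFrame(eigvecs, index=matrix.columns, columns=pc_names),
        scores=pd.DataFrame(scores, index=matrix.index, columns=pc_names),
        eigenvalues=eigvals,
        variance_fraction=eigvals / eigvals.sum(),
    )


def ellipse_radius2(prob: float, n_members: int | None = None, mode: str = "chisq") -> float:
    """Squared Mahalanobis radius of a coverage-``prob`` ellipse in 2-D.

    ``"chisq"`` uses the chi-square(2) quantile −2·ln(1−prob); ``"hotelling"``
    the small-sample radius 2(m−1)/(m−2)·F⁻¹(prob; 2, m−2).
    """
    if not 0.0 < prob < 1.0:
        raise ValueError(f"prob must be in (0, 1), got {prob}")
    if mode == "chisq":
        return float(stats.chi2.ppf(prob, df=2))
    if mode == "hotelling":
        if n_members is None or n_members < 4:
            raise ValueError("hotelling radius requires n_members >= 4")
        m = n_members
        return float(2 * (m - 1) / (m - 2) * stats.f.ppf(prob, 2, m - 2))
    raise ValueError(f"unknown ellipse mode {mode!r}")


def family_ellipse(
    scores: pd.DataFrame,
    members: Sequence[str],
    pc_pair: tuple[int, int] = (1, 2),
    prob: float = 0.70,
    family: str = "",
    mode: str = "chisq",
) -> EllipseModel:
    """Fit the coverage ellipse of one family in a PC-pair plane.

    Parameters
    ----------
    scores
        Transcript scores from :func:`correlation_pca`.
    members
        Transcript ids of the family (>= 3 required).
    pc_pair
        1-based PC indices ``(j, k)`` of the plane.
    prob
        Coverage probability.
    """
    members = list(members)
    if len(members) < 3:
        raise ValidationError(
            f"family ellipse requires >= 3 members, family {family!r} has {len(members)}"
        )
    j, k = pc_pair
    cols = [f"PC{j}", f"PC{k}"]
    missing = [c for c in cols if c not in scores.columns]
    if missing:
        raise ValidationError(f"scores lack components {missing}")
    P = scores.loc[members, cols].to_numpy(dtype=float)
    center = P.mean(axis=0)
    cov = np.cov(P, rowvar=False, ddof=1)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= max(1e-12 * max(eigvals[-1], 0.0), 0.0) or eigvals[-1] <= 0:
        raise ValidationError(
            f"singular covariance for family {family!r} in plane PC{j}/PC{k} "
            "(collinear or degenerate member scores)"
        )
    return EllipseModel(
        family=family,
        pc_pair=(j, k),
        center=center,
        covariance=cov,
        prob=prob,
        r2=ellipse_radius2(prob, n_members=len(members), mode=mode),
        n_members=len(members),
        mode=mode,
    )


def ellipse_membership(model: EllipseModel, points) -> tuple[np.ndarray, np.ndarray]:
    """Inside/outside verdicts and squared Mahalanobis distances for points.

    A point on the boundary (d² == r²) counts as inside.  Accepts one
    2-vector or an (n, 2) array/DataFrame; returns ``(inside, d2)`` as arrays
    of matching length.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2:
        raise ValueError(f"points must be 2-dimensional, got shape {pts.shape}")
    delta = pts - model.center
    d2 = np.einsum("ij,ij->i", delta, np.linalg.solve(model.covariance, delta.T).T)
    return d2 <= model.r2, d2


def membership_table(
    pca: PcaResult,
    families: pd.Series,
    pc_pairs: Sequence[tuple[int, int]] = ((1, 2), (2, 3)),
    prob: float = 0.70,
    mode: str = "chisq",
) -> pd.DataFrame:
    """Own-family ellipse membership of every transcript in every PC pair.

    Parameters
    ----------
    pca
        Result of :func:`correlation_pca`.
    families
        Family label per transcript, indexed like ``pca.scores``.
    Returns
    -------
    Long-form DataFrame with columns ``transcript_id``, ``family``,
    ``pc_pair``, ``d2``, ``r2``, ``inside``.
    """
    families = families.loc[pca.scores.index]
    rows = []
    for j, k in pc_pairs:
        for family, members in families.groupby(families, sort=True).groups.items():
            model = family_ellipse(
                pca.scores, list(members), pc_pair=(j, k), prob=prob, family=str(family), mode=mode
            )
            pts = pca.scores.loc[members, [f"PC{j}", f"PC{k}"]]
            inside, d2 = ellipse_membership(model, pts)
            for tid, ins, dist in zip(members, inside, d2):
                rows.append(
                    {
                        "transcript_id": tid,
                        "family": family,
                        "pc_pair": f"PC{j}/PC{k}",
                        "d2": dist,
                        "r2": model.r2,
                        "inside": bool(ins),
                    }
                )
    out = pd.DataFrame(rows)
    # preserve matrix row order within each pair
    order = {tid: i for i, tid in enumerate(pca.scores.index)}
    out = out.sort_values(
        by=["pc_pair", "transcript_id"], key=lambda s: s.map(order) if s.name == "transcript_id" else s
    ).reset_index(drop=True)
    return out
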