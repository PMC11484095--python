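"""Synthetic family-structured expression atlases with known specificity.

The generator emulates a 14-tissue bulk TPM atlas of three gene families.
Each transcript receives a lognormal baseline shared across tissues, a
per-tissue "profile" effect (lognormal tissue preference with family-specific
scale, correlated within the meristematic block), optional planted
enrichment — a fold-factor f applied in one target tissue or across the
block — and multiplicative lognormal measurement noise.  For a noiseless
planted transcript with k targets among n tissues the tau index is exactly

    tau_theory = (n - k) * (1 - 1/f) / (n - 1)

(k = 1 gives the familiar 1 − 1/f), and the returned ground-truth table
records this value per transcript.  Identical seeds yield bit-identical
outputs.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .config import SimulationConfig, paper_shaped_config

#: Margin applied when forcing transcripts clear of the canonical 2-TPM
#: median filter (active only with low_expression_fraction > 0).
_FILTER_TPM = 2.0


def generate_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate an expression matrix, annotation table and ground truth.

    Returns
    -------
    expression
        Transcripts x tissues TPM DataFrame (index ``transcript_id``).
    annotation
        DataFrame indexed by ``transcript_id`` with columns ``gene_id``,
        ``family``, ``ortholog_name``.
    truth
        DataFrame indexed by ``transcript_id`` with columns ``family``,
        ``planted``, ``target_tissues`` (';'-joined), ``fold`` and
        ``theoretical_tau``.
    """
    rng = np.random.default_rng(config.seed)
    tissues = list(config.tissue_names)
    n_t = len(tissues)
    tissue_index = {t: i for i, t in enumerate(tissues)}
    block_idx = [tissue_index[t] for t in config.block]
    single_pool = [tissue_index[t] for t in (config.target_tissues or tissues)]

    transcript_ids: list[str] = []
    gene_ids: list[str] = []
    ortholog_names: list[str] = []
    family_labels: list[str] = []
    profile_sds: list[float] = []
    planted_flags: list[bool] = []

    # family/gene/transcript bookkeeping; planting is chosen per family
    for family, spec in config.families.items():
        code = _family_code(family)
        counts = _transcript_counts(rng, spec)
        fam_tids = []
        for g, c in enumerate(counts, start=1):
            gene = f"SynGene.{code}.{g:03d}"
            for t in range(1, c + 1):
                tid = f"{gene}.t{t}"
                fam_tids.append(tid)
                transcript_ids.append(tid)
                gene_ids.append(gene)
                ortholog_names.append(f"{code}_{g}.{t}")
                family_labels.append(family)
                profile_sds.append(spec.profile_sd)
        n_fam = len(fam_tids)
        n_spec = int(round(spec.specific_fraction * n_fam))
        chosen = set(rng.choice(n_fam, size=n_spec, replace=False).tolist()) if n_spec else set()
        planted_flags.extend(i in chosen for i in range(n_fam))

    n = len(transcript_ids)
    families = np.array(family_labels)
    planted = np.array(planted_flags)
    prof_sd = np.array(profile_sds)

    deterministic = config.noise_cv == 0

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    log_x = np.tile(baseline[:, None], (1, n_t))

    if not deterministic:
        e = _block_correlated_normal(rng, n, n_t, block_idx, config.block_correlation)
        log_x += prof_sd[:, None] * e - prof_sd[:, None] ** 2 / 2.0

    # planted enrichment; target sets recorded for the truth table
    targets: list[list[int]] = [[] for _ in range(n)]
    log_f = np.log(config.fold_factor)
    for family in config.families:
        fam_planted = np.where(planted & (families == family))[0]
        if fam_planted.size == 0:
            continue
        order = rng.permutation(fam_planted)
        if config.target_tissue_policy == "block":
            n_block = len(order)
        elif config.target_tissue_policy == "single":
            n_block = 0
        else:
            n_block = int(round(config.block_share * len(order)))
        for i in order[:n_block]:
            targets[i] = list(block_idx)
        for i in order[n_block:]:
            targets[i] = [int(rng.choice(single_pool))]
        for i in order:
            log_x[i, targets[i]] += log_f

    if not deterministic:
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        noise = _block_correlated_normal(rng, n, n_t, block_idx, config.block_correlation)
        log_x += sigma * noise - sigma**2 / 2.0

    x = np.exp(log_x)

    if config.low_expression_fraction > 0:
        _force_low_expression(rng, x, planted, config)

    theoretical = np.zeros(n)
    for i in range(n):
        if targets[i]:
            k = len(targets[i])
            theoretical[i] = (n_t - k) * (1.0 - 1.0 / config.fold_factor) / (n_t - 1)

    index = pd.Index(transcript_ids, name="transcript_id")
    expression = pd.DataFrame(x, index=index, columns=tissues)
    annotation = pd.DataFrame(
        {"gene_id": gene_ids, "family": family_labels, "ortholog_name": ortholog_names},
        index=index,
    )
    truth = pd.DataFrame(
        {
            "family": family_labels,
            "planted": planted,
            "target_tissues": [";".join(tissues[j] for j in t) for t in targets],
            "fold": np.where(planted, config.fold_factor, 1.0),
            "theoretical_tau": theoretical,
        },
        index=index,
    )
    return expression, annotation, truth


def _family_code(family: str) -> str:
    code = re.sub(r"\W+", "", family)
    return code or "FAM"


def _transcript_counts(rng: np.random.Generator, spec) -> np.ndarray:
    lo, hi = spec.transcripts_per_gene
    if spec.n_transcripts is None:
        return rng.integers(lo, hi + 1, size=spec.n_genes)
    counts = np.full(spec.n_genes, lo, dtype=int)
    remaining = spec.n_transcripts - counts.sum()
    while remaining > 0:
        for g in rng.permutation(spec.n_genes):
            if remaining == 0:
                break
            if counts[g] < hi:
                counts[g] += 1
                remaining -= 1
    return counts


def _block_correlated_normal(
    rng: np.random.Generator, n: int, n_t: int, block_idx: list[int], rho: float
) -> np.ndarray:
    """Standard-normal matrix whose block columns share correlation rho."""
    e = rng.normal(size=(n, n_t))
    if rho > 0 and len(block_idx) >= 2:
        shared = rng.normal(size=n)
        e[:, block_idx] = np.sqrt(rho) * shared[:, None] + np.sqrt(1.0 - rho) * e[:, block_idx]
    return e


def _force_low_expression(
    rng: np.random.Generator, x: np.ndarray, planted: np.ndarray, config: SimulationConfig
) -> None:
    """Rescale rows so an exact fraction falls below the 2-TPM median filter.

    The lowest-median non-planted rows are forced below (the biologically
    weakly expressed end of the family), planted rows only if unavoidable;
    every remaining row is kept clear of the threshold so the kept count is
    exact regardless of noise draws.
    """
    n = x.shape[0]
    n_low = int(round(config.low_expression_fraction * n))
    medians = np.median(x, axis=1)
    nonplanted = np.where(~planted)[0]
    by_median = nonplanted[np.argsort(medians[nonplanted], kind="stable")]
    low = by_median[:n_low]
    if low.size < n_low:  # more low rows requested than non-planted rows exist
        extra = np.where(planted)[0][np.argsort(medians[planted], kind="stable")]
        low = np.concatenate([low, extra[: n_low - low.size]])
    lo, hi = config.low_median_range
    x[low] *= (rng.uniform(lo, hi, size=low.size) / np.median(x[low], axis=1))[:, None]
    high = np.setdiff1d(np.arange(n), low)
    risky = high[np.median(x[high], axis=1) < 1.25 * _FILTER_TPM]
    if risky.size:
        x[risky] *= (
            rng.uniform(2 * _FILTER_TPM, 25 * _FILTER_TPM, size=risky.size)
            / np.median(x[risky], axis=1)
        )[:, None]


def make_fixture(kind: str, seed: int = 0):
    """Canned fixtures: ``"small"`` (hand-checkable) or ``"paper_shaped"``.

    ``"small"`` is a 10-transcript x 4-tissue matrix containing the classic
    tau oracle row (8, 2, 2, 2), a uniform row, a single-tissue row, an
    all-zero row (degenerate input) and rows straddling the median-2 filter.
    ``"paper_shaped"`` draws a 221-transcript atlas of which exactly 133 pass
    the filter.
    """
    if kind == "paper_shaped":
        return generate_expression(paper_shaped_config(seed=seed))
    if kind != "small":
        raise ValueError(f"unknown fixture kind {kind!r}")
    tissues = ["hypocotyl", "AM", "root", "young leaf"]
    rows = {
        "t01": [8.0, 2.0, 2.0, 2.0],    # tau = 0.75 by hand
        "t02": [5.0, 5.0, 5.0, 5.0],    # tau = 0
        "t03": [0.0, 0.0, 7.0, 0.0],    # tau = 1; dropped by the filter
        "t04": [0.0, 0.0, 0.0, 0.0],    # degenerate: tau undefined
        "t05": [2.0, 4.0, 6.0, 8.0],
        "t06": [2.0, 2.0, 2.0, 2.0],    # median exactly at the filter boundary
        "t07": [1.0, 1.0, 1.0, 1.0],    # below the filter
        "t08": [20.0, 2.0, 2.0, 3.0],
        "t09": [3.0, 30.0, 3.0, 3.0],
        "t10": [1.0, 2.0, 3.0, 100.0],
        "t11": [4.0, 8.0, 2.0, 6.0],
        "t12": [9.0, 3.0, 6.0, 3.0],
    }
    index = pd.Index(rows.keys(), name="transcript_id")
    expression = pd.DataFrame(list(rows.values()), index=index, columns=tissues)
    # each family keeps >= 3 transcripts after the median-2 filter
    fam = ["Aux/IAA"] * 4 + ["ARF"] * 3 + ["TIR1/AFB"] * 3 + ["Aux/IAA", "ARF"]
    annotation = pd.DataFrame(
        {
            "gene_id": [f"SynGene.small.{i:03d}" for i in range(1, 13)],
            "family": fam,
            "ortholog_name": [f"small_{i}.1" for i in range(1, 13)],
        },
        index=index,
    )
    truth = pd.DataFrame(
        {
            "family": fam,
            "planted": [False] * 12,
            "target_tissues": [""] * 12,
            "fold": [1.0] * 12,
            "theoretical_tau": [0.0] * 12,
        },
        index=index,
    )
    return expression, annotation, truth
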