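"""Self-evaluation of the screen against simulated ground truth.

Two entry points: :func:`evaluate_recovery` reruns the full screen on many
seeded synthetic atlases and scores candidate calls against the planted
truth (sensitivity, false-positive rate, omnibus rejection and post hoc flag
rates), and :func:`type_one_error_rate` measures the empirical size of the
tie-corrected Kruskal–Wallis test under the null.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig, SimulationConfig, paper_shaped_config
from .family_stats import dunn_posthoc, kruskal_wallis
from .ordination import correlation_pca, membership_table
from .preprocess import filter_by_median
from .screen import classify_candidates
from .simulate import generate_expression
from .specificity import tau_table


def replicate_seeds(base_seed: int, n: int) -> np.ndarray:
    """Derive n child seeds (< 2^31) from one base seed."""
    return np.random.SeedSequence(base_seed).generate_state(n) % (2**31)


def screen_replicate(
    sim_config: SimulationConfig, run_config: RunConfig | None = None
) -> dict:
    """Run the screen on one synthetic atlas and score it against the truth.

    Returns the per-replicate confusion counts, the omnibus statistic and
    p-value, and whether the Dunn test separates the elevated family from
    both of the others at Holm-adjusted p < 0.05.
    """
    run_config = run_config or RunConfig(n_boot=0)
    expression, annotation, truth = generate_expression(sim_config)
    kept, _ = filter_by_median(expression, run_config.median_threshold)
    taus = tau_table(kept, run_config.tau_bins)
    pca = correlation_pca(kept)
    families = annotation.loc[kept.index, "family"]
    membership = membership_table(
        pca, families, run_config.pc_pairs, run_config.ellipse_prob, run_config.ellipse_mode
    )
    omnibus = kruskal_wallis(taus["tau"].to_numpy(), families.to_numpy(), n_boot=0)
    dunn = dunn_posthoc(taus["tau"].to_numpy(), families.to_numpy())
    candidates = classify_candidates(taus, membership, annotation, run_config)

    planted = truth.loc[kept.index, "planted"].to_numpy(dtype=bool)
    called = (candidates["call"] != "not_candidate").to_numpy()
    elevated = max(
        sim_config.families, key=lambda fam: sim_config.families[fam].specific_fraction
    )
    others = [fam for fam in families.unique() if fam != elevated]
    dunn_flags = []
    for other in others:
        mask = ((dunn.group1 == elevated) & (dunn.group2 == other)) | (
            (dunn.group1 == other) & (dunn.group2 == elevated)
        )
        dunn_flags.append(bool((dunn.loc[mask, "p_adj"] < 0.05).all()) if mask.any() else False)
    return {
        "n_kept": int(len(kept)),
        "true_positives": int((called & planted).sum()),
        "false_positives": int((called & ~planted).sum()),
        "n_planted": int(planted.sum()),
        "n_nonplanted": int((~planted).sum()),
        "h": omnibus.h,
        "p_value": omnibus.p_value,
        "epsilon_squared": omnibus.epsilon_squared,
        "dunn_flags_both": all(dunn_flags) and len(dunn_flags) > 0,
    }


def evaluate_recovery(
    n_replicates: int = 100,
    base_seed: int = 0,
    sim_config_factory=paper_shaped_config,
    run_config: RunConfig | None = None,
    p_threshold: float = 0.01,
) -> dict:
    """Aggregate screen-vs-truth metrics over seeded replicates.

    Sensitivity and the false-positive rate are pooled over all replicates'
    planted / non-planted transcripts that passed the median filter.
    """
    seeds = replicate_seeds(base_seed, n_replicates)
    tp = fp = n_planted = n_nonplanted = 0
    rejections, dunn_hits, hs, eps = 0, 0, [], []
    for seed in seeds:
        rep = screen_replicate(sim_config_factory(seed=int(seed)), run_config)
        tp += rep["true_positives"]
        fp += rep["false_positives"]
        n_planted += rep["n_planted"]
        n_nonplanted += rep["n_nonplanted"]
        rejections += rep["p_value"] < p_threshold
        dunn_hits += rep["dunn_flags_both"]
        hs.append(rep["h"])
        eps.append(rep["epsilon_squared"])
    return {
        "n_replicates": n_replicates,
        "sensitivity": tp / n_planted,
        "false_positive_rate": fp / n_nonplanted,
        "omnibus_rejection_rate": rejections / n_replicates,
        "dunn_flag_rate": dunn_hits / n_replicates,
        "h_mean": float(np.mean(hs)),
        "epsilon_squared_mean": float(np.mean(eps)),
        "n_planted_total": n_planted,
        "n_nonplanted_total": n_nonplanted,
    }


def type_one_error_rate(
    n_sims: int = 2000,
    n_per_group: int = 45,
    k_groups: int = 3,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical size of the Kruskal–Wallis test under equal continuous nulls."""
    rng = np.random.default_rng(seed)
    groups = np.repeat([f"g{i}" for i in range(k_groups)], n_per_group)
    rejections = 0
    for _ in range(n_sims):
        values = rng.normal(size=k_groups * n_per_group)
        res = kruskal_wallis(values, groups, n_boot=0)
        rejections += res.p_value < alpha
    return rejections / n_sims
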