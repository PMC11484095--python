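"""Candidate classification: ellipse escape x tau bin x tissue association.

A transcript is a strong candidate when it (i) falls outside its own family's
confidence ellipse in at least one examined PC pair, (ii) has high tau
(>= 0.8 by default), and (iii) is associated (max-normalized profile above
the intermediate cutoff) with at least one tissue of the configured
rapid-canopy-cover set.  With intermediate tau the call is an intermediate
candidate, flagged for case-by-case review; everything else is not a
candidate.
"""

from __future__ import annotations

import pandas as pd

from .config import RunConfig
from .io import ValidationError
from .specificity import profile_matrix

CALL_LABELS = ("strong_candidate", "intermediate_candidate", "not_candidate")


def tissue_association(
    profile: pd.Series, cutoffs: tuple[float, float] = (0.5, 0.8)
) -> tuple[list[str], list[str]]:
    """Split tissues into strongly / intermediately associated sets.

    Parameters
    ----------
    profile
        Max-normalized expression x̂ per tissue (index = tissue names).
    cutoffs
        ``(intermediate, strong)`` with 0 < intermediate < strong <= 1.

    Returns
    -------
    ``(strong, intermediate)`` tissue lists in profile order: strong has
    x̂ >= strong cutoff, intermediate has intermediate <= x̂ < strong.
    """
    inter, strong = cutoffs
    if not 0.0 < inter < strong <= 1.0:
        raise ValueError(f"cutoffs must satisfy 0 < intermediate < strong <= 1, got {cutoffs}")
    strong_set = [t for t, v in profile.items() if v >= strong]
    inter_set = [t for t, v in profile.items() if inter <= v < strong]
    return strong_set, inter_set


def classify_candidates(
    tau_tbl: pd.DataFrame,
    membership: pd.DataFrame,
    annotation: pd.DataFrame,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Combine tau, ellipse membership and tissue association into calls.

    Parameters
    ----------
    tau_tbl
        Output of :func:`tauscreen.specificity.tau_table`.
    membership
        Long-form table from :func:`tauscreen.ordination.membership_table`
        (one row per transcript per examined PC pair).
    annotation
        Annotation indexed by transcript id (family, ortholog_name).
    config
        Thresholds and the RCC tissue set; defaults to :class:`RunConfig()`.

    Returns
    -------
    One row per transcript: family, ortholog_name, tau, tau_bin, per-pair
    inside flags and distances, associated tissue sets, RCC overlap, the
    final call and a review flag.  Every transcript receives exactly one
    call.
    """
    config = config or RunConfig()
    transcripts = tau_tbl.index
    missing = transcripts.difference(annotation.index)
    if len(missing) > 0:
        raise ValidationError(f"transcripts missing from annotation: {missing[:5].tolist()}")
    pair_labels = sorted(membership["pc_pair"].unique())
    inside_wide = membership.pivot(index="transcript_id", columns="pc_pair", values="inside")
    d2_wide = membership.pivot(index="transcript_id", columns="pc_pair", values="d2")
    missing = transcripts.difference(inside_wide.index)
    if len(missing) > 0:
        raise ValidationError(
            f"transcripts missing from ellipse membership: {missing[:5].tolist()}"
        )
    inside_wide = inside_wide.loc[transcripts].astype(bool)
    d2_wide = d2_wide.loc[transcripts]

    profiles = profile_matrix(tau_tbl)
    rcc = set(config.rcc_tissues)
    rows = []
    for tid in transcripts:
        strong_set, inter_set = tissue_association(
            profiles.loc[tid], config.association_cutoffs
        )
        associated = strong_set + inter_set
        overlap = [t for t in associated if t in rcc]
        outside_any = bool((~inside_wide.loc[tid]).any())
        bin_label = tau_tbl.loc[tid, "tau_bin"]
        if outside_any and overlap and bin_label == "high":
            call = "strong_candidate"
        elif outside_any and overlap and bin_label == "intermediate":
            call = "intermediate_candidate"
        else:
            call = "not_candidate"
        flags = []
        if len(strong_set) == len(profiles.columns):
            flags.append("degenerate_profile")  # flat profile: every tissue "strong"
        if call == "intermediate_candidate":
            flags.append("case_by_case")
        row = {
            "family": annotation.loc[tid, "family"],
            "ortholog_name": annotation.loc[tid, "ortholog_name"],
            "tau": tau_tbl.loc[tid, "tau"],
            "tau_bin": bin_label,
        }
        for pair in pair_labels:
            key = pair.replace("/", "_")
            row[f"inside_{key}"] = bool(inside_wide.loc[tid, pair])
            row[f"d2_{key}"] = d2_wide.loc[tid, pair]
        row.update(
            {
                "outside_any": outside_any,
                "strong_tissues": ";".join(strong_set),
                "intermediate_tissues": ";".join(inter_set),
                "rcc_overlap": ";".join(overlap),
                "call": call,
                "review_flag": ";".join(flags),
            }
        )
        rows.append(row)
    out = pd.DataFrame(rows, index=transcripts)
    out.index.name = "transcript_id"
    return out


def summarize(candidates: pd.DataFrame) -> dict:
    """Counts per call and family, per-tissue tallies, ranked strong list."""
    calls = {label: 0 for label in CALL_LABELS}
    if len(candidates):
        calls.update(candidates["call"].value_counts().to_dict())
    per_family: dict[str, dict[str, int]] = {}
    if len(candidates):
        for (family, call), count in candidates.groupby(["family", "call"]).size().items():
            per_family.setdefault(str(family), {label: 0 for label in CALL_LABELS})[str(call)] = int(count)
    tissue_tally: dict[str, int] = {}
    strong_rows = candidates[candidates["call"] == "strong_candidate"] if len(candidates) else candidates
    is_candidate = (
        candidates[candidates["call"] != "not_candidate"] if len(candidates) else candidates
    )
    for overlap in is_candidate.get("rcc_overlap", pd.Series(dtype=str)):
        for tissue in str(overlap).split(";"):
            if tissue:
                tissue_tally[tissue] = tissue_tally.get(tissue, 0) + 1
    if len(strong_rows):
        ranked = strong_rows.reset_index().sort_values(
            ["tau", "transcript_id"], ascending=[False, True], kind="stable"
        )
        strong_list = ranked["transcript_id"].tolist()
    else:
        strong_list = []
    return {
        "n_transcripts": int(len(candidates)),
        "calls": {k: int(v) for k, v in calls.items()},
        "calls_by_family": per_family,
        "candidate_tissue_tally": tissue_tally,
        "strong_candidates_by_tau": strong_list,
    }
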