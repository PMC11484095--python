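"""Candidate classification rules and summaries."""

import numpy as np
import pandas as pd
import pytest

from tauscreen import RunConfig, classify_candidates, summarize, tissue_association


def make_profile(values: dict) -> pd.Series:
    return pd.Series(values, dtype=float)


class TestTissueAssociation:
    def test_single_strong_tissue(self):
        profile = make_profile({"SAM6D": 1.0, "root": 0.3, "OF": 0.2})
        strong, inter = tissue_association(profile, (0.5, 0.8))
        assert strong == ["SAM6D"] and inter == []

    def test_intermediate_am_contribution(self):
        # a 0.63 maximal-component value in AM is an intermediate association
        profile = make_profile({"AM": 0.63, "SAM6D": 1.0, "root": 0.1})
        strong, inter = tissue_association(profile, (0.5, 0.8))
        assert "AM" in inter and "SAM6D" in strong

    def test_flat_profile_everything_strong(self):
        profile = make_profile({"A": 1.0, "B": 1.0, "C": 1.0})
        strong, inter = tissue_association(profile, (0.5, 0.8))
        assert strong == ["A", "B", "C"] and inter == []

    def test_bad_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            tissue_association(make_profile({"A": 1.0}), (0.8, 0.5))


def build_inputs(rows):
    """rows: list of (tid, family, tau, xhats dict, inside12, inside23)."""
    tissues = ["hypocotyl", "AM", "root", "OF"]
    tau_rows, mem_rows, annot_rows = [], [], []
    for tid, family, tau_value, xhats, in12, in23 in rows:
        rec = {
            "tau": tau_value,
            "tau_bin": ("high" if tau_value >= 0.8 else "intermediate" if tau_value >= 0.5 else "low"),
            "argmax_tissue": max(xhats, key=xhats.get),
        }
        for t in tissues:
            rec[f"xhat_{t}"] = xhats.get(t, 0.1)
        tau_rows.append(pd.Series(rec, name=tid))
        for pair, inside in (("PC1/PC2", in12), ("PC2/PC3", in23)):
            mem_rows.append(
                {"transcript_id": tid, "family": family, "pc_pair": pair,
                 "d2": 1.0 if inside else 9.0, "r2": 2.41, "inside": inside}
            )
        annot_rows.append(pd.Series(
            {"gene_id": f"g_{tid}", "family": family, "ortholog_name": f"o_{tid}"}, name=tid))
    tau_tbl = pd.DataFrame(tau_rows)
    tau_tbl.index.name = "transcript_id"
    annot = pd.DataFrame(annot_rows)
    annot.index.name = "transcript_id"
    return tau_tbl, pd.DataFrame(mem_rows), annot


CONFIG = RunConfig(rcc_tissues=("hypocotyl", "AM"))


class TestClassify:
    def test_strong_candidate(self):
        # outside PC1/2, tau 0.82, strong RCC tissue: the canonical strong call
        tau_tbl, mem, annot = build_inputs(
            [("t1", "ARF", 0.82, {"hypocotyl": 1.0}, False, True)]
        )
        out = classify_candidates(tau_tbl, mem, annot, CONFIG)
        assert out.loc["t1", "call"] == "strong_candidate"
        assert out.loc["t1", "rcc_overlap"] == "hypocotyl"

    def test_inside_everywhere_low_tau_not_candidate(self):
        tau_tbl, mem, annot = build_inputs(
            [("t1", "ARF", 0.3, {"hypocotyl": 1.0}, True, True)]
        )
        out = classify_candidates(tau_tbl, mem, annot, CONFIG)
        assert out.loc["t1", "call"] == "not_candidate"

    def test_outside_only_in_second_plane_intermediate(self):
        # inside PC1/2 but outside PC2/3 with tau 0.67: intermediate candidate
        tau_tbl, mem, annot = build_inputs(
            [("t1", "Aux/IAA", 0.67, {"hypocotyl": 1.0}, True, False)]
        )
        out = classify_candidates(tau_tbl, mem, annot, CONFIG)
        assert out.loc["t1", "call"] == "intermediate_candidate"
        assert "case_by_case" in out.loc["t1", "review_flag"]

    def test_high_tau_without_rcc_overlap_not_candidate(self):
        tau_tbl, mem, annot = build_inputs(
            [("t1", "ARF", 0.9, {"root": 1.0, "OF": 0.6}, False, False)]
        )
        out = classify_candidates(tau_tbl, mem, annot, CONFIG)
        assert out.loc["t1", "call"] == "not_candidate"

    def test_every_transcript_gets_exactly_one_call(self, rng):
        rows = []
        for i in range(60):
            tau_value = float(rng.uniform(0, 1))
            xh = {"hypocotyl": float(rng.uniform(0, 1)), "AM": float(rng.uniform(0, 1))}
            rows.append((f"t{i}", rng.choice(["ARF", "Aux/IAA"]), tau_value, xh,
                         bool(rng.integers(2)), bool(rng.integers(2))))
        tau_tbl, mem, annot = build_inputs(rows)
        out = classify_candidates(tau_tbl, mem, annot, CONFIG)
        assert len(out) == 60
        assert out["call"].isin(["strong_candidate", "intermediate_candidate", "not_candidate"]).all()

    def test_raising_tau_never_demotes(self):
        base = [("t1", "ARF", 0.6, {"hypocotyl": 1.0}, False, True)]
        tau_tbl, mem, annot = build_inputs(base)
        call_low = classify_candidates(tau_tbl, mem, annot, CONFIG).loc["t1", "call"]
        raised = [("t1", "ARF", 0.85, {"hypocotyl": 1.0}, False, True)]
        tau_tbl2, mem2, annot2 = build_inputs(raised)
        call_high = classify_candidates(tau_tbl2, mem2, annot2, CONFIG).loc["t1", "call"]
        rank = {"not_candidate": 0, "intermediate_candidate": 1, "strong_candidate": 2}
        assert rank[call_high] >= rank[call_low]

    def test_missing_membership_is_error(self):
        tau_tbl, mem, annot = build_inputs(
            [("t1", "ARF", 0.82, {"hypocotyl": 1.0}, False, True)]
        )
        from tauscreen.io import ValidationError

        with pytest.raises(ValidationError, match="membership"):
            classify_candidates(tau_tbl, mem[mem.transcript_id != "t1"], annot, CONFIG)


class TestSummarize:
    def test_empty_table(self):
        empty = pd.DataFrame(columns=["family", "call", "tau", "rcc_overlap"])
        summary = summarize(empty)
        assert summary["n_transcripts"] == 0
        assert summary["calls"]["strong_candidate"] == 0
        assert summary["strong_candidates_by_tau"] == []

    def test_counts_partition_total(self, rng):
        rows = []
        for i in range(40):
            rows.append((f"t{i}", "ARF", float(rng.uniform(0, 1)),
                         {"hypocotyl": 1.0}, bool(rng.integers(2)), bool(rng.integers(2))))
        tau_tbl, mem, annot = build_inputs(rows)
        out = classify_candidates(tau_tbl, mem, annot, CONFIG)
        summary = summarize(out)
        assert sum(summary["calls"].values()) == summary["n_transcripts"] == 40

    def test_recovers_planted_strong_candidates(self):
        rows = [
            ("t1", "ARF", 0.95, {"hypocotyl": 1.0}, False, False),
            ("t2", "ARF", 0.85, {"AM": 1.0}, True, False),
            ("t3", "Aux/IAA", 0.90, {"hypocotyl": 1.0}, False, True),
            ("t4", "Aux/IAA", 0.40, {"hypocotyl": 1.0}, False, True),
        ]
        tau_tbl, mem, annot = build_inputs(rows)
        summary = summarize(classify_candidates(tau_tbl, mem, annot, CONFIG))
        assert summary["calls"]["strong_candidate"] == 3
        # sorted by tau descending
        assert summary["strong_candidates_by_tau"] == ["t1", "t3", "t2"]
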