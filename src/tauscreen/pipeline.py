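"""End-to-end orchestration of the screen with logging and a run manifest.

Stage order: tissue subsetting (optional aerial-7 mode) -> median filter ->
tau table -> correlation PCA -> per-family ellipses and membership in each
configured PC pair -> family rank statistics -> candidate classification ->
report writing.  Every output is a deterministic TSV (plus JSON metadata), so
two runs with the same inputs, configuration and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._version import __version__ as _version
from .config import AERIAL_TISSUES, RunConfig, SimulationConfig
from .family_stats import compare_families
from .io import (
    ValidationError,
    check_annotation_covers,
    read_annotation,
    read_expression,
    sha256_file,
    write_annotation,
    write_expression,
    write_results,
)
from .ordination import correlation_pca, membership_table
from .preprocess import filter_by_median, zscore
from .screen import classify_candidates, summarize
from .simulate import generate_expression
from .specificity import tau_table

logger = logging.getLogger("tauscreen")


class PipelineError(RuntimeError):
    """A stage of the pipeline failed; the message names the stage."""


@dataclass
class RunManifest:
    """Everything needed to audit or reproduce one pipeline run."""

    config: dict
    seed: int
    version: str
    inputs: dict[str, str]
    outputs: dict[str, str]
    timings: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str, func, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = func(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    return result, time.perf_counter() - t0


def run_pipeline(
    expression_path: str | Path,
    annotation_path: str | Path,
    config: RunConfig | str | Path | None,
    out_dir: str | Path,
) -> RunManifest:
    """Run the full screen and write all result tables to ``out_dir``.

    Parameters
    ----------
    expression_path, annotation_path
        TSV inputs (TPM matrix; transcript annotation).
    config
        A :class:`RunConfig`, a path to a JSON/YAML config file, or ``None``
        for defaults.
    out_dir
        Output directory (created if needed).
    """
    if config is None:
        config = RunConfig()
    elif not isinstance(config, RunConfig):
        config = RunConfig.from_file(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _attach_logfile(out_dir)
    timings: dict[str, float] = {}

    expression, timings["read_expression"] = _stage("read_expression", read_expression, expression_path)
    annotation, timings["read_annotation"] = _stage("read_annotation", read_annotation, annotation_path)
    _, timings["check_annotation"] = _stage(
        "check_annotation", check_annotation_covers, expression, annotation
    )
    logger.info("loaded %d transcripts x %d tissues", *expression.shape)

    if config.tissue_subset_mode == "aerial7":
        missing = [t for t in AERIAL_TISSUES if t not in expression.columns]
        if missing:
            raise PipelineError(f"stage 'tissue_subset' failed: aerial tissues absent: {missing}")
        expression = expression[list(AERIAL_TISSUES)]
        logger.info("aerial-7 mode: restricted to %d tissues", expression.shape[1])

    (kept, filter_report), timings["filter"] = _stage(
        "filter", filter_by_median, expression, config.median_threshold
    )
    logger.info("median filter (>= %g TPM): kept %d / %d", config.median_threshold,
                filter_report.n_kept, filter_report.n_total)
    if filter_report.n_kept == 0:
        raise PipelineError("stage 'filter' failed: no transcripts passed the median filter")

    zmat, timings["zscore"] = _stage("zscore", _zscore_export, kept)
    taus, timings["tau"] = _stage("tau", tau_table, kept, config.tau_bins)
    pca, timings["pca"] = _stage("pca", correlation_pca, kept)
    membership, timings["ellipses"] = _stage(
        "ellipses",
        membership_table,
        pca,
        annotation.loc[kept.index, "family"],
        config.pc_pairs,
        config.ellipse_prob,
        config.ellipse_mode,
    )
    comparison, timings["family_stats"] = _stage(
        "family_stats",
        compare_families,
        taus["tau"].to_numpy(),
        annotation.loc[kept.index, "family"].to_numpy(),
        config.n_boot,
        config.ci_level,
        config.posthoc_adjust,
        config.seed,
    )
    logger.info("Kruskal-Wallis H = %.3f (df=%d, p = %.3g, eps^2 = %.3f)",
                comparison.h, comparison.df, comparison.p_value, comparison.epsilon_squared)
    candidates, timings["classify"] = _stage(
        "classify", classify_candidates, taus, membership, annotation, config
    )
    summary = summarize(candidates)
    logger.info("calls: %s", summary["calls"])

    omnibus = pd.DataFrame(
        [
            {
                "H": comparison.h,
                "df": comparison.df,
                "p_value": comparison.p_value,
                "epsilon_squared": comparison.epsilon_squared,
                "ci_low": comparison.ci[0] if comparison.ci else float("nan"),
                "ci_high": comparison.ci[1] if comparison.ci else float("nan"),
                "n": comparison.n,
            }
        ]
    )
    variance = pd.DataFrame(
        {
            "eigenvalue": pca.eigenvalues,
            "variance_fraction": pca.variance_fraction,
        },
        index=pca.loadings.columns,
    )
    variance.index.name = "component"

    tables = {
        "filter_report": filter_report.table,
        "zscore_matrix": zmat,
        "tau_table": taus,
        "pca_scores": pca.scores,
        "pca_loadings": pca.loadings,
        "pca_variance": variance,
        "ellipse_membership": membership.set_index("transcript_id"),
        "stats_omnibus": omnibus.set_index(pd.Index([0], name="row")),
        "posthoc_dunn": comparison.posthoc_dunn.set_index(pd.Index(range(len(comparison.posthoc_dunn)), name="row")),
        "posthoc_wilcoxon": comparison.posthoc_wilcoxon.set_index(pd.Index(range(len(comparison.posthoc_wilcoxon)), name="row")),
        "candidates": candidates,
    }
    outputs = write_results(
        tables, out_dir, config=config.to_dict(), seed=config.seed, version=_version
    )
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    outputs["summary.json"] = sha256_file(summary_path)

    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        version=_version,
        inputs={
            str(expression_path): sha256_file(expression_path),
            str(annotation_path): sha256_file(annotation_path),
        },
        outputs=outputs,
        timings={k: round(v, 6) for k, v in timings.items()},
    )
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


def simulate_command(
    config: SimulationConfig | str | Path | None, out_dir: str | Path
) -> dict[str, Path]:
    """Generate a synthetic atlas and write expression/annotation/truth TSVs.

    The configuration is validated before any file is created.
    """
    if config is None:
        config = SimulationConfig()
    elif not isinstance(config, SimulationConfig):
        config = SimulationConfig.from_file(config)
    expression, annotation, truth = generate_expression(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out_dir / "expression.tsv",
        "annotation": out_dir / "annotation.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_expression(expression, paths["expression"])
    write_annotation(annotation, paths["annotation"])
    truth_out = truth.copy()
    truth_out.index.name = "transcript_id"
    truth_out.to_csv(paths["truth"], sep="\t", lineterminator="\n")
    logger.info("simulated %d transcripts x %d tissues into %s", *expression.shape, out_dir)
    return paths


def _zscore_export(kept: pd.DataFrame) -> pd.DataFrame:
    """Heatmap z-matrix; constant rows are skipped with a warning (the strict
    per-row contract lives in :func:`tauscreen.preprocess.zscore`)."""
    sd = kept.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "z-score export skips %d constant transcripts: %s",
            int(constant.sum()), kept.index[constant].tolist()[:10],
        )
        kept = kept.loc[~constant]
    return zscore(kept)


def _attach_logfile(out_dir: Path) -> None:
    """Mirror pipeline logging into <out_dir>/pipeline.log (idempotent)."""
    log_path = out_dir / "pipeline.log"
    for handler in logger.handlers:
        if isinstance(handler, logging.FileHandler) and handler.baseFilename == str(log_path):
            return
    handler = logging.FileHandler(log_path, encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
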