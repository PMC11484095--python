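"""Reading and writing of expression matrices, annotation and result tables.

Everything is tab-separated UTF-8 text with '.' decimals; expression matrices
carry one header row of tissue names and a leading transcript-id column.
Validation errors name the offending rows/cells so malformed inputs fail
loudly and early.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ("transcript_id", "gene_id", "family", "ortholog_name")


class ValidationError(ValueError):
    """Raised when an input table violates its contract."""


def validate_expression(df: pd.DataFrame, context: str = "expression matrix") -> pd.DataFrame:
    """Validate a transcripts x tissues expression matrix in place.

    Checks unique labels, at least two tissues, and finite non-negative
    numeric values; the first offending cells are reported with row/column
    coordinates.
    """
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{context}: duplicate transcript ids {dupes[:5]}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{context}: duplicate tissue names {dupes[:5]}")
    if df.shape[1] < 2:
        raise ValidationError(f"{context}: at least 2 tissues required, got {df.shape[1]}")
    if df.shape[0] == 0:
        raise ValidationError(f"{context}: no transcripts")
    try:
        # numpy's parser round-trips repr() output exactly
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        converted = df.apply(pd.to_numeric, errors="coerce")
        bad = converted.isna() & df.notna() & (df.astype(str).replace("nan", np.nan).notna())
        cells = _first_cells(bad)
        raise ValidationError(f"{context}: non-numeric cells at {cells}") from None
    numeric = pd.DataFrame(values, index=df.index, columns=df.columns)
    if np.isnan(values).any():
        cells = _first_cells(numeric.isna())
        raise ValidationError(f"{context}: missing values at {cells} (ragged or empty cells)")
    if not np.isfinite(values).all():
        cells = _first_cells(pd.DataFrame(~np.isfinite(values), index=df.index, columns=df.columns))
        raise ValidationError(f"{context}: non-finite values at {cells}")
    if (values < 0).any():
        cells = _first_cells(numeric < 0)
        raise ValidationError(f"{context}: negative values at {cells}")
    return numeric


def _first_cells(mask: pd.DataFrame, limit: int = 5) -> list[tuple]:
    rows, cols = np.nonzero(mask.to_numpy())
    return [(mask.index[r], mask.columns[c]) for r, c in zip(rows[:limit], cols[:limit])]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a TSV expression matrix (TPM) into a validated DataFrame.

    Row and column order are preserved; the index is the transcript id.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = "transcript_id"
    return validate_expression(df, context=str(path))


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df = df.copy()
    df.index.name = "transcript_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the transcript -> gene -> family -> ortholog annotation table."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing annotation columns {missing}")
    if df["transcript_id"].duplicated().any():
        dupes = df.loc[df["transcript_id"].duplicated(), "transcript_id"].unique().tolist()
        raise ValidationError(f"{path}: duplicate transcript_id {dupes[:5]}")
    if (df["family"].isna() | (df["family"].str.strip() == "")).any():
        bad = df.loc[df["family"].isna() | (df["family"].str.strip() == ""), "transcript_id"].tolist()
        raise ValidationError(f"{path}: empty family for transcripts {bad[:5]}")
    return df.set_index("transcript_id")


def write_annotation(df: pd.DataFrame, path: str | Path) -> None:
    out = df.reset_index() if df.index.name == "transcript_id" else df
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def check_annotation_covers(expression: pd.DataFrame, annotation: pd.DataFrame) -> None:
    """Require every transcript of the matrix to be annotated (pipeline mode)."""
    missing = expression.index.difference(annotation.index)
    if len(missing) > 0:
        raise ValidationError(
            f"{len(missing)} transcripts missing from annotation, e.g. {missing[:5].tolist()}"
        )


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: dict | None = None,
    seed: int | None = None,
    version: str | None = None,
) -> dict:
    """Write result tables as deterministic TSVs plus a JSON metadata file.

    Returns a manifest mapping each written file name to its sha256 digest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name in sorted(tables):
        table = tables[name]
        fname = f"{name}.tsv"
        fpath = out_dir / fname
        table.to_csv(fpath, sep="\t", lineterminator="\n")
        manifest[fname] = sha256_file(fpath)
    meta = {
        "config": config,
        "seed": seed,
        "version": version,
        "files": manifest,
    }
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    manifest["run_metadata.json"] = sha256_file(meta_path)
    return manifest


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
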