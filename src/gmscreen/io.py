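"""Tab-separated text I/O conventions shared by every pipeline stage.

All files are UTF-8 TSV with a header row. Feature-by-sample matrices carry
the feature id in the first column; missing values are written as the token
``NA``. Matrices are written at full float precision so that a write/read
cycle is lossless; derived statistics tables (``pairs.tsv``) are written with
6 significant digits.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd

NA_TOKEN = "NA"

#: column order of the pair-statistics table
PAIR_COLUMNS = [
    "gene_id",
    "metabolite_id",
    "n_complete",
    "pcc",
    "pqc",
    "n_outliers",
    "pcc_rm",
    "pqc_rm",
    "category",
]


class InputFileError(FileNotFoundError):
    """A declared input file is missing; the message names the file."""


def _require(path: str) -> str:
    if not os.path.exists(path):
        raise InputFileError(f"required input file not found: {path}")
    return path


def write_matrix(df: pd.DataFrame, path: str, index_label: str = "feature_id") -> None:
    """Write a feature-by-sample matrix; NaN becomes the NA token."""
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, index_label=index_label)


def read_matrix(path: str) -> pd.DataFrame:
    df = pd.read_csv(_require(path), sep="\t", index_col=0, na_values=[NA_TOKEN],
                     keep_default_na=False, float_precision="round_trip")
    return df.astype(float)


def write_table(df: pd.DataFrame, path: str, float_format: str | None = None) -> None:
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, index=False, float_format=float_format)


def read_table(path: str, required: Iterable[str] = ()) -> pd.DataFrame:
    try:
        df = pd.read_csv(_require(path), sep="\t", na_values=[NA_TOKEN],
                         keep_default_na=False)
    except pd.errors.ParserError as exc:  # pragma: no cover - malformed input path
        raise ValueError(f"malformed TSV in {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_pairs(records: pd.DataFrame, path: str) -> None:
    """Serialize the pair-statistics table with 6 significant digits."""
    out = records.reindex(columns=PAIR_COLUMNS)
    write_table(out, path, float_format="%.6g")


def read_pairs(path: str) -> pd.DataFrame:
    df = read_table(path, required=["gene_id", "metabolite_id"])
    for col in ("pcc", "pqc", "pcc_rm", "pqc_rm"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "n_outliers" in df.columns:
        df["n_outliers"] = pd.to_numeric(df["n_outliers"], errors="coerce")
    return df


def write_samples(samples: pd.DataFrame, path: str) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_samples(path: str) -> pd.DataFrame:
    df = pd.read_csv(_require(path), sep="\t", index_col=0, dtype=str)
    if "class" not in df.columns:
        raise ValueError(f"{path}: missing required column 'class'")
    return df
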