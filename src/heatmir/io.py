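"""Typed CSV readers/writers and the run manifest.

All artifacts are comma-separated UTF-8 with "." decimals and ISO-8601
dates.  Spectra travel as wide CSV: ``sample_id`` plus 1,060 point columns
``pt_0001 .. pt_1060``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import N_POINTS

__all__ = [
    "write_spectra_csv",
    "read_spectra_csv",
    "write_csv",
    "sha256_of",
    "write_manifest",
]

FLOAT_FMT = "%.10g"


def write_spectra_csv(spectra: pd.DataFrame, path) -> None:
    """Write a (samples x 1060) spectra frame with ``pt_0001..pt_1060`` header."""
    if spectra.shape[1] != N_POINTS:
        raise ValueError(f"expected {N_POINTS} columns, got {spectra.shape[1]}")
    out = spectra.copy()
    out.columns = [f"pt_{int(c):04d}" for c in range(1, N_POINTS + 1)]
    out.index.name = "sample_id"
    out.to_csv(path, float_format=FLOAT_FMT)


def read_spectra_csv(path) -> pd.DataFrame:
    """Read and validate a wide spectra CSV.

    Returns a DataFrame indexed by sample id with integer point-number
    columns 1..1060.  Wrong column counts and non-numeric cells raise
    ``ValueError`` naming the problem.
    """
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] != N_POINTS:
        raise ValueError(
            f"spectra file {path} has {df.shape[1]} point columns; "
            f"expected exactly {N_POINTS}"
        )
    bad = df.columns[~df.columns.str.fullmatch(r"pt_\d{4}")]
    if len(bad):
        raise ValueError(f"unexpected spectra column name {bad[0]!r}")
    if len(df) == 0:
        df.columns = np.arange(1, N_POINTS + 1)
        return df.astype(float)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(
                f"non-numeric value in column {col!r}, row {row!r}"
            )
    df.columns = np.arange(1, N_POINTS + 1)
    return df


def write_csv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=FLOAT_FMT)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, config: dict, stage: str, files, seeds=None) -> Path:
    """Append one stage entry to the run manifest (JSON lines)."""
    outdir = Path(outdir)
    path = outdir / "manifest.jsonl"
    entry = {
        "stage": stage,
        "config": config,
        "seeds": seeds or {},
        "outputs": {str(Path(f).name): sha256_of(f) for f in files},
    }
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps(entry, default=str) + "\n")
    return path
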