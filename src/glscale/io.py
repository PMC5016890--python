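"""Delimited-text matrix I/O and provenance sidecars.

Matrices are plain CSV/TSV with '.' decimals, one sample per row and an
optional header (auto-detected: a first row with any non-numeric field
is a header).  Missing or non-numeric cells are rejected with the row
and column named — values are never imputed.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_matrix", "write_matrix", "write_sidecar", "sidecar_path"]


def _floatable(token: str) -> bool:
    try:
        float(token)
    except (TypeError, ValueError):
        return False
    return True


def read_matrix(
    path,
    delimiter: str = ",",
    label_col: str | None = None,
) -> tuple[np.ndarray, list[str], np.ndarray | None]:
    """Load a samples x features matrix, optionally splitting off a label column.

    Returns ``(X, feature_names, labels)``; ``labels`` is None when no
    ``label_col`` is given.  The header row is auto-detected.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: file is empty")
    has_header = not all(_floatable(tok) for tok in first.strip().split(delimiter))
    df = pd.read_csv(path, sep=delimiter, header=0 if has_header else None)
    if not has_header:
        df.columns = [f"f{j}" for j in range(df.shape[1])]
    else:
        df.columns = [str(c) for c in df.columns]

    labels = None
    if label_col is not None:
        if label_col not in df.columns:
            raise ValueError(
                f"{path}: label column {label_col!r} not found; columns: {list(df.columns)}"
            )
        labels = df.pop(label_col).to_numpy()

    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"{path}: non-numeric value at row {row}, column {col!r}")
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ValueError(f"{path}: missing value at row {row}, column {col!r}")
        df[col] = numeric
    return df.to_numpy(dtype=float), [str(c) for c in df.columns], labels


def write_matrix(path, X, feature_names=None, delimiter: str = ",", labels=None, label_col: str = "label") -> None:
    X = np.asarray(X)
    names = feature_names or [f"f{j}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    if labels is not None:
        df[label_col] = labels
    df.to_csv(path, sep=delimiter, index=False)


def sidecar_path(output_path) -> Path:
    return Path(str(output_path) + ".meta.json")


def write_sidecar(output_path, payload: dict) -> Path:
    """Write a provenance sidecar (config echo) next to an output file."""
    target = sidecar_path(output_path)
    with open(target, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return target
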