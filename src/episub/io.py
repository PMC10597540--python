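"""Readers and writers for the pipeline's plain-text formats.

All tables are tab-separated. Expression matrices have the feature id in
the first column and sample ids in the header; metadata follows the
clinical table layout of :class:`~episub.containers.CohortMetadata`;
regulator networks are three-column edge lists; gene sets use the GMT
convention (name, description, then members).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import MODALITIES, CohortMetadata, ExpressionMatrix

NETWORK_SIGNS = ("repression", "activation")


def read_matrix(path: str, modality: str, unit: str = "cpm") -> ExpressionMatrix:
    """Read a feature x sample TSV matrix.

    Raises ``ValueError`` naming the offending row/column on duplicate
    identifiers or non-numeric cells.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dup = next(s for s in samples if samples.count(s) > 1)
        raise ValueError(f"{path}: duplicate sample id {dup!r} in header")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty matrix")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    return ExpressionMatrix(df, modality=modality, unit=unit)


def write_matrix(matrix: ExpressionMatrix, path: str) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id", float_format="%.10g")


def read_metadata(path: str) -> CohortMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for m in MODALITIES:
        col = f"has_{m}"
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return CohortMetadata(df)


def write_metadata(metadata: CohortMetadata, path: str) -> None:
    metadata.table.to_csv(path, sep="\t", index_label="sample_id")


def read_network(path: str) -> pd.DataFrame:
    """Read a regulator->target edge list (columns regulator, target, sign)."""
    df = pd.read_csv(path, sep="\t")
    expected = ["regulator", "target", "sign"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    bad = set(df["sign"]) - set(NETWORK_SIGNS)
    if bad:
        raise ValueError(f"{path}: unknown edge sign {sorted(bad)}")
    if df.duplicated(["regulator", "target"]).any():
        raise ValueError(f"{path}: duplicate regulator->target edges")
    return df


def write_network(edges: pd.DataFrame, path: str) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_gmt(path: str) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, members = parts[0], [g for g in parts[2:] if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path: str, description: str = "episub") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
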