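"""Readers and writers for the plain-text formats the pipeline exchanges.

All tabular inputs are TSV (features x samples, first column = feature id);
gene-set collections use the GMT convention (set name, description, then
member genes, tab-separated).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "read_gmt",
    "write_gmt",
]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix (first column is the feature id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_metadata(path: str | Path, sample_col: str = "sample") -> pd.DataFrame:
    """Read a sample-metadata TSV indexed by its sample column."""
    meta = pd.read_csv(path, sep="\t")
    if sample_col not in meta.columns:
        raise ValueError(f"metadata must contain a '{sample_col}' column")
    return meta.set_index(sample_col)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need name, description, genes): {line!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
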