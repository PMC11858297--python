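"""Flat-file readers/writers shared across the pipeline.

All tables are tab-separated UTF-8 with LF line endings.  The abundance
table is taxa x samples with a ``taxon_id`` first column; taxonomy maps
``taxon_id`` to a semicolon-joined ``phylum;class;order;family;genus``
lineage; metadata is samples x variables with a ``sample_id`` first column.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

TAXONOMY_RANKS = ("phylum", "class", "order", "family", "genus")


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Read a taxa x samples integer count table."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "taxon_id"
    if df.empty:
        raise ValueError(f"abundance table {path} is empty")
    if (df.values < 0).any():
        raise ValueError(f"abundance table {path} contains negative counts")
    return df.astype(int)


def write_abundance(table: pd.DataFrame, path: str | Path) -> None:
    table = table.copy()
    table.index.name = "taxon_id"
    _write_tsv(table, path)


def read_taxonomy(path: str | Path) -> pd.Series:
    """Read taxon_id -> lineage string mapping."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(str)


def write_taxonomy(taxonomy: pd.Series, path: str | Path) -> None:
    df = taxonomy.to_frame(name="lineage")
    df.index.name = "taxon_id"
    _write_tsv(df, path)


def split_lineage(lineage: str) -> dict[str, str]:
    """Split ``phylum;class;...`` into named ranks; missing ranks empty."""
    parts = [p.strip() for p in str(lineage).split(";")]
    parts += [""] * (len(TAXONOMY_RANKS) - len(parts))
    return dict(zip(TAXONOMY_RANKS, parts))


def rank_of(lineage: str, rank: str = "phylum") -> str:
    value = split_lineage(lineage).get(rank, "")
    return value if value else "unidentified"


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "sample_id"
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated sample IDs in {path}: {dupes}")
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata = metadata.copy()
    metadata.index.name = "sample_id"
    _write_tsv(metadata, path)


def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
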