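"""TSV readers and writers for the five pipeline inputs and its outputs.

All files are plain tab-separated text. Lines starting with ``#`` are
provenance headers and are skipped on read.
"""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd

from .tables import CompositionTable, CountTable

__all__ = [
    "read_counts",
    "read_genome_lengths",
    "read_count_table",
    "read_labels",
    "read_composition",
    "write_composition",
    "write_table",
    "read_annotation",
    "write_annotation",
]


def _provenance_lines(provenance: Mapping[str, object] | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def write_table(df: pd.DataFrame, path: str | os.PathLike,
                provenance: Mapping[str, object] | None = None,
                index_label: str = "id") -> None:
    """Write a DataFrame as TSV with an optional ``#``-commented header."""
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        df.to_csv(fh, sep="\t", index_label=index_label)


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a taxon x sample integer count TSV (header row of sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df.astype(int)


def read_genome_lengths(path: str | os.PathLike) -> pd.Series:
    """Read a two-column ``taxon_id<TAB>length`` TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df.iloc[:, 0].astype(float)


def read_count_table(counts_path, lengths_path) -> CountTable:
    return CountTable(read_counts(counts_path), read_genome_lengths(lengths_path))


def read_labels(path: str | os.PathLike) -> pd.Series:
    """Read a two-column ``sample_id<TAB>group`` TSV into a Series."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    return df.iloc[:, 0]


def read_composition(path: str | os.PathLike, kind: str = "taxonomic") -> CompositionTable:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#").astype(float)
    return CompositionTable(df, kind=kind)


def write_composition(table: CompositionTable, path: str | os.PathLike,
                      provenance: Mapping[str, object] | None = None) -> None:
    write_table(table.values, path, provenance=provenance)


def read_annotation(path: str | os.PathLike) -> dict[str, frozenset[str]]:
    """Read a ``function_id<TAB>categories`` TSV.

    Categories are concatenated one-letter codes, e.g. ``GP`` for a
    function annotated to both G and P.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    mapping: dict[str, frozenset[str]] = {}
    for fid, letters in df.iloc[:, 0].items():
        if not letters:
            raise ValueError(f"empty annotation for function {fid!r}")
        mapping[str(fid)] = frozenset(letters)
    return mapping


def write_annotation(mapping: Mapping[str, frozenset[str]],
                     path: str | os.PathLike,
                     provenance: Mapping[str, object] | None = None) -> None:
    rows = {fid: "".join(sorted(cats)) for fid, cats in mapping.items()}
    df = pd.DataFrame({"categories": pd.Series(rows)})
    write_table(df, path, provenance=provenance, index_label="function_id")
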