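"""Genomic Content Network (GCN) and the taxonomic-to-functional projection.

A GCN is a weighted bipartite network between a catalog of genomes
(taxa) and a set of functions (orthologous gene groups); the weight
G_ft is the copy number of function f in genome t. Seen as a linear
operator, the GCN maps each sample's relative species abundance vector
into a functional profile,

    Phi_fs = sum_t G_ft * T_ts

which is then column-normalized to give compositional functional data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .tables import CompositionTable, DegenerateSampleError

__all__ = [
    "GCN",
    "CategoryAnnotation",
    "COG_ALPHABET",
    "project",
    "read_gcn",
    "write_gcn",
]

#: default annotation alphabet: the 21 one-letter COG functional categories
COG_ALPHABET = tuple("JKLDVTMNZWUOCGEFHIPQS")


@dataclass
class GCN:
    """Function x taxon copy-number matrix in sparse storage.

    ``weights`` is a CSR matrix of non-negative integers; row/column
    order follows ``function_ids`` / ``taxon_ids``.
    """

    weights: sp.csr_matrix
    function_ids: pd.Index
    taxon_ids: pd.Index

    def __post_init__(self) -> None:
        self.weights = sp.csr_matrix(self.weights)
        self.function_ids = pd.Index(self.function_ids)
        self.taxon_ids = pd.Index(self.taxon_ids)
        if self.weights.shape != (len(self.function_ids), len(self.taxon_ids)):
            raise ValueError("weight matrix shape does not match identifier lists")
        if self.function_ids.has_duplicates or self.taxon_ids.has_duplicates:
            raise ValueError("duplicate function or taxon identifiers")
        if (self.weights.data < 0).any():
            raise ValueError("copy numbers must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    def empty_genomes(self) -> list:
        """Taxa whose genome carries no function (all-zero columns)."""
        colsum = np.asarray(self.weights.sum(axis=0)).ravel()
        return list(self.taxon_ids[colsum == 0])

    def to_dense(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights.toarray(), index=self.function_ids, columns=self.taxon_ids
        )


@dataclass
class CategoryAnnotation:
    """Function -> set of one-letter COG categories.

    A function may carry several letters (multi-annotation); every
    letter must belong to ``alphabet``.
    """

    mapping: Mapping[str, frozenset]
    alphabet: tuple = COG_ALPHABET

    def __post_init__(self) -> None:
        allowed = set(self.alphabet)
        self.mapping = {str(f): frozenset(c) for f, c in self.mapping.items()}
        for fid, cats in self.mapping.items():
            if not cats:
                raise ValueError(f"function {fid!r} has no category")
            stray = cats - allowed
            if stray:
                raise ValueError(
                    f"function {fid!r} uses letters outside the alphabet: {sorted(stray)}"
                )

    def categories(self, function_id: str) -> frozenset:
        return self.mapping[str(function_id)]

    def __contains__(self, function_id) -> bool:
        return str(function_id) in self.mapping


def project(gcn: GCN, td: CompositionTable) -> CompositionTable:
    """Project a taxonomic composition into functional space (column-normalized).

    Every taxon of ``td`` must be resolvable in the GCN; missing taxa
    are a hard error rather than a silent drop, because taxonomy and
    function must stay consistently linked.
    """
    missing = td.component_ids.difference(gcn.taxon_ids)
    if len(missing):
        raise KeyError(
            f"taxa absent from the GCN: {sorted(map(str, missing))[:10]}"
        )
    # align GCN columns to the table's taxon order
    pos = gcn.taxon_ids.get_indexer(td.component_ids)
    weights = gcn.weights[:, pos]
    raw = weights @ td.values.to_numpy()
    colsums = raw.sum(axis=0)
    empty = colsums == 0
    if empty.any():
        name = td.sample_ids[empty][0]
        raise DegenerateSampleError(
            f"sample {name!r} projects to an all-zero functional column"
        )
    df = pd.DataFrame(
        raw / colsums, index=gcn.function_ids, columns=td.sample_ids
    )
    return CompositionTable(df, kind="functional")


def project_raw(gcn: GCN, td: CompositionTable) -> np.ndarray:
    """Unnormalized projection sum_t G_ft T_ts (linear in the input)."""
    pos = gcn.taxon_ids.get_indexer(td.component_ids)
    if (pos < 0).any():
        raise KeyError("taxa absent from the GCN")
    return gcn.weights[:, pos] @ td.values.to_numpy()


def read_gcn(path) -> GCN:
    """Read a ``function_id<TAB>taxon_id<TAB>copy_number`` edge list."""
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={0: str, 1: str},
        names=["function_id", "taxon_id", "copy_number"], header=0,
    )
    cn = df["copy_number"]
    if not np.array_equal(cn, cn.astype(int)) or (cn <= 0).any():
        raise ValueError("copy numbers must be positive integers")
    dup = df.duplicated(subset=["function_id", "taxon_id"])
    if dup.any():
        pair = df.loc[dup, ["function_id", "taxon_id"]].iloc[0]
        raise ValueError(
            f"duplicate edge ({pair['function_id']!r}, {pair['taxon_id']!r})"
        )
    functions = pd.Index(sorted(df["function_id"].unique()))
    taxa = pd.Index(sorted(df["taxon_id"].unique()))
    rows = functions.get_indexer(df["function_id"])
    cols = taxa.get_indexer(df["taxon_id"])
    mat = sp.csr_matrix(
        (df["copy_number"].astype(int), (rows, cols)),
        shape=(len(functions), len(taxa)),
    )
    return GCN(mat, functions, taxa)


def write_gcn(gcn: GCN, path, provenance: Mapping[str, object] | None = None) -> None:
    """Write the edge list; ``read_gcn(write_gcn(g))`` round-trips exactly."""
    coo = gcn.weights.tocoo()
    df = pd.DataFrame(
        {
            "function_id": gcn.function_ids[coo.row],
            "taxon_id": gcn.taxon_ids[coo.col],
            "copy_number": coo.data.astype(int),
        }
    ).sort_values(["function_id", "taxon_id"])
    with open(path, "w") as fh:
        if provenance:
            fh.write("".join(f"# {k}: {v}\n" for k, v in provenance.items()))
        df.to_csv(fh, sep="\t", index=False)
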