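"""Core data containers shared across the pipeline.

Two tables carry the whole analysis: a taxon-by-sample read-count table
(``CountTable``) and the compositional tables derived from it
(``CompositionTable``), which hold either relative taxon abundances
(``kind="taxonomic"``) or relative function abundances
(``kind="functional"``). Both wrap a pandas DataFrame with components on
the rows and samples on the columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "CompositionTable",
    "DegenerateSampleError",
    "group_samples",
    "COLUMN_SUM_TOL",
]

#: tolerance on compositional column sums
COLUMN_SUM_TOL = 1e-9


class DegenerateSampleError(ValueError):
    """A sample column is empty (all zero) where data are required."""


@dataclass
class CountTable:
    """Taxon x sample integer read counts plus per-taxon genome lengths.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers; rows are taxa, columns samples.
    genome_lengths
        Series of strictly positive genome lengths (bases), indexed by the
        same taxon identifiers as ``counts``.
    """

    counts: pd.DataFrame
    genome_lengths: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate taxon identifiers in count table")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers in count table")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("read counts must be non-negative")
        missing = self.counts.index.difference(self.genome_lengths.index)
        if len(missing):
            raise ValueError(
                f"taxa without genome length: {sorted(map(str, missing))[:5]}"
            )
        self.genome_lengths = self.genome_lengths.reindex(self.counts.index)
        if (self.genome_lengths.to_numpy() <= 0).any():
            raise ValueError("genome lengths must be strictly positive")

    @property
    def taxon_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class CompositionTable:
    """Component x sample relative abundances; every column sums to 1.

    Serves both the taxonomic table T_ts and the functional table
    Phi_fs, distinguished by ``kind``. ``zero_components`` records
    components that are zero in every sample (kept so shapes stay stable
    across thresholding) .
    """

    values: pd.DataFrame
    kind: str = "taxonomic"
    zero_components: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("taxonomic", "functional"):
            raise ValueError(f"unknown table kind: {self.kind!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate component identifiers")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        vals = self.values.to_numpy(dtype=float)
        if (vals < 0).any() or (vals > 1 + COLUMN_SUM_TOL).any():
            raise ValueError("relative abundances must lie in [0, 1]")
        sums = vals.sum(axis=0)
        bad = np.abs(sums - 1.0) > COLUMN_SUM_TOL
        if bad.any():
            names = list(self.values.columns[bad][:5])
            raise ValueError(f"columns do not sum to 1: {names}")

    @property
    def component_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def group_samples(labels: pd.Series, group: str) -> pd.Index:
    """Sample identifiers carrying label ``group`` (e.g. ``"H"`` or ``"U"``).

    ``group="all"`` returns every labelled sample.
    """
    if group == "all":
        return labels.index
    if group not in set(labels.unique()):
        raise KeyError(f"unknown group label: {group!r}")
    return labels.index[labels == group]
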