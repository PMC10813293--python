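"""Correlation structure of component abundances, per group and representation.

For a group's samples, C_ij is the Pearson correlation between the raw
relative abundances of components i and j across samples, and
A_ij = MA_i * MA_j is the couple abundance — the product of the two
components' mean abundances. Couple abundance is used two ways: as the
x-axis of a 2D histogram against C_ij (are abundant couples more
correlated?), and as the weight of a weighted correlation profile that
emphasizes abundant couples. Finally the sorted eigenvalue spectra of
the correlation and covariance matrices measure the effective
dimensionality of each group: the faster the decay, the fewer
independent directions of fluctuation.

Correlations are computed on raw relative abundances (not logs, no
centered-log-ratio correction); compositional closure can induce
spurious negative correlation, which is a documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CompositionTable, group_samples

__all__ = [
    "CorrelationSummary",
    "EigenSpectrum",
    "correlation_matrix",
    "hist2d_corr_abundance",
    "correlation_profile",
    "eigenvalue_decay",
    "aggregate_categories",
]


@dataclass
class CorrelationSummary:
    """Pearson matrix C, couple abundances A and bookkeeping for one group."""

    corr: pd.DataFrame
    couple_abundance: pd.DataFrame
    included_ids: list
    dropped_ids: list
    group: str
    representation: str

    def __post_init__(self) -> None:
        C = self.corr.to_numpy()
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-9):
            raise ValueError("correlation diagonal must be 1")
        if (np.abs(C) > 1 + 1e-9).any():
            raise ValueError("correlations must lie in [-1, 1]")
        if (self.couple_abundance.to_numpy() < 0).any():
            raise ValueError("couple abundances must be non-negative")


def _as_frame(table) -> tuple[pd.DataFrame, str]:
    """Accept a CompositionTable or any component x sample DataFrame."""
    if isinstance(table, CompositionTable):
        return table.values, table.kind
    return table, "custom"


def correlation_matrix(table, labels: pd.Series | None,
                       group: str = "all") -> CorrelationSummary:
    """Pairwise Pearson correlations across the group's samples.

    ``table`` may be a :class:`CompositionTable` or a plain component x
    sample DataFrame (the patterns apply to any component system).
    Zero-variance components (Pearson undefined) are dropped and listed
    in ``dropped_ids``.
    """
    values, kind = _as_frame(table)
    cols = (values.columns if labels is None
            else group_samples(labels, group))
    if len(cols) < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    sub = values[cols]
    var = sub.var(axis=1, ddof=1)
    keep = var > 0
    if not keep.any():
        raise ValueError("all components have zero variance")
    kept = sub[keep]
    C = np.atleast_2d(np.corrcoef(kept.to_numpy()))
    np.fill_diagonal(C, 1.0)
    ma = kept.mean(axis=1).to_numpy()
    A = np.outer(ma, ma)
    ids = kept.index
    return CorrelationSummary(
        corr=pd.DataFrame(C, index=ids, columns=ids),
        couple_abundance=pd.DataFrame(A, index=ids, columns=ids),
        included_ids=list(ids),
        dropped_ids=list(sub.index[~keep]),
        group=group,
        representation=kind,
    )


def _couples(summary: CorrelationSummary) -> tuple[np.ndarray, np.ndarray]:
    """Off-diagonal unordered couples: (C_ij, A_ij) for i < j."""
    C = summary.corr.to_numpy()
    A = summary.couple_abundance.to_numpy()
    iu = np.triu_indices(C.shape[0], k=1)
    return C[iu], A[iu]


def hist2d_corr_abundance(summary: CorrelationSummary, bins: int = 50
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """2D histogram of (log10 A_ij, C_ij) over unordered couples.

    Returns ``(counts, log10A_edges, C_edges, n_zero_A_excluded)``;
    couples with A_ij = 0 cannot appear on a log axis and are excluded
    but tallied.
    """
    c, a = _couples(summary)
    if c.size == 0:
        raise ValueError("no off-diagonal couples")
    ok = a > 0
    n_excluded = int((~ok).sum())
    H, xedges, yedges = np.histogram2d(np.log10(a[ok]), c[ok], bins=bins)
    return H, xedges, yedges, n_excluded


def correlation_profile(summary: CorrelationSummary, mode: str = "even",
                        bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of the C_ij values, unit-area normalized.

    ``even`` counts each couple once; ``weighted`` weights couple
    (i, j) by its couple abundance A_ij, giving proportionally more
    importance to couples of abundant components.
    """
    c, a = _couples(summary)
    if c.size == 0:
        raise ValueError("no off-diagonal couples")
    if mode == "even":
        weights = None
    elif mode == "weighted":
        if not (a > 0).any():
            raise ValueError("all couple abundances are zero")
        weights = a
    else:
        raise ValueError(f"unknown mode {mode!r}")
    density, edges = np.histogram(c, bins=bins, range=(-1, 1),
                                  weights=weights, density=True)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, density


@dataclass
class EigenSpectrum:
    """Sorted eigenvalues of a group's correlation or covariance matrix."""

    eigenvalues: np.ndarray
    normalized: np.ndarray
    matrix_kind: str
    group: str
    representation: str
    n_components: int

    def __post_init__(self) -> None:
        if (np.diff(self.eigenvalues) > 1e-12).any():
            raise ValueError("eigenvalues must be sorted descending")

    def cumulative_fraction(self, k: int) -> float:
        """Share of total variance carried by the top-k eigenvalues."""
        return float(self.normalized[:k].sum())


def eigenvalue_decay(table, labels: pd.Series | None,
                     group: str = "all",
                     matrix_kind: str = "correlation") -> EigenSpectrum:
    """Descending eigenvalue spectrum of the group's C or covariance matrix.

    The correlation spectrum measures effective dimensionality of the
    relative fluctuations (its trace equals the number of included
    components); the covariance spectrum uses the original abundance
    units. Tiny negative eigenvalues from round-off are clipped to 0.
    """
    if matrix_kind not in ("correlation", "covariance"):
        raise ValueError(f"unknown matrix kind {matrix_kind!r}")
    values, kind = _as_frame(table)
    if matrix_kind == "correlation":
        summary = correlation_matrix(table, labels, group)
        mat = summary.corr.to_numpy()
        p = len(summary.included_ids)
    else:
        cols = (values.columns if labels is None
                else group_samples(labels, group))
        if len(cols) < 3:
            raise ValueError("need at least 3 samples")
        mat = np.cov(values[cols].to_numpy())
        p = mat.shape[0]
    vals = np.linalg.eigvalsh(mat)[::-1]
    vals = np.where(np.abs(vals) < 1e-10, 0.0, vals)
    vals = np.clip(vals, 0.0, None)
    return EigenSpectrum(
        eigenvalues=vals, normalized=vals / vals.sum(),
        matrix_kind=matrix_kind, group=group or "all",
        representation=kind, n_components=p,
    )


def aggregate_categories(table: CompositionTable, annotation) -> CompositionTable:
    """Category-aggregated composition (equal split of multi-annotated
    functions); convenience for category-category correlation analyses."""
    letters = list(annotation.alphabet)
    agg = pd.DataFrame(0.0, index=letters, columns=table.sample_ids)
    for fid in table.component_ids:
        key = str(fid)
        if key in annotation:
            cats = annotation.categories(key)
            agg.loc[list(cats)] += table.values.loc[fid].to_numpy() / len(cats)
    colsums = agg.sum(axis=0)
    if (colsums == 0).any():
        raise ValueError("a sample has no annotated functional abundance")
    return CompositionTable(agg / colsums, kind="functional")
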