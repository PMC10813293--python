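"""Build the compositional taxonomic table from read counts.

The pipeline has three steps. Read counts are first corrected for the
length bias of shotgun sequencing — the probability of drawing a read
from a genome scales with its length L_t — by dividing each taxon's
counts by L_t and renormalizing every sample column to 1:

    T_ts = (reads_ts / L_t) / sum_t' (reads_t's / L_t')

Second, a detection threshold eta0 is chosen as the logarithmic flex
point of the mean alpha-diversity curve <alpha(eta)> (the mean, over
samples, of the number of components above eta), i.e. the eta at which
d<alpha>/d log(eta) is most negative: below the flex, lowering the
threshold mostly admits spurious low-abundance assignments. Third,
entries below eta0 are zeroed and each column renormalized to restore
compositionality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CompositionTable, CountTable, DegenerateSampleError

__all__ = [
    "AlphaCurve",
    "length_normalize",
    "default_eta_grid",
    "alpha_diversity_curve",
    "find_flex_threshold",
    "apply_threshold_renormalize",
    "build_taxonomic_table",
]


class DegenerateCurveError(ValueError):
    """The alpha-diversity curve is constant; no flex point exists."""


@dataclass
class AlphaCurve:
    """Mean alpha diversity as a function of the detection threshold.

    ``thresholds`` is the strictly increasing eta grid; ``mean_alpha[k]``
    is the mean, over samples, of the number of components whose relative
    abundance exceeds ``thresholds[k]``.
    """

    thresholds: np.ndarray
    mean_alpha: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.mean_alpha = np.asarray(self.mean_alpha, dtype=float)
        if self.thresholds.ndim != 1 or self.thresholds.size != self.mean_alpha.size:
            raise ValueError("thresholds and mean_alpha must be 1-D and equal length")
        if self.thresholds.size and (
            (np.diff(self.thresholds) <= 0).any() or (self.thresholds <= 0).any()
        ):
            raise ValueError("thresholds must be positive and strictly increasing")


def length_normalize(counts: CountTable) -> CompositionTable:
    """Genome-length-corrected relative abundances (cell-count proxy).

    Divides each taxon row by its genome length and normalizes each
    sample column to 1.

    Raises
    ------
    DegenerateSampleError
        If a sample column contains no reads.
    """
    vals = counts.counts.to_numpy(dtype=float)
    lengths = counts.genome_lengths.to_numpy(dtype=float)
    weighted = vals / lengths[:, None]
    colsums = weighted.sum(axis=0)
    empty = colsums == 0
    if empty.any():
        name = counts.sample_ids[empty][0]
        raise DegenerateSampleError(f"sample {name!r} has no reads")
    df = pd.DataFrame(
        weighted / colsums, index=counts.taxon_ids, columns=counts.sample_ids
    )
    return CompositionTable(df, kind="taxonomic")


def default_eta_grid(lo: float = 1e-8, hi: float = 1e-1, n: int = 50) -> np.ndarray:
    """Log-spaced threshold grid used when none is supplied."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def alpha_diversity_curve(table: CompositionTable, eta_grid: np.ndarray) -> AlphaCurve:
    """Mean number of components with relative abundance > eta, per eta.

    Counting is strict (``> eta``), consistent with strict removal
    (``< eta0``) in :func:`apply_threshold_renormalize`, so a component
    exactly at the threshold survives both.
    """
    grid = np.asarray(eta_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("eta grid is empty")
    if (grid <= 0).any() or (grid >= 1).any() or (np.diff(grid) <= 0).any():
        raise ValueError("eta grid must be strictly increasing within (0, 1)")
    vals = table.values.to_numpy()
    # alpha[k] = mean over samples of #(components > grid[k])
    alpha = (vals[:, :, None] > grid[None, None, :]).sum(axis=0).mean(axis=0)
    return AlphaCurve(grid, alpha)


def find_flex_threshold(curve: AlphaCurve) -> float:
    """Threshold at the logarithmic flex point of the alpha curve.

    Returns the grid point minimizing d<alpha>/d log(eta), estimated by
    central finite differences in log eta (one-sided at the ends). Since
    <alpha> is non-increasing, the minimum is the steepest descent. Ties
    break toward the smallest eta (removes less).

    Raises
    ------
    DegenerateCurveError
        If the curve is constant.
    """
    if curve.thresholds.size < 3:
        raise ValueError("need at least 3 grid points to locate a flex")
    if np.allclose(curve.mean_alpha, curve.mean_alpha[0]):
        raise DegenerateCurveError("alpha curve is constant; no flex point")
    slope = np.gradient(curve.mean_alpha, np.log(curve.thresholds))
    # ties (within float tolerance) break toward the smallest eta
    cutoff = slope.min() + 1e-9 * max(1.0, abs(slope.min()))
    return float(curve.thresholds[int(np.flatnonzero(slope <= cutoff)[0])])


def apply_threshold_renormalize(
    table: CompositionTable, eta0: float
) -> CompositionTable:
    """Zero entries below eta0 (strict) and renormalize columns to 1.

    Components that end up zero in every sample are retained as zero
    rows — downstream shapes stay stable — and listed in the result's
    ``zero_components``.

    Raises
    ------
    DegenerateSampleError
        If a sample loses all its components at this threshold.
    """
    if not 0 < eta0 < 1:
        raise ValueError("eta0 must lie in (0, 1)")
    vals = table.values.to_numpy().copy()
    vals[vals < eta0] = 0.0
    colsums = vals.sum(axis=0)
    empty = colsums == 0
    if empty.any():
        name = table.sample_ids[empty][0]
        raise DegenerateSampleError(
            f"sample {name!r} has no components above eta0={eta0:g}"
        )
    vals /= colsums
    df = pd.DataFrame(vals, index=table.component_ids, columns=table.sample_ids)
    dropped = list(table.component_ids[(vals == 0).all(axis=1)])
    return CompositionTable(df, kind=table.kind, zero_components=dropped)


def build_taxonomic_table(
    counts: CountTable,
    eta_grid: np.ndarray | None = None,
    eta0: float | None = None,
) -> tuple[CompositionTable, float]:
    """Full three-step pipeline: length-normalize, threshold, renormalize.

    If ``eta0`` is not given it is selected from the alpha-diversity
    flex point over ``eta_grid`` (default grid if None). Returns the
    final table and the threshold used.
    """
    comp = length_normalize(counts)
    if eta0 is None:
        grid = default_eta_grid() if eta_grid is None else np.asarray(eta_grid)
        eta0 = find_flex_threshold(alpha_diversity_curve(comp, grid))
    return apply_threshold_renormalize(comp, eta0), float(eta0)
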