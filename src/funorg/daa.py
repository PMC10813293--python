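"""Differential abundance analysis with a label-permutation null model.

For each component i (taxon or function) the log differential between
the unhealthy and healthy group means,

    delta_i = log10(MA_i(U)) - log10(MA_i(H)),

is collected into a rolling histogram: right tail = enriched in U,
left tail = depleted. Significance is judged against a null model of
(by default) 150 independent relabelings of the samples that preserve
the two group sizes; the null band is the pointwise replicate mean
plus/minus sigma+/sigma-, the RMS of the above-/below-mean deviations.

Components with zero mean abundance in either group are excluded from
delta (thresholded compositional zeros are structural; no pseudo-count
is applied) and listed in ``DeltaProfile.excluded_ids``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .macroeco import DEFAULT_STEP, DEFAULT_WIDTH, RollingHistogram, \
    rolling_histogram
from .tables import CompositionTable, group_samples

__all__ = [
    "DeltaProfile",
    "NullEnsemble",
    "log_differential",
    "delta_histogram",
    "permutation_null",
    "flag_anomalies",
    "delta_histogram_statistic",
]

DEFAULT_N_NULL = 150


@dataclass
class DeltaProfile:
    """Per-component log10 differential between group mean abundances."""

    delta: pd.Series
    ma_H: pd.Series
    ma_U: pd.Series
    excluded_ids: list

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta.to_numpy()).all():
            raise ValueError("delta must be finite on the co-present set")


@dataclass
class NullEnsemble:
    """Permutation replicates of a vector statistic with asymmetric bands."""

    replicates: np.ndarray  # (n_realizations, n_points)
    mean: np.ndarray
    sigma_plus: np.ndarray
    sigma_minus: np.ndarray
    n_realizations: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.replicates.shape[0] != self.n_realizations:
            raise ValueError("replicate count does not match n_realizations")
        if (self.sigma_plus < 0).any() or (self.sigma_minus < 0).any():
            raise ValueError("sigma bands must be non-negative")


def log_differential(table: CompositionTable, labels: pd.Series,
                     groups: tuple[str, str] = ("H", "U")) -> DeltaProfile:
    """delta_i = log10 MA_i(U) - log10 MA_i(H) on the co-present set."""
    g_ref, g_alt = groups
    cols_ref = group_samples(labels, g_ref)
    cols_alt = group_samples(labels, g_alt)
    if len(cols_ref) == 0 or len(cols_alt) == 0:
        raise ValueError("both groups must have at least one sample")
    ma_ref = table.values[cols_ref].mean(axis=1)
    ma_alt = table.values[cols_alt].mean(axis=1)
    ok = (ma_ref > 0) & (ma_alt > 0)
    delta = np.log10(ma_alt[ok]) - np.log10(ma_ref[ok])
    return DeltaProfile(
        delta=delta, ma_H=ma_ref, ma_U=ma_alt,
        excluded_ids=list(table.component_ids[~ok]),
    )


def delta_histogram(profile: DeltaProfile, width: float = DEFAULT_WIDTH,
                    step: float = DEFAULT_STEP,
                    centers: np.ndarray | None = None) -> RollingHistogram:
    """Rolling histogram of delta on a linear axis."""
    if profile.delta.size == 0:
        raise ValueError("empty delta profile")
    return rolling_histogram(profile.delta.to_numpy(), width, step,
                             log=False, centers=centers)


def _shuffled(labels: pd.Series, rng: np.random.Generator) -> pd.Series:
    """Random relabeling preserving the cardinality of each group."""
    return pd.Series(rng.permutation(labels.to_numpy()),
                     index=labels.index, name=labels.name)


def permutation_null(
    table: CompositionTable,
    labels: pd.Series,
    statistic: Callable[[CompositionTable, pd.Series], np.ndarray],
    n_realizations: int = DEFAULT_N_NULL,
    seed: int | None = None,
) -> NullEnsemble:
    """Null ensemble of ``statistic`` under group-size-preserving shuffles.

    Permutations are sampled uniformly with replacement, so requesting
    more realizations than there are distinct assignments is allowed.
    """
    if n_realizations < 1:
        raise ValueError("need at least one realization")
    rng = np.random.default_rng(seed)
    reps = np.array(
        [np.asarray(statistic(table, _shuffled(labels, rng)), dtype=float)
         for _ in range(n_realizations)]
    )
    mean = reps.mean(axis=0)
    dev = reps - mean
    pos_n = (dev > 0).sum(axis=0)
    neg_n = (dev < 0).sum(axis=0)
    pos_sq = np.where(dev > 0, dev ** 2, 0.0).sum(axis=0)
    neg_sq = np.where(dev < 0, dev ** 2, 0.0).sum(axis=0)
    sigma_plus = np.sqrt(pos_sq / np.maximum(pos_n, 1))
    sigma_minus = np.sqrt(neg_sq / np.maximum(neg_n, 1))
    return NullEnsemble(reps, mean, sigma_plus, sigma_minus,
                        n_realizations, seed)


def flag_anomalies(observed: np.ndarray, null: NullEnsemble) -> np.ndarray:
    """Per-point flags: ``above`` / ``below`` / ``inside`` the null band."""
    obs = np.asarray(observed, dtype=float)
    if obs.shape != null.mean.shape:
        raise ValueError("observed statistic and null band differ in support")
    flags = np.full(obs.shape, "inside", dtype=object)
    flags[obs > null.mean + null.sigma_plus] = "above"
    flags[obs < null.mean - null.sigma_minus] = "below"
    return flags.astype(str)


def delta_histogram_statistic(
    centers: np.ndarray, width: float = DEFAULT_WIDTH,
    step: float = DEFAULT_STEP, groups: tuple[str, str] = ("H", "U"),
    density: bool = True,
) -> Callable[[CompositionTable, pd.Series], np.ndarray]:
    """Statistic factory: delta histogram evaluated on a fixed grid.

    The co-present component set may differ per relabeling; evaluating
    every replicate on the same window grid keeps the band pointwise
    well-defined.
    """
    centers = np.asarray(centers, dtype=float)

    def stat(table: CompositionTable, labels: pd.Series) -> np.ndarray:
        profile = log_differential(table, labels, groups)
        hist = delta_histogram(profile, width, step, centers=centers)
        return hist.density if density else hist.counts

    return stat
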