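"""Macroecological abundance patterns, per group, for any component system.

Four classic patterns, computed identically for taxa (T- prefix) and
functions (F- prefix) because both live in the same component-by-sample
compositional structure:

* MAD — distribution of the per-component mean abundance across the
  group's samples;
* OA  — occurrence (fraction of samples where a component is present)
  against mean abundance;
* SAD — distribution of abundances within one sample, standardized in
  log units to zero mean / unit variance and averaged across samples;
* AFD — distribution of one component's abundances across samples (no
  rescaling), averaged across components.

All histograms are rolling: windows of a constant width in log10 space
slide by a fixed step, and a value is tallied in every window covering
it. Windows are half-open, ``[center - width/2, center + width/2)``, so
that when ``step == width`` the windows tile the axis and each value is
counted exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import CompositionTable, group_samples

__all__ = [
    "RollingHistogram",
    "GroupedPattern",
    "OccurrenceProfile",
    "rolling_histogram",
    "rolling_log_histogram",
    "mean_abundance_distribution",
    "occurrence_abundance",
    "sad",
    "afd",
    "DEFAULT_WIDTH",
    "DEFAULT_STEP",
]

DEFAULT_WIDTH = 0.5  # decades
DEFAULT_STEP = 0.1   # decades


@dataclass
class RollingHistogram:
    """Overlapping-window histogram on a regular grid of window centers."""

    window_centers: np.ndarray
    density: np.ndarray
    counts: np.ndarray
    window_width: float
    step: float
    n_values: int = 0

    def __post_init__(self) -> None:
        self.window_centers = np.asarray(self.window_centers, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.density < 0).any():
            raise ValueError("densities must be non-negative")
        if self.window_centers.size > 1:
            gaps = np.diff(self.window_centers)
            if not np.allclose(gaps, self.step):
                raise ValueError("window centers must be evenly spaced by step")


def _window_grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(np.floor((hi - lo) / step + 0.5)) + 1
    return lo + step * np.arange(n)


def _counts_on_grid(x: np.ndarray, centers: np.ndarray, width: float,
                    weights: np.ndarray | None = None) -> np.ndarray:
    """Tally of values (or weights) per half-open window on ``centers``."""
    lo = centers - width / 2
    hi = centers + width / 2
    inside = (x[:, None] >= lo[None, :]) & (x[:, None] < hi[None, :])
    if weights is None:
        return inside.sum(axis=0).astype(float)
    return (inside * weights[:, None]).sum(axis=0)


def rolling_histogram(values: np.ndarray, width: float = DEFAULT_WIDTH,
                      step: float = DEFAULT_STEP, log: bool = False,
                      centers: np.ndarray | None = None) -> RollingHistogram:
    """Rolling histogram of ``values`` on a linear (or log10) axis.

    ``density`` is ``count / (n_values * width)``. With ``log=True``,
    zero values are dropped before taking log10; an all-zero input is an
    error. A precomputed ``centers`` grid may be supplied so that
    several histograms share support.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    x = np.asarray(values, dtype=float).ravel()
    if log:
        x = x[x > 0]
        if x.size == 0:
            raise ValueError("no positive values to histogram on a log axis")
        x = np.log10(x)
    elif x.size == 0:
        raise ValueError("empty input")
    if centers is None:
        centers = _window_grid(x.min(), x.max(), step)
    counts = _counts_on_grid(x, centers, width)
    return RollingHistogram(
        centers, counts / (x.size * width), counts, width, step, n_values=x.size
    )


def rolling_log_histogram(values, width: float = DEFAULT_WIDTH,
                          step: float = DEFAULT_STEP,
                          centers: np.ndarray | None = None) -> RollingHistogram:
    """Rolling histogram in log10 space (zeros excluded)."""
    return rolling_histogram(values, width, step, log=True, centers=centers)


@dataclass
class GroupedPattern:
    """A macroecological pattern curve for one group (H or U)."""

    pattern: str
    group: str
    window_centers: np.ndarray
    mean_curve: np.ndarray
    sd_band: np.ndarray
    window_width: float = DEFAULT_WIDTH
    step: float = DEFAULT_STEP
    n_excluded: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (np.asarray(self.sd_band) < 0).any():
            raise ValueError("sd band must be non-negative")


def group_mean_abundance(table: CompositionTable, labels: pd.Series,
                         group: str) -> pd.Series:
    """Per-component mean relative abundance over the group's samples."""
    cols = group_samples(labels, group)
    if len(cols) == 0:
        raise ValueError(f"group {group!r} has no samples")
    return table.values[cols].mean(axis=1)


def mean_abundance_distribution(table: CompositionTable, labels: pd.Series,
                                group: str, width: float = DEFAULT_WIDTH,
                                step: float = DEFAULT_STEP) -> GroupedPattern:
    """MAD: rolling log histogram of nonzero per-component mean abundances."""
    cols = group_samples(labels, group)
    ma = table.values[cols].mean(axis=1)
    nz = ma[ma > 0]
    hist = rolling_log_histogram(nz.to_numpy(), width, step)
    # the band combines the histogram's counting error with the
    # intra-group variability (the spread, across the group's samples,
    # of single-sample abundance histograms on the MAD's grid)
    per_sample = []
    for s in cols:
        col = table.values[s].to_numpy()
        logs = np.log10(col[col > 0])
        counts = _counts_on_grid(logs, hist.window_centers, width)
        per_sample.append(counts / (logs.size * width))
    spread = np.std(np.array(per_sample), axis=0)
    poisson = np.sqrt(hist.counts) / (hist.n_values * width)
    sd = np.sqrt(spread ** 2 + poisson ** 2)
    return GroupedPattern(
        pattern="MAD", group=group, window_centers=hist.window_centers,
        mean_curve=hist.density, sd_band=sd,
        window_width=width, step=step, n_excluded=int((ma == 0).sum()),
        extras={"counts": hist.counts, "ma": ma},
    )


@dataclass
class OccurrenceProfile:
    """Occurrence-abundance relation for one group."""

    group: str
    per_component: pd.DataFrame  # columns: ma, occurrence
    window_centers: np.ndarray   # log10 MA
    mean_occurrence: np.ndarray
    sigma_plus: np.ndarray
    sigma_minus: np.ndarray
    window_width: float
    step: float
    n_excluded: int


def asymmetric_sigma(values: np.ndarray, mean: float) -> tuple[float, float]:
    """RMS of above-mean and of below-mean deviations from ``mean``."""
    dev = np.asarray(values, dtype=float) - mean
    pos, neg = dev[dev > 0], dev[dev < 0]
    sp = float(np.sqrt(np.mean(pos ** 2))) if pos.size else 0.0
    sm = float(np.sqrt(np.mean(neg ** 2))) if neg.size else 0.0
    return sp, sm


def occurrence_abundance(table: CompositionTable, labels: pd.Series,
                         group: str, width: float = DEFAULT_WIDTH,
                         step: float = DEFAULT_STEP) -> OccurrenceProfile:
    """OA: per-component occurrence, binned by log mean abundance.

    Each rolling window reports the mean occurrence of the components
    whose mean abundance falls inside it, with asymmetric sigma bands.
    Components absent from every group sample are excluded from the
    binning and tallied in ``n_excluded``.
    """
    cols = group_samples(labels, group)
    sub = table.values[cols]
    ma = sub.mean(axis=1)
    occurrence = (sub > 0).mean(axis=1)
    per_component = pd.DataFrame({"ma": ma, "occurrence": occurrence})
    present = ma > 0
    logs = np.log10(ma[present].to_numpy())
    occ = occurrence[present].to_numpy()
    centers = _window_grid(logs.min(), logs.max(), step)
    mean_occ = np.full(centers.size, np.nan)
    sig_p = np.zeros(centers.size)
    sig_m = np.zeros(centers.size)
    for j, c in enumerate(centers):
        inside = (logs >= c - width / 2) & (logs < c + width / 2)
        if inside.any():
            m = occ[inside].mean()
            mean_occ[j] = m
            sig_p[j], sig_m[j] = asymmetric_sigma(occ[inside], m)
    return OccurrenceProfile(
        group=group, per_component=per_component, window_centers=centers,
        mean_occurrence=mean_occ, sigma_plus=sig_p, sigma_minus=sig_m,
        window_width=width, step=step, n_excluded=int((~present).sum()),
    )


def sad(table: CompositionTable, labels: pd.Series, group: str,
        width: float = DEFAULT_WIDTH, step: float = DEFAULT_STEP) -> GroupedPattern:
    """SAD: standardized log-abundance histogram, averaged across samples.

    Per sample, log10 of the nonzero abundances is standardized to zero
    mean and unit variance; the per-sample rolling histograms share one
    grid, and the curve reports their across-sample mean and standard
    deviation.
    """
    cols = group_samples(labels, group)
    standardized = []
    for s in cols:
        col = table.values[s].to_numpy()
        nz = np.log10(col[col > 0])
        if nz.size < 2:
            raise ValueError(f"sample {s!r} has fewer than 2 nonzero components")
        standardized.append((nz - nz.mean()) / nz.std())
    lo = min(z.min() for z in standardized)
    hi = max(z.max() for z in standardized)
    centers = _window_grid(lo, hi, step)
    curves = np.array(
        [_counts_on_grid(z, centers, width) / (z.size * width) for z in standardized]
    )
    return GroupedPattern(
        pattern="SAD", group=group, window_centers=centers,
        mean_curve=curves.mean(axis=0), sd_band=curves.std(axis=0),
        window_width=width, step=step,
        extras={"per_sample": curves, "standardized": standardized},
    )


def afd(table: CompositionTable, labels: pd.Series, group: str,
        width: float = DEFAULT_WIDTH, step: float = DEFAULT_STEP,
        min_presence: int = 2) -> GroupedPattern:
    """AFD: per-component abundance-fluctuation histograms, averaged.

    Each component present (nonzero) in at least ``min_presence`` of
    the group's samples contributes the log histogram of its nonzero
    abundances across those samples; no rescaling is applied. The curve
    is the across-component mean with its standard deviation band.
    """
    cols = group_samples(labels, group)
    if len(cols) < 2:
        raise ValueError("AFD needs a group with at least 2 samples")
    sub = table.values[cols].to_numpy()
    keep = (sub > 0).sum(axis=1) >= min_presence
    if not keep.any():
        raise ValueError("no component present in enough samples")
    rows = [np.log10(r[r > 0]) for r in sub[keep]]
    lo = min(r.min() for r in rows)
    hi = max(r.max() for r in rows)
    centers = _window_grid(lo, hi, step)
    curves = np.array(
        [_counts_on_grid(r, centers, width) / (r.size * width) for r in rows]
    )
    return GroupedPattern(
        pattern="AFD", group=group, window_centers=centers,
        mean_curve=curves.mean(axis=0), sd_band=curves.std(axis=0),
        window_width=width, step=step, n_excluded=int((~keep).sum()),
        extras={"per_component": curves,
                "component_ids": list(table.component_ids[keep])},
    )


def band_agreement(a: GroupedPattern, b: GroupedPattern) -> float:
    """Fraction of windows (over the overlapping support) where each
    curve lies inside the other's sd band; curves are compared by
    linear interpolation since the two grids are anchored to their own
    data ranges. Used to compare H and U pattern curves."""
    lo = max(a.window_centers.min(), b.window_centers.min())
    hi = min(a.window_centers.max(), b.window_centers.max())
    if lo > hi:
        raise ValueError("patterns share no windows")
    xs = np.unique(np.concatenate([
        a.window_centers[(a.window_centers >= lo) & (a.window_centers <= hi)],
        b.window_centers[(b.window_centers >= lo) & (b.window_centers <= hi)],
    ]))
    ca = np.interp(xs, a.window_centers, a.mean_curve)
    sa = np.interp(xs, a.window_centers, a.sd_band)
    cb = np.interp(xs, b.window_centers, b.mean_curve)
    sb = np.interp(xs, b.window_centers, b.sd_band)
    ok = (np.abs(ca - cb) <= sb) | (np.abs(ca - cb) <= sa)
    return float(ok.mean())
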