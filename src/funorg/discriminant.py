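"""Discriminant directions in functional space, projected on COG categories.

A discriminant direction xi is a vector in functional space pointing
from the healthy toward the unhealthy condition. Two constructions are
supported:

* MA method — the difference of group mean abundances,
  xi_i = MA_i(U) - MA_i(H);
* SVM method — the normal of the maximum-margin hyperplane of a linear
  support vector machine trained to separate H from U samples, with the
  sign fixed so that xi points from the H side to the U side.

Either xi is then projected onto the COG functional categories: each
function contributes xi_f split equally across its annotated letters,
unannotated mass is reported as leakage, and the 21-letter profile is
normalized to unit Euclidean length so that observed and null profiles
compare as directions. Significance per category is judged against the
same label-permutation null as the differential abundance analysis
(the whole pipeline — direction, projection, normalization — is
recomputed for every relabeling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .daa import DEFAULT_N_NULL, NullEnsemble, flag_anomalies, permutation_null
from .gcn import CategoryAnnotation
from .tables import CompositionTable, group_samples

__all__ = [
    "CategoryProjection",
    "DiscriminantProfile",
    "ma_direction",
    "svm_direction",
    "project_to_categories",
    "category_discriminant",
]


def ma_direction(table: CompositionTable, labels: pd.Series,
                 groups: tuple[str, str] = ("H", "U")) -> pd.Series:
    """xi_i = MA_i(U) - MA_i(H) over all functions (no logs, zeros kept)."""
    g_ref, g_alt = groups
    cols_ref = group_samples(labels, g_ref)
    cols_alt = group_samples(labels, g_alt)
    if len(cols_ref) == 0 or len(cols_alt) == 0:
        raise ValueError("both groups must be nonempty")
    xi = table.values[cols_alt].mean(axis=1) - table.values[cols_ref].mean(axis=1)
    xi.name = "xi"
    return xi


def svm_direction(table: CompositionTable, labels: pd.Series,
                  groups: tuple[str, str] = ("H", "U"),
                  regularization: float = 1.0) -> pd.Series:
    """Hyperplane normal of a linear SVM separating the two groups.

    Features are the raw functional compositions (no standardization:
    the compositional scale is meaningful, and the MA method uses it).
    The sign is fixed so that xi . (mean_U - mean_H) > 0.
    """
    g_ref, g_alt = groups
    cols_ref = group_samples(labels, g_ref)
    cols_alt = group_samples(labels, g_alt)
    if len(cols_ref) < 2 or len(cols_alt) < 2:
        raise ValueError("each group needs at least 2 samples for the SVM")
    X = table.values.T.to_numpy()
    y = (labels.reindex(table.sample_ids) == g_alt).to_numpy().astype(int)
    clf = SVC(kernel="linear", C=regularization)
    clf.fit(X, y)
    w = clf.coef_.ravel().copy()
    diff = table.values[cols_alt].mean(axis=1) - table.values[cols_ref].mean(axis=1)
    if float(w @ diff.to_numpy()) < 0:
        w = -w
    return pd.Series(w, index=table.component_ids, name="xi")


@dataclass
class CategoryProjection:
    """COG-category projection of a discriminant direction."""

    values: pd.Series       # unit-L2-normalized, indexed by category letter
    raw: pd.Series          # before normalization
    leakage: float          # summed xi of unannotated functions

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(self.values.to_numpy()))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("category profile must have unit Euclidean norm")


def _membership(annotation: CategoryAnnotation,
                function_ids) -> tuple[np.ndarray, np.ndarray, list]:
    """Equal-split membership matrix M (letters x functions) and the
    covered-function mask; M[c, f] = 1/k for each of f's k letters."""
    letters = list(annotation.alphabet)
    pos = {c: i for i, c in enumerate(letters)}
    M = np.zeros((len(letters), len(function_ids)))
    covered = np.zeros(len(function_ids), dtype=bool)
    for j, fid in enumerate(function_ids):
        key = str(fid)
        if key in annotation:
            cats = annotation.categories(key)
            covered[j] = True
            for c in cats:
                M[pos[c], j] = 1.0 / len(cats)
    return M, covered, letters


def _project(xi_values: np.ndarray, M: np.ndarray,
             covered: np.ndarray) -> tuple[np.ndarray, float]:
    raw = M @ xi_values
    norm = float(np.linalg.norm(raw))
    if norm == 0:
        raise ValueError("zero direction cannot be normalized")
    leakage = float(xi_values[~covered].sum())
    return raw, leakage


def project_to_categories(xi: pd.Series,
                          annotation: CategoryAnnotation) -> CategoryProjection:
    """Equal-split projection of xi over the annotation alphabet.

    A function annotated to k letters contributes xi_f / k to each, so
    the unnormalized letter sums plus the unannotated leakage conserve
    the total xi mass.
    """
    M, covered, letters = _membership(annotation, xi.index)
    if not covered.any():
        raise ValueError("annotation covers no function in xi's support")
    raw, leakage = _project(xi.to_numpy(dtype=float), M, covered)
    raw_s = pd.Series(raw, index=letters)
    return CategoryProjection(values=raw_s / np.linalg.norm(raw),
                              raw=raw_s, leakage=leakage)


@dataclass
class DiscriminantProfile:
    """Observed category profile with its permutation-null band and flags."""

    method: str
    xi: pd.Series
    category_values: pd.Series
    null_band: NullEnsemble
    flags: pd.Series
    leakage: float

    @property
    def enriched(self) -> list:
        return list(self.flags.index[self.flags == "above"])

    @property
    def depleted(self) -> list:
        return list(self.flags.index[self.flags == "below"])


def _direction(method: str, table, labels, groups, regularization):
    if method.upper() == "MA":
        return ma_direction(table, labels, groups)
    if method.upper() == "SVM":
        return svm_direction(table, labels, groups, regularization)
    raise ValueError(f"unknown method {method!r} (expected 'MA' or 'SVM')")


def category_discriminant(
    table: CompositionTable,
    labels: pd.Series,
    annotation: CategoryAnnotation,
    method: str = "MA",
    n_null: int = DEFAULT_N_NULL,
    seed: int | None = None,
    groups: tuple[str, str] = ("H", "U"),
    regularization: float = 1.0,
) -> DiscriminantProfile:
    """Observed category profile vs the label-permutation null.

    Every null realization repeats the full pipeline — direction,
    category projection, unit normalization — on shuffled labels.
    Categories above the band are enriched in the second group,
    categories below are depleted.
    """
    xi = _direction(method, table, labels, groups, regularization)
    proj = project_to_categories(xi, annotation)
    M, covered, _ = _membership(annotation, table.component_ids)

    def stat(tbl: CompositionTable, lab: pd.Series) -> np.ndarray:
        d = _direction(method, tbl, lab, groups, regularization)
        raw, _leak = _project(d.to_numpy(dtype=float), M, covered)
        return raw / np.linalg.norm(raw)

    null = permutation_null(table, labels, stat, n_realizations=n_null, seed=seed)
    flags = pd.Series(
        flag_anomalies(proj.values.to_numpy(), null),
        index=proj.values.index, name="flag",
    )
    return DiscriminantProfile(
        method=method.upper(), xi=xi, category_values=proj.values,
        null_band=null, flags=flags, leakage=proj.leakage,
    )
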