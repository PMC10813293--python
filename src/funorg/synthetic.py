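"""Synthetic gut-microbiome cohorts with known ground truth.

The generator emulates the statistical structure the analysis relies
on, without modelling sequencing itself:

* per-taxon mean abundances follow a lognormal mean-abundance law;
* per-sample abundances fluctuate around those means with a gamma law
  of fixed shape (Taylor-like variance scaling);
* read counts are multinomial with probability proportional to
  abundance times genome length, so the length bias that the
  normalization step corrects is actually present;
* a Genomic Content Network with a functionally redundant core (core
  functions carried by every genome, with genome-independent copy
  numbers) plus category-coherent accessory functions;
* optional planted effects: taxa rich in chosen COG categories are
  boosted (or depleted) in the unhealthy group, and a shared latent
  factor with group-specific loading drives a block of high-abundance
  taxa, producing a correlated functional core that is stronger in one
  group than the other.

Everything is deterministic given ``SimParams.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .gcn import COG_ALPHABET, GCN, CategoryAnnotation, write_gcn
from . import io as _io
from .tables import CountTable

__all__ = ["SimParams", "GroundTruth", "generate_gcn", "generate_study",
           "write_study", "null_params"]


@dataclass(frozen=True)
class SimParams:
    """Knobs of the synthetic cohort generator.

    Defaults give a desk-scale cohort mirroring the study design: 67
    healthy (H) and 151 unhealthy (U) stool samples, a few hundred taxa
    and functions, and no planted group difference (``effect_size=1``).
    """

    n_taxa: int = 300
    n_functions: int = 800
    n_categories: int = 21
    n_samples_H: int = 67
    n_samples_U: int = 151
    reads_per_sample: int = 100_000
    #: lognormal mean-abundance law (natural-log units)
    mad_log_mean: float = 0.0
    mad_log_sd: float = 1.5
    #: gamma shape of per-sample abundance fluctuations
    afd_shape: float = 1.0
    #: genome lengths lognormal around 3 Mb
    genome_length_log_mean: float = math.log(3e6)
    genome_length_log_sd: float = 0.35
    #: fraction of functions carried by every genome
    core_fraction: float = 0.3
    enriched_categories: frozenset = frozenset()
    depleted_categories: frozenset = frozenset()
    #: multiplicative abundance boost applied in U samples (>= 1)
    effect_size: float = 1.0
    #: latent-factor loading of the correlated taxon block, per group
    core_corr_H: float = 0.9
    core_corr_U: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_H < 2 or self.n_samples_U < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        if not 0 <= self.core_fraction <= 1:
            raise ValueError("core_fraction must lie in [0, 1]")
        if self.n_functions < self.n_categories:
            raise ValueError("need at least one function per category")
        if not (0 <= self.core_corr_H <= 1 and 0 <= self.core_corr_U <= 1):
            raise ValueError("latent-factor loadings must lie in [0, 1]")
        enr = frozenset(self.enriched_categories)
        dep = frozenset(self.depleted_categories)
        if enr & dep:
            raise ValueError("enriched and depleted category sets overlap")
        alphabet = set(COG_ALPHABET[: self.n_categories])
        if (enr | dep) - alphabet:
            raise ValueError("planted categories outside the category alphabet")
        object.__setattr__(self, "enriched_categories", enr)
        object.__setattr__(self, "depleted_categories", dep)

    @property
    def letters(self) -> tuple:
        return COG_ALPHABET[: self.n_categories]


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    enriched_categories: frozenset
    depleted_categories: frozenset
    core_function_ids: list
    boosted_taxon_ids: list

    def __post_init__(self) -> None:
        if set(self.enriched_categories) & set(self.depleted_categories):
            raise ValueError("enriched and depleted sets overlap")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["enriched_categories"] = sorted(d["enriched_categories"])
        d["depleted_categories"] = sorted(d["depleted_categories"])
        return json.dumps(d, indent=1)


def _ids(prefix: str, n: int) -> pd.Index:
    width = max(4, len(str(n)))
    return pd.Index(f"{prefix}{i:0{width}d}" for i in range(1, n + 1))


def _taxon_clusters(params: SimParams) -> np.ndarray:
    """Category letter of each taxon's cluster, assigned cyclically."""
    letters = params.letters
    return np.array([letters[i % len(letters)] for i in range(params.n_taxa)])


#: carriage probability of an accessory function inside / outside its
#: category's taxon cluster
P_CLUSTER = 0.6
P_BACKGROUND = 0.3
#: fraction of taxa forming the planted "signature" set
SIGNATURE_FRACTION = 0.10


def _signature_taxa(params: SimParams) -> np.ndarray:
    """Indices of the planted signature taxa (empty when nothing planted).

    Signature taxa are the carriers of the planted group difference:
    rich in the enriched categories, devoid of accessory functions of
    the depleted ones, and exactly community-average in every other
    category, so boosting them leaves neutral categories unshifted.
    """
    if not (params.enriched_categories or params.depleted_categories):
        return np.array([], dtype=int)
    n_sig = max(2, round(SIGNATURE_FRACTION * params.n_taxa))
    return np.arange(params.n_taxa - n_sig, params.n_taxa)


def generate_gcn(params: SimParams) -> tuple[GCN, CategoryAnnotation]:
    """Sample a GCN plus category annotation.

    Core functions (a ``core_fraction`` share) appear in every genome
    with a genome-independent copy number, so full redundancy
    (``core_fraction=1``) makes all genomes functionally identical.
    Accessory functions are carried mainly by the taxa of their
    category's cluster (p=0.8) and sporadically elsewhere (p=0.05).
    About 10% of functions carry a second category letter.

    When enrichment/depletion is planted, a small signature taxon set
    carries accessory functions of the enriched categories at an
    elevated rate (chosen so the extra mass balances the depleted
    categories' missing mass), none of the depleted categories, and
    the community-average rate elsewhere.
    """
    rng = np.random.default_rng([params.seed, 0])
    letters = params.letters
    fun_ids = _ids("F", params.n_functions)
    tax_ids = _ids("T", params.n_taxa)
    clusters = _taxon_clusters(params)
    signature = _signature_taxa(params)
    is_sig = np.zeros(params.n_taxa, dtype=bool)
    is_sig[signature] = True

    # mean accessory carriage rate and the signature rates: average for
    # neutral letters, 0 for depleted, elevated for enriched so that the
    # signature's total accessory content stays community-representative
    n_cat = len(letters)
    p_avg = P_CLUSTER / n_cat + P_BACKGROUND * (n_cat - 1) / n_cat
    n_enr = max(len(params.enriched_categories), 1)
    # enrichment factor: absorb the depleted categories' missing mass,
    # with a floor of 2x so enrichment is planted even when nothing is
    # depleted
    p_enr = p_avg * max(2.0, 1.0 + len(params.depleted_categories) / n_enr)

    n_core = round(params.core_fraction * params.n_functions)
    rows, cols, data = [], [], []

    # core block: carried by every genome. Copy numbers are Poisson
    # around a per-function rate that itself varies lognormally across
    # functions, so core mean abundances spread smoothly over a range
    # (rather than clumping at integer copy numbers) while individual
    # genomes still differ in dosage.
    core_rate = rng.lognormal(0.3, 0.7, size=n_core)
    for fi in range(n_core):
        copies = 1 + np.minimum(rng.poisson(core_rate[fi], size=params.n_taxa), 5)
        rows.extend([fi] * params.n_taxa)
        cols.extend(range(params.n_taxa))
        data.extend(copies)

    # accessory block: category-coherent clusters
    primary = np.array(
        [letters[i % len(letters)] for i in range(params.n_functions)]
    )
    for fi in range(n_core, params.n_functions):
        cat = primary[fi]
        in_cluster = clusters == cat
        p = np.where(in_cluster, P_CLUSTER, P_BACKGROUND)
        p[is_sig] = 0.0  # signature carriage is stratified separately below
        carry = rng.random(params.n_taxa) < p
        if not carry.any():
            carry[rng.choice(np.flatnonzero(in_cluster & ~is_sig))] = True
        idx = np.flatnonzero(carry)
        rows.extend([fi] * idx.size)
        cols.extend(idx)
        data.extend(rng.integers(1, 4, size=idx.size))

    # signature genomes: stratified accessory carriage — every signature
    # taxon carries an exact per-category number of accessory functions
    # (community-average for neutral letters, elevated for enriched,
    # none for depleted) at a fixed copy number, so each signature
    # genome is individually representative of the neutral categories
    # no matter how abundances weight the signature set
    if is_sig.any():
        acc_by_cat = {
            c: np.flatnonzero(primary[n_core:] == c) + n_core for c in letters
        }
        n_sig = signature.size
        for c, funs in acc_by_cat.items():
            if c in params.depleted_categories or funs.size == 0:
                continue
            rate = p_enr if c in params.enriched_categories else p_avg
            # largest-remainder allocation: the signature set as a whole
            # carries exactly the target rate, spread evenly over taxa
            total = max(n_sig, round(rate * funs.size * n_sig))
            base, extra = divmod(total, n_sig)
            for j, t in enumerate(signature):
                k = min(base + (1 if j < extra else 0), funs.size)
                chosen = rng.choice(funs, size=k, replace=False)
                rows.extend(chosen)
                cols.extend([t] * k)
                data.extend([2] * k)

    weights = sp.csr_matrix(
        (np.asarray(data), (np.asarray(rows), np.asarray(cols))),
        shape=(params.n_functions, params.n_taxa),
    )
    gcn = GCN(weights, fun_ids, tax_ids)

    mapping: dict[str, frozenset] = {}
    double = rng.random(params.n_functions) < 0.10
    for fi, fid in enumerate(fun_ids):
        cats = {primary[fi]}
        if double[fi]:
            other = letters[rng.integers(len(letters))]
            cats.add(other)  # may coincide with primary; then single
        mapping[fid] = frozenset(cats)
    annotation = CategoryAnnotation(mapping, alphabet=letters)
    return gcn, annotation


def generate_study(
    params: SimParams,
) -> tuple[CountTable, GCN, CategoryAnnotation, pd.Series, GroundTruth]:
    """Sample a full study: counts, GCN, annotation, labels, ground truth."""
    gcn, annotation = generate_gcn(params)
    rng = np.random.default_rng([params.seed, 1])

    n_H, n_U = params.n_samples_H, params.n_samples_U
    n_s = n_H + n_U
    sample_ids = pd.Index(
        [f"H{i:03d}" for i in range(1, n_H + 1)]
        + [f"U{i:03d}" for i in range(1, n_U + 1)]
    )
    labels = pd.Series(["H"] * n_H + ["U"] * n_U, index=sample_ids, name="group")

    mean_ab = rng.lognormal(params.mad_log_mean, params.mad_log_sd, params.n_taxa)
    # signature taxa sit in the upper-middle of the abundance law (their
    # z-scores drawn uniformly in [0.2, 1]): abundant enough for the
    # planted boost to register, but never a dominating bloom, so the
    # signature's total abundance share is stable across realizations
    signature = _signature_taxa(params)
    if signature.size:
        z = rng.uniform(0.2, 1.0, size=signature.size)
        mean_ab[signature] = np.exp(params.mad_log_mean + params.mad_log_sd * z)
    lengths = pd.Series(
        rng.lognormal(params.genome_length_log_mean,
                      params.genome_length_log_sd, params.n_taxa),
        index=gcn.taxon_ids, name="genome_length",
    )

    # gamma fluctuations with unit mean; Taylor-like variance scaling
    k = params.afd_shape
    noise = rng.gamma(k, 1.0 / k, size=(params.n_taxa, n_s))

    # correlated core: one shared latent factor drives the top-abundance
    # taxon block, with group-specific loading. The factor acts as a
    # seesaw — one half of the block swings up while the other swings
    # down — so it moves relative abundances (a factor multiplying the
    # whole block would largely cancel under compositional closure).
    n_block = max(2, params.n_taxa // 4)
    block = np.argsort(mean_ab)[-n_block:]
    z = rng.standard_normal(n_s)
    # seesaw sides alternate within each category cluster, so the two
    # sides are balanced in functional-category content and the factor
    # moves functions rather than whole categories
    clusters_all = _taxon_clusters(params)
    order = np.lexsort((-mean_ab[block], clusters_all[block]))
    side = np.empty(n_block)
    side[order] = np.where(np.arange(n_block) % 2 == 0, 1.0, -1.0)
    # lognormal seesaw with unit mean on both sides
    sigma_f = 0.5
    latent = np.exp(sigma_f * side[:, None] * z[None, :] - 0.5 * sigma_f ** 2)
    loading = np.where(np.arange(n_s) < n_H, params.core_corr_H, params.core_corr_U)
    mix = noise.copy()
    mix[block, :] = (1.0 - loading)[None, :] * noise[block, :] \
        + loading[None, :] * latent
    abundance = mean_ab[:, None] * mix

    # planted differential abundance: boost the signature taxa in U
    is_U = np.arange(n_s) >= n_H
    planted = params.effect_size > 1 and signature.size > 0
    if planted:
        abundance[np.ix_(signature, is_U)] *= params.effect_size

    # reads: multinomial with genome-length bias
    p = abundance * lengths.to_numpy()[:, None]
    p /= p.sum(axis=0)
    counts = np.empty((params.n_taxa, n_s), dtype=np.int64)
    for s in range(n_s):
        counts[:, s] = rng.multinomial(params.reads_per_sample, p[:, s])
    count_table = CountTable(
        pd.DataFrame(counts, index=gcn.taxon_ids, columns=sample_ids), lengths
    )

    n_core = round(params.core_fraction * params.n_functions)
    truth = GroundTruth(
        enriched_categories=params.enriched_categories if planted else frozenset(),
        depleted_categories=params.depleted_categories if planted else frozenset(),
        core_function_ids=list(gcn.function_ids[:n_core]),
        boosted_taxon_ids=list(gcn.taxon_ids[signature]) if planted else [],
    )
    return count_table, gcn, annotation, labels, truth


def null_params(**overrides) -> SimParams:
    """Null configuration: no planted effect, equal latent loadings."""
    base = dict(effect_size=1.0, enriched_categories=frozenset(),
                depleted_categories=frozenset(),
                core_corr_H=0.6, core_corr_U=0.6)
    base.update(overrides)
    return SimParams(**base)


def write_study(params: SimParams, out_dir: str | os.PathLike) -> GroundTruth:
    """Generate a study and write the five input TSVs plus ground truth."""
    counts, gcn, annotation, labels, truth = generate_study(params)
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    prov = {"stage": "simulate", "seed": params.seed}
    _io.write_table(counts.counts, os.path.join(out, "counts.tsv"),
                    provenance=prov, index_label="taxon_id")
    _io.write_table(counts.genome_lengths.to_frame(),
                    os.path.join(out, "genome_lengths.tsv"),
                    provenance=prov, index_label="taxon_id")
    write_gcn(gcn, os.path.join(out, "gcn.tsv"), provenance=prov)
    _io.write_annotation(annotation.mapping, os.path.join(out, "annotation.tsv"),
                         provenance=prov)
    _io.write_table(labels.to_frame(), os.path.join(out, "labels.tsv"),
                    provenance=prov, index_label="sample_id")
    with open(os.path.join(out, "ground_truth.json"), "w") as fh:
        fh.write(truth.to_json())
    return truth
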