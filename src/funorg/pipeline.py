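"""End-to-end orchestration: simulate/load -> normalize -> project ->
patterns -> differential abundance -> discriminant -> correlation.

A run is described by a :class:`RunConfig` (typically loaded from a
YAML file): either paths to the five input TSVs (counts, genome
lengths, GCN edge list, category annotation, sample labels) or a
``simulate`` block of generator parameters — exactly one of the two.
``run_all`` executes the stages in order, writes each stage's TSV
outputs with a provenance header, and returns a machine-readable
report (also written as JSON).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .correlation import correlation_profile, correlation_matrix, eigenvalue_decay
from .daa import delta_histogram, delta_histogram_statistic, flag_anomalies, \
    log_differential, permutation_null
from .discriminant import category_discriminant
from .gcn import CategoryAnnotation, read_gcn
from .macroeco import afd, band_agreement, mean_abundance_distribution, \
    occurrence_abundance, sad
from .gcn import project
from .normalize import build_taxonomic_table, default_eta_grid
from .synthetic import SimParams, generate_study
from .tables import CountTable

__all__ = ["RunConfig", "run_all", "load_config", "default_config"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    inputs: dict | None = None        # paths: counts, lengths, gcn, annotation, labels
    simulate: dict | None = None      # SimParams fields
    eta_grid: tuple = (1e-8, 1e-1, 50)
    eta0: float | None = None
    window_width: float = 0.5
    window_step: float = 0.1
    n_null: int = 150
    seed: int = 0
    out_dir: str = "funorg_run"

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError(
                "exactly one of 'inputs' and 'simulate' must be present"
            )

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def default_config() -> dict:
    """All configurable defaults, as a plain dictionary."""
    cfg = dataclasses.asdict(RunConfig(simulate={}))
    cfg["simulate"] = dataclasses.asdict(SimParams())
    for key in ("enriched_categories", "depleted_categories"):
        cfg["simulate"][key] = sorted(cfg["simulate"][key])
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    stray = set(raw) - known
    if stray:
        raise ValueError(f"unknown config keys: {sorted(stray)}")
    return RunConfig(**raw)


def _load_inputs(cfg: RunConfig):
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        sim.setdefault("seed", cfg.seed)
        for key in ("enriched_categories", "depleted_categories"):
            if key in sim:
                sim[key] = frozenset(sim[key])
        params = SimParams(**sim)
        counts, gcn, annotation, labels, truth = generate_study(params)
        return counts, gcn, annotation, labels, truth
    paths = cfg.inputs
    counts = _io.read_count_table(paths["counts"], paths["lengths"])
    gcn = read_gcn(paths["gcn"])
    annotation = CategoryAnnotation(_io.read_annotation(paths["annotation"]))
    labels = _io.read_labels(paths["labels"])
    return counts, gcn, annotation, labels, None


def _pattern_tsv(pattern, path, prov):
    df = pd.DataFrame(
        {"center": pattern.window_centers, "mean": pattern.mean_curve,
         "sd": pattern.sd_band}
    )
    _io.write_table(df, path, provenance=prov, index_label="window")


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage in order; returns (and writes) the report."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    prov_base = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    def prov(stage):
        return {**prov_base, "stage": stage}

    def out(name):
        return os.path.join(cfg.out_dir, name)

    report: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    counts, gcn, annotation, labels, truth = _load_inputs(cfg)

    # normalize
    lo, hi, n = cfg.eta_grid
    grid = default_eta_grid(lo, hi, int(n))
    td, eta0 = build_taxonomic_table(counts, eta_grid=grid, eta0=cfg.eta0)
    report["eta0"] = eta0
    _io.write_composition(td, out("taxonomic_table.tsv"), provenance=prov("normalize"))

    # project
    fd = project(gcn, td)
    _io.write_composition(fd, out("functional_table.tsv"), provenance=prov("project"))

    # macroecological patterns (functional), per group
    w, st = cfg.window_width, cfg.window_step
    agreement = {}
    for name, fn in (("MAD", mean_abundance_distribution), ("SAD", sad), ("AFD", afd)):
        pats = {g: fn(fd, labels, g, width=w, step=st) for g in ("H", "U")}
        for g, p in pats.items():
            _pattern_tsv(p, out(f"pattern_{name.lower()}_{g}.tsv"), prov("patterns"))
        agreement[name] = band_agreement(pats["H"], pats["U"])
    report["pattern_band_agreement"] = agreement
    for g in ("H", "U"):
        oa = occurrence_abundance(fd, labels, g, width=w, step=st)
        df = pd.DataFrame({"center": oa.window_centers, "mean": oa.mean_occurrence,
                           "sigma_plus": oa.sigma_plus, "sigma_minus": oa.sigma_minus})
        _io.write_table(df, out(f"pattern_oa_{g}.tsv"), provenance=prov("patterns"))

    # differential functional abundance with permutation null
    profile = log_differential(fd, labels)
    hist = delta_histogram(profile, width=w, step=st)
    stat = delta_histogram_statistic(hist.window_centers, width=w, step=st)
    null = permutation_null(fd, labels, stat, n_realizations=cfg.n_null,
                            seed=cfg.seed)
    flags = flag_anomalies(hist.density, null)
    _io.write_table(
        profile.delta.to_frame("delta"), out("daa_delta.tsv"), provenance=prov("daa")
    )
    _io.write_table(
        pd.DataFrame({"center": hist.window_centers, "density": hist.density,
                      "null_mean": null.mean, "sigma_plus": null.sigma_plus,
                      "sigma_minus": null.sigma_minus, "flag": flags}),
        out("daa_histogram.tsv"), provenance=prov("daa"),
    )
    report["daa"] = {
        "n_components": int(profile.delta.size),
        "n_excluded": len(profile.excluded_ids),
        "fraction_windows_inside_band": float((flags == "inside").mean()),
    }

    # discriminant directions
    report["discriminant"] = {}
    for method in ("MA", "SVM"):
        dp = category_discriminant(fd, labels, annotation, method=method,
                                   n_null=cfg.n_null, seed=cfg.seed)
        _io.write_table(
            pd.DataFrame({"value": dp.category_values,
                          "null_mean": dp.null_band.mean,
                          "sigma_plus": dp.null_band.sigma_plus,
                          "sigma_minus": dp.null_band.sigma_minus,
                          "flag": dp.flags}),
            out(f"discriminant_{method.lower()}.tsv"),
            provenance=prov("discriminant"), index_label="category",
        )
        report["discriminant"][method] = {
            "enriched": dp.enriched, "depleted": dp.depleted,
            "leakage": dp.leakage,
        }

    # correlation structure
    report["correlation"] = {}
    for g in ("H", "U"):
        summary = correlation_matrix(fd, labels, g)
        centers_e, even = correlation_profile(summary, "even")
        _, weighted = correlation_profile(summary, "weighted")
        _io.write_table(
            pd.DataFrame({"center": centers_e, "even": even, "weighted": weighted}),
            out(f"correlation_profile_{g}.tsv"), provenance=prov("correlation"),
        )
        spec = eigenvalue_decay(fd, labels, g, "correlation")
        _io.write_table(
            pd.DataFrame({"eigenvalue": spec.eigenvalues,
                          "normalized": spec.normalized}),
            out(f"correlation_spectrum_{g}.tsv"), provenance=prov("correlation"),
            index_label="rank",
        )
        bw = centers_e[1] - centers_e[0]
        report["correlation"][g] = {
            "weighted_mass_absC_gt_0.8": float(weighted[np.abs(centers_e) > 0.8].sum() * bw),
            "even_mass_absC_gt_0.8": float(even[np.abs(centers_e) > 0.8].sum() * bw),
            "top5_cumulative_fraction": spec.cumulative_fraction(5),
        }

    # ground-truth comparison, when simulated
    if truth is not None:
        flagged = report["discriminant"]["MA"]
        report["ground_truth"] = {
            "planted_enriched": sorted(truth.enriched_categories),
            "planted_depleted": sorted(truth.depleted_categories),
            "recovered_enriched_MA": sorted(
                set(flagged["enriched"]) & set(truth.enriched_categories)
            ),
            "recovered_depleted_MA": sorted(
                set(flagged["depleted"]) & set(truth.depleted_categories)
            ),
        }

    with open(out("report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
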