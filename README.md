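# funorg

Functional organization of gut microbiomes in health and disease, as a
tested, reusable analysis pipeline.

Shotgun metagenomics of stool samples yields a taxon-by-sample read
count table. Taxonomic composition alone is a poor marker of dysbiosis:
strong functional redundancy means *which* microbes are present matters
less than *what they can do*. `funorg` therefore projects taxonomic
compositions into functional space and characterizes healthy (H) versus
unhealthy (U) cohorts at the level of functional abundances, category
enrichment, and functional correlation structure.

## The model

Three linked representations:

1. **Taxonomic table** `T_ts` — read counts are corrected for genome
   length (the probability of sampling a read scales with genome length
   `L_t`) and closed to relative abundances:

   `T_ts = (reads_ts / L_t) / Σ_t' (reads_t's / L_t')`

   A detection threshold `η₀` removes false-positive assignments. It is
   selected as the logarithmic flex point of the mean alpha-diversity
   curve, `η₀ = argmin_η d⟨α(η)⟩/d log η`, where `⟨α(η)⟩` is the mean
   number of components above `η`; columns are then renormalized.

2. **Genomic Content Network** `G_ft` — a weighted bipartite network
   linking genomes (taxa) to functions (orthologous gene groups); the
   weight is the copy number of function `f` in genome `t`. Acting as a
   linear operator it maps taxonomic to functional compositions:

   `Φ_fs = Σ_t G_ft · T_ts`, column-normalized.

3. **Group comparisons** on either table:
   * macroecological patterns (MAD, occurrence–abundance, SAD, AFD) as
     rolling log-binned histograms, per group;
   * differential abundance `δ_i = log₁₀ MA_i(U) − log₁₀ MA_i(H)`
     against a null of 150 group-size-preserving label shuffles,
     with asymmetric bands (σ± = RMS of above-/below-mean deviations);
   * discriminant directions `ξ` in functional space — the group-mean
     difference (MA method) or a linear SVM's hyperplane normal (SVM
     method) — projected onto the 21 one-letter COG categories,
     unit-normalized, and flagged against the same permutation null;
   * Pearson correlation structure: couple abundance `A_ij = MA_i·MA_j`
     versus `C_ij`, even and A-weighted correlation profiles, and
     correlation/covariance eigenvalue decay (effective dimensionality).

A fully parameterized synthetic-cohort generator (`funorg.synthetic`)
provides ground-truth studies — lognormal mean abundances, gamma
fluctuations, genome-length read bias, a functionally redundant core,
category-coherent accessory functions, plantable category
enrichment/depletion, and a latent factor producing a correlated
functional core with group-specific strength — so the whole pipeline is
testable without downloads.

## Worked example

Simulate a cohort of 30 healthy and 30 unhealthy samples (300 taxa, 800
functions) in which taxa rich in carbohydrate-metabolism (G) and
ion-transport (P) functions are boosted fivefold in the unhealthy
group, and run every stage:

```python
from funorg.pipeline import RunConfig, run_all

cfg = RunConfig(
    simulate=dict(n_taxa=300, n_functions=800, n_samples_H=30, n_samples_U=30,
                  enriched_categories=["G", "P"],
                  depleted_categories=["D", "J", "O"], effect_size=5.0),
    n_null=150, seed=7, out_dir="example_run")
report = run_all(cfg)
```

The run prints/writes (abridged):

```
eta0: 0.003728
MA  enriched: ['G', 'P'] depleted: ['J', 'D', 'O']
SVM enriched: ['G', 'P'] depleted: ['J', 'D', 'O']
H weighted |C|>0.8 mass: 0.152  top-5 eigenvalue share: 0.692
U weighted |C|>0.8 mass: 0.000  top-5 eigenvalue share: 0.518
```

Reading: the flex-point threshold settled at `η₀ ≈ 3.7×10⁻³`; both
discriminant methods flag exactly the planted categories — G and P
enriched, D (cell cycle), J (translation), O (protein turnover)
depleted in the unhealthy group; and the healthy cohort shows the
stronger correlated functional core — more A-weighted mass at
`|C| > 0.8` and a larger top-5 eigenvalue share (smaller effective
dimensionality). On null cohorts (no planted effect) the H and U
macroecological curves coincide within each other's bands — first-order
patterns carry no group signature — while a strong planted boost does
leave a visible SAD footprint.

Every stage is also exposed as a CLI (`funorg simulate | normalize |
project | patterns | daa | discriminant | correlation | run-all`;
`funorg config --defaults` prints all knobs), reading and writing plain
TSV with provenance headers.

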