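# Methods

## Pipeline

The analysis operates on compositional tables: component × sample
matrices whose columns sum to 1, holding either relative taxon
abundances (T) or relative function abundances (Φ). All group-level
statistics are computed identically for taxa and functions.

**Length normalization.** Read counts are divided by genome length
before closure, turning read proportions into cell-count proportions
under the assumption that read sampling probability is proportional to
genome length. Empty sample columns are an error, not a silent drop.

**Threshold selection.** The detection threshold η₀ is the logarithmic
flex point of the mean alpha-diversity curve: the grid point minimizing
the finite-difference d⟨α⟩/d log η (central differences, one-sided at
the ends). Counting is strict (`> η`) and removal is strict (`< η₀`),
so a component exactly at the threshold survives both; argmin ties
break toward the smaller η (removes less). The default grid is 50
log-spaced points in [10⁻⁸, 10⁻¹], configurable. Note a structural
property of this rule: the flex point sits where the per-decade density
of components is largest, i.e. *inside* the low-abundance mode it is
meant to remove. On a bimodal spectrum it therefore removes the bulk of
that mode (everything below its density peak), not all of it.

**GCN projection.** Φ = G·T column-normalized, with sparse storage of
G and a hard error for taxa absent from the network (taxonomy and
function must stay consistently linked; silent drops would decouple
them). Projection is linear before the final normalization.

**Rolling histograms.** All abundance distributions use rolling
windows of constant width in log₁₀ space (width 0.5 decades, step 0.1
by default; the differential-abundance histogram uses the same
machinery on a linear axis). Windows are half-open
[c − w/2, c + w/2), so when step = width the windows tile the axis and
tallies are conserved. Density is count/(n·width).

**Pattern bands.** SAD bands are the across-sample standard deviation
of per-sample standardized log-abundance histograms; AFD bands the
across-component deviation; the occurrence–abundance profile reports
asymmetric σ± per window. The MAD is a single histogram of means with
no natural replicate axis, so its band is a declared choice: the
quadrature sum of the window counting error (√count scaled to density
units) and the across-sample spread of single-sample histograms
(intra-group variability). Components with zero group abundance are
excluded from log histograms and tallied; AFD requires presence in ≥2
group samples (a fluctuation needs two points).

**Permutation null.** Group labels are reshuffled preserving the two
group sizes, sampled uniformly with replacement over assignments; the
statistic (δ histogram on a fixed window grid, or the full
direction → category-projection → normalization pipeline) is recomputed
per replicate. The band is the pointwise replicate mean with
σ+ = RMS of above-mean deviations and σ− = RMS of below-mean
deviations; a point is flagged when it strictly exceeds mean + σ+ or
falls below mean − σ−. 150 realizations by default. These are
~1-sigma envelopes: on a true null an exchangeable observation pokes
outside somewhere in a 21-coordinate profile essentially always, so
isolated single-category excursions should be read as band-level
noise; the planted-effect calls reported by the tests are the
categories that exceed the band jointly and reproducibly.

**Discriminant directions.** The MA direction is the plain group-mean
difference (compositional closure makes it sum to zero). The SVM
direction is the hyperplane normal of `sklearn.svm.SVC(kernel=
"linear", C=1)` fit on raw compositions — no feature standardization,
because the compositional scale is meaningful and the MA method uses
it — sign-fixed to point from the H toward the U side. Multi-annotated
functions split their weight equally across their category letters;
unannotated mass is reported as leakage; the 21-letter profile is
normalized to unit Euclidean length so observed and null profiles are
compared as directions.

**Correlation structure.** Pearson correlations are computed on raw
relative abundances (no logs, no centered-log-ratio transform): C is
defined directly on component values, and log or CLR transforms would
silently change zero handling. Compositional closure can induce
spurious negative correlation; this is a known limitation shared with
the analysis the package implements. Zero-variance components are
dropped and listed. Couples with zero couple-abundance are excluded
from the log-axis 2D histogram (tallied) but retained in the even
profile. Eigenvalue spectra clip numerical negatives at zero; with n
samples and p > n components at most n − 1 eigenvalues are nonzero.

## Synthetic cohorts

The generator emulates the statistical features the method exercises,
not sequencing mechanics (no error model, no strain variation, no read
lengths).

* **Abundance laws.** Per-taxon mean abundances are lognormal
  (`mad_log_sd` = 1.5 natural-log units by default: ~4 decades of
  spread without single-taxon dominance of the community). Per-sample
  fluctuations are gamma with fixed shape (`afd_shape` = 1) and mean
  equal to the taxon's mean abundance — Taylor-like variance scaling.
  Read counts are multinomial with probability ∝ abundance × genome
  length (lengths lognormal around 3 Mb), so the length bias that
  normalization corrects is really present.
* **GCN.** A core fraction (30%) of functions is carried by every
  genome — functional redundancy — with Poisson copy numbers around a
  lognormally varying per-function rate, so core mean abundances spread
  smoothly instead of clumping at integer copy values. Accessory
  functions belong to category-coherent taxon clusters (carriage 0.6
  inside the cluster, 0.3 outside; the high background keeps category
  content spread over many carriers, as redundancy implies). 10% of
  functions carry a second category letter, exercising the equal-split
  projection rule.
* **Planted differential abundance.** A signature set (10% of taxa)
  carries accessory functions of the enriched categories at an elevated
  rate, none of the depleted categories, and exactly the
  community-average rate elsewhere (largest-remainder allocation, fixed
  copy number 2, every signature genome individually representative).
  The enrichment factor absorbs the depleted categories' missing mass,
  so the signature's total content is community-representative and
  boosting it in U (×`effect_size`) shifts only the planted categories.
  Signature abundances sit in the upper-middle of the abundance law
  (z-scores uniform in [0.2, 1]) so the planted mass share is stable
  across realizations. This construction is what makes exact category
  recovery a well-posed target; a cruder boost (e.g. whole category
  clusters) shifts every other category through renormalization.
* **Correlated core.** One latent standard-normal factor per sample
  drives the top abundance quartile of taxa with group-specific loading
  (0.9 in H, 0.3 in U by default), as a seesaw: half the block (chosen
  by alternating within category clusters, ordered by abundance) swings
  up as lognormal exp(+σz), the other half down as exp(−σz), σ = 0.5,
  both unit-mean. A factor multiplying a whole block would largely
  cancel under compositional closure; the seesaw moves relative
  abundances, producing strong positive and negative correlations among
  abundant functions in H and weak ones in U, while its category
  content cancels between the two sides. Mixing is linear:
  block abundance = mean × ((1 − ρ)·gamma + ρ·seesaw).

Passing tests on these cohorts show that the pipeline recovers effects
of the planted kind at desk scale (hundreds of taxa, 30 + 30 samples);
they do not show robustness to real-data features the generator omits
(sequencing error, compositional artifacts of extreme sparsity,
annotation noise, batch structure).

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run cohorts of 300 taxa ×
800 functions × 30 + 30 samples with 150-replicate nulls, 8–20 seeds
per property — sizes chosen so the full suite completes in about a
minute on one CPU while keeping the recovery and contrast statistics
stable. Every stochastic step takes an explicit seed; `SimParams.seed`
fixes every generated byte, and pipeline runs with the same
configuration and seed are byte-identical.

## Known limitations

* The flex-point threshold removes the bulk, not the entirety, of a
  low-abundance false-positive mode (see above).
* σ± bands are 1-sigma objects without multiplicity control; on a true
  null, scattered single-window or single-category excursions are
  expected (~32% of points), and the package reports them as such
  rather than applying a correction the method does not define.
* Correlations on raw compositions inherit closure-induced negative
  bias, strongest for the most abundant components.
* The generator's parameters are free knobs chosen for plausibility,
  not estimates fitted to any real cohort.
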