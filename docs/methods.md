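# Methods

This note documents the models, conventions and numerical choices behind
`vcmkit`, what the synthetic-data generators do and do not emulate, and the
known limitations. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Normalization chain

Raw peak-count matrices pass through a fixed chain, each stage stamping a
layer tag (`raw → size-normalized → residual → int-transformed`) and
refusing wrong-layer input:

1. **Paired-end doubling** (optional): counters that report half-fragments
   for paired-end data are corrected by multiplying all counts by two
   *before* size-factor estimation.
2. **Median-of-ratios size factors**: per sample, the median across peaks
   of the ratio to the per-peak geometric mean; peaks containing any zero
   are excluded from factor estimation (their geometric mean vanishes). A
   matrix with no all-positive peak row is an error.
3. **Covariate residualization**: per peak, OLS residuals against an
   intercept plus user-supplied covariates (population PCs, batch, sex, …).
   Covariates are inputs, never inferred; a rank-deficient design is
   rejected with the collinear columns named.
4. **Rank inverse-normal transform**: values replaced by
   Φ⁻¹((rank − 3/8)/(n + 1/4)) — the Blom offset, matching the common
   `qqnorm` convention — with ties averaged. The default transforms each
   *peak* across samples, which is what a downstream QTL regression
   requires; a per-sample mode (each individual's profile across peaks) is
   available behind a flag. Constant rows are an error, since the
   transform is undefined.

The residualize-then-transform order is fixed by this package; swapping the
two stages changes results only marginally for approximately normal
residuals but is deliberately not supported, to keep outputs reproducible.

## Module calling

The test universe is every unordered same-chromosome peak pair whose
interval midpoints lie within a window (default 2 Mb — bracketing the TAD
scale at which cis-coordination operates; configurable). Pearson r gets a
two-sided p from t = r·√((n−2)/(1−r²)) with n−2 df, and BH q-values are
computed per chromosome over the emitted pairs, so chromosomes do not
couple through the FDR step. At n ≈ 311 samples a 0.1% pair FDR
corresponds to r ≈ 0.24 (p ≈ 1.9×10⁻⁵) — lenient enough that occasional
spurious edges can merge neighboring modules, which is why the fixed
r > 0.5 threshold exists as the stricter default alternative.

Modules are connected components of the kept-edge graph; grouping is
therefore transitive by construction (a chain A–B–C groups even when A–C
itself is not significant). Components keep only positive-r edges by
default (module activity is a co-activation concept; a two-sided mode is
provided), never report singletons, and record the mean r over their kept
edges. For ≤ 12 peaks the implementation is verified exactly against a
hand-written BFS component oracle.

The hierarchical variant clusters peaks per chromosome with average linkage
on distance 1 − r (out-of-window pairs forced to r = 0) and reports the
*maximal* tree nodes whose mean within-node |r| meets the cut (default
0.5). This is a stated approximation to dedicated CRD-clustering tools, not
a re-implementation of any of them. Consensus merging unions members and
spans of span-overlapping modules across call sets and tags provenance;
mixed genome builds are refused.

## Activity scores and QTL scans

The activity score of a module is the first principal component of its
standardized member peaks, computed by SVD. PC1's sign is intrinsically
arbitrary; it is fixed by positive correlation with the mean standardized
member signal, so higher scores always mean more active chromatin. The
score is re-standardized (mean 0, variance 1) and the leading-eigenvalue
share recorded. The result is invariant to member order and to affine
rescaling of any member row.

QTL scans are per-(variant, target) OLS on additive dosage with an
intercept. Dosage is 0/1/2 (no dominance term); missing dosages are dropped
per test, never imputed; tests with constant dosage or fewer than 10
complete samples are flagged untestable and excluded from the FDR universe.
Because the FDR universe differs between analyses (genome-wide screens vs
TAD-restricted effect-size estimation), it is an explicit input. β equals
cov(dosage, target)/var(dosage) to 10⁻¹⁰ and matches statsmodels OLS in
tests. The three-way screen takes variants with q ≤ 0.10 in the
module-activity, expression and binding scans whose module has ≥ 2 member
elements, ordered by minimum q.

A consequence worth noting: because the activity score is standardized to
unit variance, the sampling sd of its genotype β at n = 300 and MAF 0.27 is
1/√(n·2p(1−p)) ≈ 0.09, and the planted effect is recovered with shrinkage
by the latent-factor sd √(1 + β²·2p(1−p)) ≈ 1.05. The benchmarks therefore
assess the estimator's bias (mean over replicate cohorts) and its
significance rate, not a per-cohort ±0.1 event whose probability is capped
near 71% by that sampling sd alone.

## Allelic imbalance

Counts from all heterozygous variants overlapping a region are summed per
assay (half-open intervals; duplicate (assay, variant) rows are an error to
prevent double counting). The null ALT probability p₀ is the input assay's
ALT share in the same region — this absorbs reference/mapping bias into the
null — falling back to 0.5 with a flag when the input has no reads. Assays
with fewer than 6 total reads are filtered, not tested. The two-sided rule
is the minimum-likelihood convention (sum of probabilities of all outcomes
no more likely than observed; scipy's default), with the tail-doubling rule
available behind a flag. BH runs across the tested assays within each
region. The log₂ fold change of assay ALT% over input ALT% receives one
read on both alleles whenever an allele count is zero, keeping it finite.
The exact test is conservative at these depths: the measured null
P(p ≤ 0.05) over depths 6–200 is ≈ 0.04.

The upstream stage of the real analysis — alignment to personalized diploid
genomes and per-variant re-genotyping — is replaced by the count-table
interface; reconstructing aligner behavior is out of scope.

## Motif Z-scores

PWMs are consumed as 4×L natural-log odds (rows A,C,G,T). The converter
from count matrices uses a uniform background and pseudocount 1 split by
background, and is explicit because motif databases differ in convention.
Scanning scores every offset on both strands; windows containing non-ACGT
bases are skipped rather than scored, to avoid fabricating sites. Per-TF
calibration collects the maximum score per background region and stores
mean and sd (n−1); degenerate (sd = 0) calibrations are kept but flagged,
with Z defined only at the mean. Z is invariant under any affine transform
applied jointly to a PWM and its calibration. Both alleles are windowed
identically — equal flanks centered on the variant (default 757 bp total),
so the ALT window is shorter in genomic span by the indel length. The
top-site convention (max over windows, then standardize) is used for every
Z in this package. TF ranking by ΔZ = Z_ALT − Z_REF breaks ties
lexicographically and can filter on a supplied TF-expression table
(default mean FPKM ≥ 0.5).

## Conformation statistics

Chromatin-tracing ensembles store cells × segment-pair distances in nm with
missing values; medians are computed per pair ignoring missing entries, and
pairs observed in fewer than 20 cells (configurable) are masked — the
source protocols filter cells but state no per-pair rule, so the floor is
this package's choice. Contact fraction uses a strict `< threshold`
(default 150 nm) with missing-aware denominators. The ALT−REF comparison
subtracts median matrices, reports the median difference, and tests the
sign balance of nonzero differences with a two-sided exact binomial at
success probability ½; all-zero differences give p = 1 by convention.
Replicate ensembles may be concatenated cell-wise before statistics or
analyzed per replicate. A convenience transform computes pairwise Euclidean
distances from per-segment 3D coordinates; image processing is out of
scope.

Capture-C profiles are viewpoint-excluded (fragment midpoint within ±1 kb
of the viewpoint, configurable), scaled so the TAD total is 1, and binned
by fragment midpoint into fixed windows tiled from the TAD start (half-open
bins; a midpoint on a boundary goes right). Fold changes compare mean
normalized counts per bin between genotypes with an epsilon equal to the
smallest positive normalized unit, so empty bins stay finite; a fold change
is therefore only meaningful on bins whose signal is well above that floor.
The fraction of TAD signal in the viewpoint-containing bin is reported per
replicate. Formal differential testing (negative-binomial modeling of
replicate counts) is deliberately not re-implemented; the package supplies
the normalized, binned inputs plus descriptive fold changes.

## Synthetic-data generators

All generators draw from named sub-streams spawned deterministically from
one seed, so identical configurations are byte-reproducible and enlarging
one component does not perturb the others.

* **Peak cohorts.** Planted modules are equicorrelated by a shared latent
  factor with loading a = √(r/(1−r)) against unit noise, giving pairwise
  correlation a²/(a²+1) = r analytically (r = 1 degenerates to identical
  columns; r = 0 to independence). Genotype dosages are Hardy–Weinberg
  draws at the configured MAF — default 0.27, the population frequency of
  the regulatory indel this models — and contribute β per dosage unit to
  the latent factor. Output carries the `residual` layer: mean-zero
  continuous signal to be inverse-normal transformed before calling. Not
  emulated: count noise, peak-width variation, LD between variants,
  covariate structure.
* **Allelic reads.** Per (assay, region): depth ~ Poisson, ALT reads ~
  Binomial(depth, true ALT fraction); the input draws from its own
  fraction, which is where reference bias lives. No read-level or
  mapping-bias simulation.
* **Indel sequences.** The REF allele carries the planted consensus split
  by a 5-bp spacer; deleting the spacer (ALT) fuses a contiguous motif
  match at the junction. Construction verifies the exact consensus occurs
  once in ALT and never in REF on either strand, retrying with fresh draws
  (bounded). PWMs are sharp (≈94% consensus base per column with jitter);
  decoys are random motifs of the same length. Background regions are
  i.i.d. uniform sequences — real accessible regions have composition bias
  the generator does not model, so Z magnitudes on real data will differ.
* **Tracing ensembles.** Mean distance follows a cube-root power law of
  genomic separation (equilibrium-polymer scaling, ~160 nm at one 8-kb
  step), REF cells add Gaussian noise (floored at 0), ALT scales the curve
  by the compaction factor with independent noise, and entries go missing
  as i.i.d. Bernoulli. Defaults mirror the benchmark geometry: 25 segments
  × 8 kb, 2,000 cells per genotype. Spatial correlation between pairs
  within a cell is not modeled.
* **Capture-C.** Expected fragment counts decay exponentially with distance
  from the viewpoint (uniform in the infinite-decay limit); replicates are
  independent Poisson draws; ALT multiplies chosen 5-kb bins by a planted
  boost. In benchmarks the boost sits ~25 kb from the viewpoint, where
  signal is far above the epsilon floor; a boost planted on a distant,
  near-empty bin is damped by the floor, by design.

Because the generators plant exactly the statistical structure the methods
assume (equicorrelation, binomial sampling, global scaling), passing
benchmarks demonstrates correctness and calibration of the machinery — not
robustness to the messiness of real data (batch effects, mapping bias,
composition bias, structured missingness).

## Benchmark problem sizes

The test suite runs the module-recovery benchmark at n = 300 samples, four
10-peak modules (ρ = 0.6) plus 20 noise peaks over 20 cohorts; QTL recovery
over 100 effect and 400 null cohorts; imbalance calibration over 10,000
null regions (balanced input, so p₀ is exact and the bound tests the exact
test itself, not p₀ estimation noise); motif nomination over 50 seeds with
20 decoys and 250 background regions per seed; compaction recovery over 20
seeds at 2,000 cells per genotype. `scripts/acceptance.py` recomputes the
same quantities at moderately smaller replicate counts (10 cohorts, 50/500
QTL simulations, 4,000 regions, 20 motif seeds, 5 tracing seeds), chosen as
comfortable single-CPU sizes with Monte-Carlo error small relative to the
margins checked. Its child seeds derive from the command-line seed via
`SeedSequence` spawning (drawing integer seeds out of a generator stream
measurably correlated replicate simulations and was replaced).

## Known limitations

* Trans (inter-chromosomal) modules are out of scope; so are directed
  CRE-hierarchy models.
* The hierarchical caller's cut rule is an approximation, not a clone of
  any published clustering tool.
* The background-calibration quality bounds Z accuracy: with n background
  regions, the Z sd is estimated with relative error ~1/√(2n).
* Capture-C fold changes are descriptive; no replicate-variance model.
* The consensus merger is span-based; two unrelated modules whose spans
  interleave on the same chromosome will merge.
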