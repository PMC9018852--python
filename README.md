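# vcmkit

Statistical toolkit for dissecting **variable chromatin modules (VCMs)** —
sets of cis-regulatory elements (enhancers/promoters) whose chromatin marks,
TF binding and accessibility covary across individuals — and for tracing how
a single regulatory variant switches such a module on: module calling from
peak-correlation structure, module-activity QTL scanning, allele-specific
TF-binding tests on phased haplotypes, PWM top-site Z-score comparisons
between alleles, and chromosome-conformation summary statistics for
chromatin-tracing and Capture-C readouts.

It is aimed at regulatory-genomics analysts working with population-scale
ChIP-seq/ATAC-seq peak matrices and locus-scale conformation data. Every
pipeline input can also be simulated with planted ground truth
(`vcmkit.simulate`), so the full analysis chain is testable without any
controlled-access data.

## What it computes

**Module calling.** From a normalized peaks × samples matrix, Pearson
correlations *r* are computed for all same-chromosome peak pairs within a
window (default 2 Mb), with two-sided p-values from the exact *t*
distribution of *r* (df = n−2) and Benjamini–Hochberg q-values per
chromosome. Modules are connected components of the significant-pair graph
under either a pair-FDR cut (default 0.1%) or a fixed threshold (default
r > 0.5); an average-linkage hierarchical variant (distance 1−r, cut on
mean within-node |r|) and span-overlap consensus merging are also provided.

**Activity QTLs.** A module's activity (aVCM) is the first principal
component of its standardized member peaks, sign-oriented to correlate
positively with the mean member signal and re-standardized. QTL scans fit
per variant–target OLS of the target on additive dosage (0/1/2),
`target = α + β·dosage + ε`, reporting β, its standard error, two-sided
t-test p and BH q over an explicitly declared test universe. A three-way
screen intersects module-activity, expression and TF-binding QTLs at
FDR ≤ 10% for modules with ≥ 2 member elements.

**Allelic imbalance.** Per-variant ALT/REF read counts are summed over a
region's heterozygous variants; each assay is tested with a two-sided exact
binomial test of the ALT count at the *input's* ALT fraction p₀ (correcting
reference bias), filtering assays with < 6 total reads, BH-adjusting within
region, and reporting log₂(assay ALT% / input ALT%) with a +1/+1
pseudocount when an allele has zero reads.

**Motif Z-scores.** PWMs (4×L log-odds) are scanned over both strands; per
TF, the maximum ("top-site") score of a sequence is standardized by the
mean/sd of top-site scores over thousands of background accessible regions,
Z = (s − μ_TF)/σ_TF, making scores comparable across TFs. Alleles of an
indel are scanned with equal flanks (default 757 bp total) and TFs ranked
by ΔZ = Z_ALT − Z_REF, optionally filtered by TF expression.

**Conformation.** Chromatin-tracing ensembles (cells × segment-pair
distances, nm) are summarized as population-median distance matrices and
contact fractions (< 150 nm); ALT−REF comparisons use a two-sided exact
binomial sign test on the nonzero per-pair differences. Capture-C fragment
counts are viewpoint-excluded (±1 kb), normalized to the TAD total, binned
(5 kb) and compared as per-bin log₂ fold changes.

## Worked example

```python
import vcmkit as vk

config = vk.SimulationConfig(
    seed=1, n_samples=300, n_peaks=40,
    modules=[vk.ModuleSpec(size=10, within_module_correlation=0.6),
             vk.ModuleSpec(size=10, within_module_correlation=0.6)],
)
matrix, genotype, truth = vk.simulate_peak_cohort(config)
matrix = vk.rank_inverse_normal(matrix)
pairs = vk.pairwise_correlations(matrix, window_bp=2_000_000)
for mod in vk.call_vcms_rthreshold(pairs, matrix.peaks, r_min=0.5):
    print(mod.module_id, mod.size, mod.span, round(mod.mean_r, 2))
```

prints

```
r-threshold_0 10 (1000000, 1090200) 0.57
r-threshold_1 10 (1110000, 1200200) 0.57
```

— the two planted 10-peak modules, recovered exactly; the 20 independent
noise peaks stay unassigned because no noise pair reaches r ≥ 0.5 at
n = 300. The observed mean within-module r (0.57) fluctuates around the
planted 0.6. Continuing with the QTL stage (`examples/02_activity_qtl.py`,
planted β = 0.5 at MAF 0.27) prints

```
module r-threshold_0: 10 peaks, PC1 explains 67% of member variance
QTL: beta = 0.607 +- 0.089, p = 6.11e-11, n = 300
```

— the dosage effect on the standardized activity score, whose single-cohort
estimate scatters around the planted value with sd ≈ 0.09.

The `examples/` directory holds one short script per capability (module
calling, activity QTL, allelic imbalance, motif ΔZ ranking, chromatin
tracing, Capture-C), each printing the numbers it computes and what they
mean. A thin CLI mirrors the library
(`vcmkit simulate|preprocess|vcm-call|avcm|qtl|ase|density|motif-z|orca|capturec`);
all outputs are byte-deterministic for a fixed seed.

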