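"""Score module activity (aVCM) and scan for an activity QTL.

A genotype effect of 0.5 per ALT dosage unit is planted on the module's
shared latent factor (variant at minor allele frequency 0.27, the
frequency of the indel this models). The module activity score is the
standardized PC1 of the member peaks; the QTL scan regresses it on dosage.
"""

import pandas as pd

import vcmkit as vk

config = vk.SimulationConfig(
    seed=2,
    n_samples=300,
    n_peaks=30,
    modules=[vk.ModuleSpec(size=10, within_module_correlation=0.6)],
    variant_maf=0.27,
    genotype_effect_beta=0.5,
)
matrix, genotype, truth = vk.simulate_peak_cohort(config)
matrix = vk.rank_inverse_normal(matrix)

pairs = vk.pairwise_correlations(matrix)
module = vk.call_vcms_rthreshold(pairs, matrix.peaks, r_min=0.5)[0]
score = vk.compute_avcm(matrix, module)
print(
    f"module {module.module_id}: {module.size} peaks, "
    f"PC1 explains {score.variance_explained:.0%} of member variance"
)

targets = pd.DataFrame({"aVCM": score.score}, index=matrix.sample_ids)
result = vk.qtl_scan(targets, [genotype]).iloc[0]
print(
    f"QTL: beta = {result['beta']:.3f} +- {result['se']:.3f}, "
    f"p = {result['p']:.2e}, n = {result['n']}"
)

# beta estimates the dosage effect on the unit-variance activity score.
# Its sampling sd at n = 300 and MAF 0.27 is ~0.09, so single-cohort
# estimates scatter around the (slightly standardization-shrunk) planted
# 0.5; the association itself is overwhelmingly significant.
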