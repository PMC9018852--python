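"""Detect a subtle global compaction from chromatin-tracing distances.

Simulates single-cell pairwise distances (nm) for 25 x 8-kb segments in
2,000 REF and 2,000 ALT cells, with ALT distances globally scaled by 0.9.
Population-median matrices, the ALT - REF sign-balance binomial test and
the contact fraction below 150 nm summarize the comparison.
"""

import numpy as np

import vcmkit as vk

config = vk.SimulationConfig(
    seed=5, orca=vk.OrcaSpec(n_cells=2000, compaction_factor=0.9)
)
ref, alt, truth = vk.simulate_orca_ensembles(config)
print(f"{ref.n_segments} segments -> {len(ref.pairs)} pairs per cell")

med_ref = vk.median_distance_matrix(ref, min_obs=20)
med_alt = vk.median_distance_matrix(alt, min_obs=20)
test = vk.diff_matrix_test(med_alt, med_ref)
print(
    f"median(ALT - REF) = {test['median_diff']:.2f} nm; "
    f"{test['n_closer']} pairs closer vs {test['n_further']} further; "
    f"binomial p = {test['p']:.2e}"
)

iu = np.triu_indices(ref.n_segments, k=1)
factor = np.nanmedian(med_alt.matrix[iu] / med_ref.matrix[iu])
print(f"recovered compaction factor: {factor:.3f} (planted {truth.compaction_factor})")

cf_ref = vk.contact_fraction(ref, threshold_nm=150.0)
cf_alt = vk.contact_fraction(alt, threshold_nm=150.0)
print(
    f"mean contact fraction (<150 nm): REF {np.nanmean(cf_ref.matrix):.3f}, "
    f"ALT {np.nanmean(cf_alt.matrix):.3f}"
)

# A 0.9 scaling shifts nearly every pair closer in ALT, so the sign test is
# astronomically significant even though each individual change is small --
# the signature of subtle, locus-wide compaction.
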