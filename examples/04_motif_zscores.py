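"""Nominate the TF whose binding site a 5-bp deletion creates.

Builds a REF/ALT sequence pair in which deleting 5 bp fuses the two halves
of a planted motif into a contiguous site, scans one planted PWM plus 20
decoys over both alleles, calibrates per-TF top-site Z-scores on random
background regions, and ranks TFs by the ALT - REF Z difference.
"""

import vcmkit as vk

config = vk.SimulationConfig(
    seed=4, motif=vk.MotifSpec(n_decoys=20, n_background=500)
)
ref, alt, pwms, backgrounds, truth = vk.simulate_indel_sequences(config)
print(
    f"REF {len(ref)} bp, ALT {len(alt)} bp "
    f"(5-bp deletion); planted TF: {truth.planted_motif_tf}"
)

calibration = vk.calibrate_background(pwms, backgrounds)
results = vk.allele_max_zscores(pwms, calibration, ref, alt)
ranked = vk.rank_allele_deltas(results)

print("\ntop 5 TFs by delta Z (ALT - REF):")
print(ranked.head(5).to_string(index=False, float_format="%.2f"))

# The planted TF should top the ranking with a large positive delta Z (its
# site exists only on the ALT allele); decoys sit near delta Z = 0 because
# the two alleles are identical outside the 5-bp junction.
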