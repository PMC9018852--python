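"""Normalize Capture-C profiles and recover a planted contact gain.

Simulates viewpoint-anchored fragment counts (exponential distance decay,
3 replicates per genotype) with a 2x contact boost planted on one 5-kb bin
of the ALT allele. Profiles are viewpoint-excluded (+-1 kb), normalized to
the TAD total, binned at 5 kb, and compared as per-bin log2 fold changes.
"""

import numpy as np

import vcmkit as vk

BOOST_BIN = 95  # ~25 kb from the viewpoint

config = vk.SimulationConfig(
    seed=6,
    capturec=vk.CaptureCSpec(alt_boost={BOOST_BIN: 2.0}, total_depth=1e5),
)
profiles, truth = vk.simulate_capturec(config)

binned = {
    genotype: [
        vk.capturec_bin_normalize(p, bin_bp=5000, viewpoint_exclusion_bp=1000)
        for p in plist
    ]
    for genotype, plist in profiles.items()
}
for p in binned["REF"] + binned["ALT"]:
    assert abs(p.fragments["count"].sum() - 1.0) < 1e-12  # mass conservation

fc = vk.capturec_fold_changes(binned["ALT"], binned["REF"])
bins = fc["bins"]
# judge fold changes only on bins with decent coverage: far, near-empty
# bins fluctuate at the epsilon floor and carry no usable signal
mean_ref = np.mean([p.fragments["count"].to_numpy() for p in binned["REF"]], axis=0)
covered = mean_ref > mean_ref.mean()
top = int(np.flatnonzero(covered)[np.argmax(np.abs(fc["log2fc"][covered]))])
print(
    f"largest |log2 FC| among covered bins: bin {top} "
    f"({bins['start'][top]}-{bins['end'][top]}): {fc['log2fc'][top]:+.2f}"
)
print(f"planted boost was 2x on bin {BOOST_BIN} (log2 = 1)")
print(
    "viewpoint-bin fraction of TAD signal per replicate:",
    {k: round(v, 3) for k, v in fc["viewpoint_bin_fraction"].items()},
)

# The boosted bin should carry the largest fold change, close to log2 = 1
# (slightly shrunk because ALT profiles are re-normalized to the TAD total).
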