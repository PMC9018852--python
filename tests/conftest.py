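import numpy as np
import pandas as pd
import pytest

import vcmkit as vk


def make_matrix(values, layer="int-transformed", chrom="chr17", spacing=1000):
    """Wrap a peaks x samples array in a PeakSignalMatrix with simple metadata."""
    values = np.asarray(values, dtype=float)
    n_peaks, n_samples = values.shape
    peaks = pd.DataFrame(
        {
            "chrom": chrom,
            "start": 1_000_000 + spacing * np.arange(n_peaks),
            "end": 1_000_000 + spacing * np.arange(n_peaks) + 200,
            "peak_id": [f"p{i}" for i in range(n_peaks)],
            "assay": "H3K27ac",
        }
    )
    return vk.PeakSignalMatrix(
        peaks=peaks,
        sample_ids=[f"S{i}" for i in range(n_samples)],
        values=values,
        layer=layer,
    )


@pytest.fixture
def cohort():
    """A planted-module cohort with a genotype effect, n=300."""
    config = vk.SimulationConfig(
        seed=11,
        n_samples=300,
        n_peaks=30,
        modules=[vk.ModuleSpec(size=10, within_module_correlation=0.6)],
        genotype_effect_beta=0.5,
    )
    return vk.simulate_peak_cohort(config)
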