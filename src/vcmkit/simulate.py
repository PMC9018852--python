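"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: peak cohorts with
planted correlated modules and an additive genotype effect, binomial
haplotype read counts with a controllable true ALT fraction and input
reference bias, REF/ALT sequence pairs whose 5-bp deletion creates a
planted motif, chromatin-tracing distance ensembles related by a global
compaction factor, and viewpoint-anchored fragment counts with distance
decay. All randomness flows from a single seed through deterministically
spawned sub-streams, so enlarging one part of a simulation does not perturb
the others.

Planted modules are equicorrelated by construction: members share a latent
factor with loading a = sqrt(r / (1 - r)) against unit noise, which gives
pairwise correlation a^2 / (a^2 + 1) = r analytically. The genotype acts
additively on the latent factor, mirroring how a regulatory variant shifts
the coordinated activity of a chromatin module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import (
    CaptureCProfile,
    DistanceEnsemble,
    GenotypeVector,
    PeakSignalMatrix,
    PositionWeightModel,
)
from .allelic import INPUT_ASSAY
from .motif import counts_to_log_odds, reverse_complement

__all__ = [
    "ModuleSpec",
    "AseSpec",
    "MotifSpec",
    "OrcaSpec",
    "CaptureCSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_peak_cohort",
    "simulate_allelic_reads",
    "simulate_indel_sequences",
    "simulate_orca_ensembles",
    "simulate_capturec",
]


@dataclass
class ModuleSpec:
    """One planted module: member count, target correlation, location."""

    size: int
    within_module_correlation: float
    chromosome: str = "chr17"
    span_bp: int = 100_000

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("module size must be >= 2")
        if not 0.0 <= self.within_module_correlation <= 1.0:
            raise ValueError("within_module_correlation must lie in [0, 1]")
        if self.span_bp <= 0:
            raise ValueError("span_bp must be positive")


@dataclass
class AseSpec:
    """Allele-specific read-count simulation parameters."""

    n_assays: int = 10
    n_regions: int = 1
    reads_per_region_mean: float = 50.0
    true_alt_fractions: tuple[float, ...] | None = None  # per assay; default 0.5
    input_alt_fraction: float = 0.5
    input_reads_mean: float = 100.0

    def __post_init__(self) -> None:
        if self.true_alt_fractions is None:
            self.true_alt_fractions = tuple([0.5] * self.n_assays)
        if len(self.true_alt_fractions) != self.n_assays:
            raise ValueError("need one true ALT fraction per assay")
        for f in (*self.true_alt_fractions, self.input_alt_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("allele fractions must lie in [0, 1]")


@dataclass
class MotifSpec:
    """Planted-indel motif simulation parameters."""

    planted_pwm_id: str = "TF_PLANTED"
    indel_length: int = 5
    n_decoys: int = 20
    motif_length: int = 10
    sequence_length: int = 757
    n_background: int = 5000
    background_length: int = 700

    def __post_init__(self) -> None:
        if self.motif_length > self.sequence_length:
            raise ValueError("planted PWM longer than the sequence context")
        if self.indel_length < 1:
            raise ValueError("indel_length must be >= 1")


@dataclass
class OrcaSpec:
    """Chromatin-tracing ensemble simulation parameters."""

    n_segments: int = 25
    segment_bp: int = 8000
    n_cells: int = 2000
    compaction_factor: float = 0.9
    noise_sd_nm: float = 50.0
    missing_rate: float = 0.1
    chromosome: str = "chr17"
    start: int = 63_486_119

    def __post_init__(self) -> None:
        if self.n_segments < 2:
            raise ValueError("need at least 2 segments")
        if self.compaction_factor <= 0:
            raise ValueError("compaction_factor must be positive")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")


@dataclass
class CaptureCSpec:
    """Viewpoint fragment-count simulation parameters."""

    n_fragments: int = 200
    decay_bp: float = 50_000.0
    viewpoint: int = 500_000
    tad: tuple[int, int] = (0, 1_000_000)
    total_depth: float = 100_000.0
    n_replicates: int = 3
    alt_boost: dict[int, float] = field(default_factory=dict)  # bin idx -> factor
    boost_bin_bp: int = 5000
    chromosome: str = "chr17"

    def __post_init__(self) -> None:
        if not self.tad[0] <= self.viewpoint < self.tad[1]:
            raise ValueError("viewpoint must lie inside the TAD")


@dataclass
class SimulationConfig:
    """Full simulation configuration; the seed fully determines all outputs."""

    seed: int
    n_samples: int = 300
    n_peaks: int = 60
    modules: list[ModuleSpec] = field(default_factory=list)
    variant_maf: float = 0.27
    genotype_effect_beta: float = 0.0
    ase: AseSpec = field(default_factory=AseSpec)
    motif: MotifSpec = field(default_factory=MotifSpec)
    orca: OrcaSpec = field(default_factory=OrcaSpec)
    capturec: CaptureCSpec = field(default_factory=CaptureCSpec)

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_peaks < 1:
            raise ValueError("counts must be positive")
        if not 0.0 < self.variant_maf <= 0.5:
            raise ValueError("variant_maf must lie in (0, 0.5]")
        if sum(m.size for m in self.modules) > self.n_peaks:
            raise ValueError("module sizes sum exceeds n_peaks")


@dataclass
class SyntheticTruth:
    """Planted parameters, recorded exactly as used."""

    module_labels: dict[str, str] = field(default_factory=dict)
    true_beta: float = 0.0
    true_alt_fractions: dict[str, float] = field(default_factory=dict)
    input_alt_fraction: float | None = None
    planted_motif_tf: str | None = None
    planted_site: dict | None = None
    compaction_factor: float | None = None
    capturec_boosts: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def _streams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    """Named child RNG streams spawned deterministically from one seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


# ---------------------------------------------------------------------------
# peak cohort


def simulate_peak_cohort(
    config: SimulationConfig,
) -> tuple[PeakSignalMatrix, GenotypeVector, SyntheticTruth]:
    """Peak matrix with planted equicorrelated modules and a genotype effect.

    Module members share a latent factor (loading a = sqrt(r/(1-r))) to
    which the genotype dosage contributes ``genotype_effect_beta`` per
    dosage unit; non-member peaks are independent noise. Genotype dosages
    follow Hardy-Weinberg at ``variant_maf``. The returned matrix carries
    the ``residual`` layer (mean-zero continuous signal): apply the rank
    inverse-normal transform before module calling.
    """
    n = config.n_samples
    rngs = _streams(config.seed, ["genotype", "factors", "peaks"])

    p = config.variant_maf
    dosage = rngs["genotype"].choice(
        [0.0, 1.0, 2.0], size=n, p=[(1 - p) ** 2, 2 * p * (1 - p), p**2]
    )

    sample_ids = [f"S{i:04d}" for i in range(n)]
    values = np.empty((config.n_peaks, n))
    meta_rows = []
    labels: dict[str, str] = {}

    peak_streams = np.random.SeedSequence(config.seed).spawn(3)[2].spawn(
        config.n_peaks
    )
    peak_rngs = [np.random.default_rng(ss) for ss in peak_streams]

    peak = 0
    cursor: dict[str, int] = {}
    peak_width = 200
    for m_idx, mod in enumerate(config.modules):
        r = mod.within_module_correlation
        latent = rngs["factors"].standard_normal(n) + (
            config.genotype_effect_beta * dosage
        )
        start0 = cursor.get(mod.chromosome, 1_000_000)
        spacing = max(mod.span_bp // mod.size, peak_width + 1)
        for k in range(mod.size):
            pid = f"peak{peak:04d}"
            if r >= 1.0:
                values[peak] = latent  # degenerate: identical columns
            else:
                a = np.sqrt(r / (1.0 - r))
                values[peak] = a * latent + peak_rngs[peak].standard_normal(n)
            s = start0 + k * spacing
            meta_rows.append(
                {
                    "chrom": mod.chromosome,
                    "start": s,
                    "end": s + peak_width,
                    "peak_id": pid,
                    "assay": "H3K27ac",
                }
            )
            labels[pid] = f"module{m_idx}"
            peak += 1
        cursor[mod.chromosome] = start0 + mod.span_bp + 10_000

    noise_chrom = config.modules[0].chromosome if config.modules else "chr17"
    start0 = cursor.get(noise_chrom, 1_000_000)
    for k in range(config.n_peaks - peak):
        pid = f"peak{peak:04d}"
        values[peak] = peak_rngs[peak].standard_normal(n)
        s = start0 + k * 1000
        meta_rows.append(
            {
                "chrom": noise_chrom,
                "start": s,
                "end": s + peak_width,
                "peak_id": pid,
                "assay": "H3K27ac",
            }
        )
        labels[pid] = "noise"
        peak += 1

    matrix = PeakSignalMatrix(
        peaks=pd.DataFrame(meta_rows),
        sample_ids=sample_ids,
        values=values,
        layer="residual",
    )
    first = config.modules[0] if config.modules else None
    genotype = GenotypeVector(
        variant_id="var_planted",
        chrom=first.chromosome if first else noise_chrom,
        position=1_000_001,
        ref_allele="ATCAAA",
        alt_allele="A",
        sample_ids=sample_ids,
        dosage=dosage,
    )
    truth = SyntheticTruth(
        module_labels=labels, true_beta=config.genotype_effect_beta
    )
    return matrix, genotype, truth


# ---------------------------------------------------------------------------
# allelic read counts


def simulate_allelic_reads(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Binomial ALT/REF read counts per assay and region, plus a matched input.

    ALT reads per (assay, region) are Binomial(n, true_alt_fraction) with
    n ~ Poisson(reads_per_region_mean); the input assay draws from its own
    fraction (reference bias lives there).
    """
    spec = config.ase
    rng = _streams(config.seed, ["ase"])["ase"]
    rows = []
    for region in range(spec.n_regions):
        region_id = f"region{region:05d}"
        for a, frac in enumerate(spec.true_alt_fractions):
            n = int(rng.poisson(spec.reads_per_region_mean))
            alt = int(rng.binomial(n, frac)) if n else 0
            rows.append(
                {
                    "assay_id": f"assay{a:03d}",
                    "region_id": region_id,
                    "alt_reads": alt,
                    "ref_reads": n - alt,
                }
            )
        n_inp = int(rng.poisson(spec.input_reads_mean))
        alt_inp = int(rng.binomial(n_inp, spec.input_alt_fraction)) if n_inp else 0
        rows.append(
            {
                "assay_id": INPUT_ASSAY,
                "region_id": region_id,
                "alt_reads": alt_inp,
                "ref_reads": n_inp - alt_inp,
            }
        )
    truth = SyntheticTruth(
        true_alt_fractions={
            f"assay{a:03d}": f for a, f in enumerate(spec.true_alt_fractions)
        },
        input_alt_fraction=spec.input_alt_fraction,
    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# planted-indel sequences and PWMs


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _sharp_pwm(
    tf_id: str, consensus: str, rng: np.random.Generator
) -> PositionWeightModel:
    """Informative log-odds PWM whose consensus is the given string."""
    L = len(consensus)
    counts = np.full((4, L), 2.0)
    for j, base in enumerate(consensus):
        counts["ACGT".index(base), j] = 94.0
    # small jitter so decoys are not numerically identical
    counts += rng.uniform(0, 1.0, size=(4, L))
    for j, base in enumerate(consensus):  # keep the intended consensus
        counts["ACGT".index(base), j] += 2.0
    return counts_to_log_odds(tf_id, counts, source="synthetic")


def _contains(seq: str, motif: str) -> bool:
    return motif in seq or motif in reverse_complement(seq)


def simulate_indel_sequences(
    config: SimulationConfig, max_attempts: int = 50
) -> tuple[str, str, list[PositionWeightModel], list[str], SyntheticTruth]:
    """REF/ALT pair differing by a deletion that creates a planted motif site.

    The REF sequence carries the planted consensus split by an inserted
    ``indel_length`` spacer; deleting the spacer (the ALT allele) restores
    a contiguous match at the junction. The exact planted consensus occurs
    nowhere else on either strand of either allele; decoy PWMs are random
    motifs with no planted site. Construction retries with fresh draws and
    fails after ``max_attempts``.
    """
    spec = config.motif
    rng = _streams(config.seed, ["motif"])["motif"]
    L = spec.motif_length

    for _ in range(max_attempts):
        consensus = _random_sequence(rng, L)
        split = L // 2
        spacer = _random_sequence(rng, spec.indel_length)
        flank_total = spec.sequence_length - L - spec.indel_length
        left = _random_sequence(rng, flank_total // 2)
        right = _random_sequence(rng, flank_total - flank_total // 2)
        ref = left + consensus[:split] + spacer + consensus[split:] + right
        alt = left + consensus + right
        # the motif must appear once in ALT (the junction) and never in REF
        if _contains(ref, consensus):
            continue
        if alt.count(consensus) + reverse_complement(alt).count(consensus) != 1:
            continue
        break
    else:
        raise RuntimeError(
            f"could not embed the planted motif in {max_attempts} attempts"
        )

    planted = _sharp_pwm(spec.planted_pwm_id, consensus, rng)
    decoys = []
    for d in range(spec.n_decoys):
        while True:
            dc = _random_sequence(rng, L)
            if dc != consensus:
                break
        decoys.append(_sharp_pwm(f"TF_DECOY{d:03d}", dc, rng))

    backgrounds = [
        _random_sequence(rng, spec.background_length)
        for _ in range(spec.n_background)
    ]
    truth = SyntheticTruth(
        planted_motif_tf=spec.planted_pwm_id,
        planted_site={
            "consensus": consensus,
            "alt_position": len(left),
            "indel_position": len(left) + split,
            "indel_length": spec.indel_length,
        },
    )
    return ref, alt, [planted] + decoys, backgrounds, truth


# ---------------------------------------------------------------------------
# chromatin-tracing ensembles


def _segment_table(spec: OrcaSpec) -> pd.DataFrame:
    starts = spec.start + spec.segment_bp * np.arange(spec.n_segments)
    return pd.DataFrame(
        {
            "index": np.arange(spec.n_segments),
            "chrom": spec.chromosome,
            "start": starts,
            "end": starts + spec.segment_bp,
        }
    )


def expected_distance_curve(separations_bp: np.ndarray) -> np.ndarray:
    """Monotone distance (nm) vs genomic separation: d = 40 * (sep/8kb)^(1/3).

    The cube-root growth mimics equilibrium-polymer scaling of spatial
    distance with genomic separation at the hundreds-of-nm scale.
    """
    return 40.0 * np.cbrt(separations_bp / 8000.0) * 4.0


def simulate_orca_ensembles(
    config: SimulationConfig,
) -> tuple[DistanceEnsemble, DistanceEnsemble, SyntheticTruth]:
    """REF/ALT distance ensembles related by a global compaction factor.

    REF per-cell pair distances are the monotone distance-vs-separation
    curve plus Gaussian noise (floored at 0); ALT distances use the same
    curve scaled by ``compaction_factor`` plus independent noise. Entries
    are masked missing at ``missing_rate``.
    """
    spec = config.orca
    rngs = _streams(config.seed, ["orca_ref", "orca_alt"])
    segments = _segment_table(spec)
    S = spec.n_segments
    iu, ju = np.triu_indices(S, k=1)
    pairs = list(zip(iu.tolist(), ju.tolist()))
    sep = (ju - iu) * spec.segment_bp
    base = expected_distance_curve(sep.astype(float))

    def draw(rng: np.random.Generator, scale: float, tag: str) -> DistanceEnsemble:
        d = scale * base + rng.normal(0.0, spec.noise_sd_nm, size=(spec.n_cells, base.size))
        d = np.maximum(d, 0.0)
        if spec.missing_rate > 0:
            mask = rng.random(d.shape) < spec.missing_rate
            d[mask] = np.nan
        return DistanceEnsemble(
            genotype=tag, segments=segments, pairs=pairs, distances=d
        )

    ref = draw(rngs["orca_ref"], 1.0, "REF")
    alt = draw(rngs["orca_alt"], spec.compaction_factor, "ALT")
    truth = SyntheticTruth(compaction_factor=spec.compaction_factor)
    return ref, alt, truth


# ---------------------------------------------------------------------------
# Capture-C fragment counts


def simulate_capturec(
    config: SimulationConfig,
) -> tuple[dict[str, list[CaptureCProfile]], SyntheticTruth]:
    """Fragment counts per genotype/replicate with distance decay.

    Expected counts decay exponentially with distance of the fragment
    midpoint from the viewpoint (decay constant ``decay_bp``; uniform in
    the limit decay_bp -> infinity); replicate counts are independent
    Poisson draws. ALT profiles receive the configured multiplicative
    boosts on chosen ``boost_bin_bp`` bins.
    """
    spec = config.capturec
    rng = _streams(config.seed, ["capturec"])["capturec"]
    tad_lo, tad_hi = spec.tad
    width = (tad_hi - tad_lo) / spec.n_fragments
    starts = tad_lo + width * np.arange(spec.n_fragments)
    ends = starts + width
    mids = (starts + ends) / 2.0

    if np.isfinite(spec.decay_bp) and spec.decay_bp > 0:
        expected = np.exp(-np.abs(mids - spec.viewpoint) / spec.decay_bp)
    else:
        expected = np.ones_like(mids)
    expected = expected / expected.sum() * spec.total_depth

    bin_of_fragment = ((mids - tad_lo) // spec.boost_bin_bp).astype(int)
    boost = np.ones(spec.n_fragments)
    for b, factor in spec.alt_boost.items():
        boost[bin_of_fragment == b] *= factor

    profiles: dict[str, list[CaptureCProfile]] = {"REF": [], "ALT": []}
    for genotype, mult in (("REF", np.ones_like(boost)), ("ALT", boost)):
        for rep in range(spec.n_replicates):
            counts = rng.poisson(expected * mult)
            frags = pd.DataFrame(
                {
                    "chrom": spec.chromosome,
                    "start": starts.astype(int),
                    "end": ends.astype(int),
                    "count": counts,
                }
            )
            profiles[genotype].append(
                CaptureCProfile(
                    replicate_id=f"{genotype}_rep{rep}",
                    genotype=genotype,
                    fragments=frags,
                    viewpoint=spec.viewpoint,
                    tad=spec.tad,
                )
            )
    truth = SyntheticTruth(
        capturec_boosts={str(k): v for k, v in spec.alt_boost.items()}
    )
    return profiles, truth
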