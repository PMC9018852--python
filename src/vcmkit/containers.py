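"""Shared in-memory containers for the pipeline.

Tabular results (pair correlations, QTL scans, imbalance tests) are plain
pandas DataFrames with documented column schemas; the dataclasses here hold
the structured objects that carry genomic metadata alongside numeric arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PeakSignalMatrix",
    "CovariateTable",
    "GenotypeVector",
    "ChromatinModule",
    "ActivityScore",
    "PositionWeightModel",
    "BackgroundCalibration",
    "AlleleScanResult",
    "DistanceEnsemble",
    "MedianDistanceMatrix",
    "CaptureCProfile",
]

#: Normalization layers, in mandatory pipeline order.
LAYERS = ("raw", "size-normalized", "residual", "int-transformed")


@dataclass
class PeakSignalMatrix:
    """Peaks x samples signal matrix with genomic peak metadata.

    ``peaks`` is a DataFrame with columns ``chrom``, ``start``, ``end``
    (0-based half-open), ``peak_id`` and ``assay``; ``values`` is a
    peaks x samples float matrix aligned row-wise with ``peaks``.
    ``layer`` records the normalization stage reached so far.
    """

    peaks: pd.DataFrame
    sample_ids: list[str]
    values: np.ndarray
    layer: str = "raw"
    genome_build: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        required = {"chrom", "start", "end", "peak_id", "assay"}
        missing = required - set(self.peaks.columns)
        if missing:
            raise ValueError(f"peak metadata missing columns: {sorted(missing)}")
        if self.values.shape != (len(self.peaks), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.peaks)} peaks x {len(self.sample_ids)} samples"
            )
        if self.peaks["peak_id"].duplicated().any():
            raise ValueError("duplicate peak_ids")
        if (self.peaks["start"] >= self.peaks["end"]).any():
            raise ValueError("peak intervals must satisfy start < end")
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.layer == "raw" and np.nanmin(self.values) < 0:
            raise ValueError("raw layer must be non-negative")

    @property
    def peak_ids(self) -> list[str]:
        return self.peaks["peak_id"].tolist()

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def with_values(self, values: np.ndarray, layer: str) -> "PeakSignalMatrix":
        """Return a copy carrying new values and layer tag."""
        return replace(self, values=np.asarray(values, dtype=float), layer=layer)

    def subset_peaks(self, peak_ids: list[str]) -> "PeakSignalMatrix":
        idx = self.peaks.index[self.peaks["peak_id"].isin(peak_ids)]
        pos = [self.peaks.index.get_loc(i) for i in idx]
        return replace(
            self,
            peaks=self.peaks.iloc[pos].reset_index(drop=True),
            values=self.values[pos],
        )

    def to_frame(self) -> pd.DataFrame:
        """Peak metadata and per-sample values as one wide DataFrame."""
        vals = pd.DataFrame(self.values, columns=self.sample_ids)
        return pd.concat([self.peaks.reset_index(drop=True), vals], axis=1)


@dataclass
class CovariateTable:
    """Samples x k covariate matrix, order-aligned with a signal matrix."""

    sample_ids: list[str]
    values: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("covariate rows must match sample_ids")
        if not self.names:
            self.names = [f"cov{i}" for i in range(self.values.shape[1])]


@dataclass
class GenotypeVector:
    """Additive dosage (0/1/2, NaN = missing) for one variant across samples."""

    variant_id: str
    chrom: str
    position: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str
    sample_ids: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if len(self.dosage) != len(self.sample_ids):
            raise ValueError("dosage length must match sample_ids")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")


@dataclass(frozen=True)
class ChromatinModule:
    """A called variable chromatin module (VCM): >=2 co-varying peaks."""

    module_id: str
    member_peaks: frozenset[str]
    chromosome: str
    span: tuple[int, int]
    method: str
    mean_r: float
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.member_peaks) < 2:
            raise ValueError("a module must contain at least 2 peaks")
        if self.span[0] >= self.span[1]:
            raise ValueError("span must satisfy start < end")

    @property
    def size(self) -> int:
        return len(self.member_peaks)


@dataclass
class ActivityScore:
    """Module activity (aVCM): standardized PC1 across member peaks."""

    module_id: str
    sample_ids: list[str]
    score: np.ndarray
    variance_explained: float
    orientation: int

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if not 0.0 <= self.variance_explained <= 1.0 + 1e-12:
            raise ValueError("variance_explained must lie in [0, 1]")
        if self.orientation not in (-1, 1):
            raise ValueError("orientation must be +1 or -1")


@dataclass
class PositionWeightModel:
    """4 x L log-odds matrix, rows in fixed A, C, G, T order."""

    tf_id: str
    matrix: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError("PWM must be a 4 x L matrix (rows A,C,G,T)")
        if self.matrix.shape[1] < 1:
            raise ValueError("PWM must have at least one column")
        if not np.isfinite(self.matrix).all():
            raise ValueError("PWM entries must be finite")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))


@dataclass
class BackgroundCalibration:
    """Per-TF mean/sd of top-site PWM scores over background regions."""

    tf_id: str
    n_regions: int
    mean_top_score: float
    sd_top_score: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.sd_top_score < 0:
            raise ValueError("sd must be non-negative")
        if self.sd_top_score == 0:
            self.degenerate = True


@dataclass
class AlleleScanResult:
    """Max PWM score and calibrated Z per allele, plus their difference."""

    tf_id: str
    max_score_ref: float
    max_score_alt: float
    z_ref: float
    z_alt: float
    best_ref: tuple[int, str]  # (position, strand)
    best_alt: tuple[int, str]

    @property
    def delta_z(self) -> float:
        return self.z_alt - self.z_ref


@dataclass
class DistanceEnsemble:
    """Single-cell pairwise segment distances (nm) for one genotype.

    ``distances`` is cells x n_pairs with NaN for missing measurements;
    ``pairs`` lists the (i, j) segment index of each column, i < j.
    """

    genotype: str
    segments: pd.DataFrame  # columns: index, chrom, start, end
    pairs: list[tuple[int, int]]
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.ndim != 2 or self.distances.shape[1] != len(self.pairs):
            raise ValueError("distances must be cells x n_pairs")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.distances) < 0 if self.distances.size else False:
                raise ValueError("distances must be non-negative")
        for i, j in self.pairs:
            if not 0 <= i < j < len(self.segments):
                raise ValueError("pair indices must satisfy 0 <= i < j < n_segments")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_cells(self) -> int:
        return self.distances.shape[0]

    def valid_counts_per_cell(self) -> np.ndarray:
        return np.sum(~np.isnan(self.distances), axis=1)

    def concatenate(self, other: "DistanceEnsemble") -> "DistanceEnsemble":
        """Merge replicate ensembles cell-wise (same segment grid required)."""
        if self.pairs != other.pairs:
            raise ValueError("ensembles must share the same segment pair grid")
        return DistanceEnsemble(
            genotype=self.genotype,
            segments=self.segments,
            pairs=self.pairs,
            distances=np.vstack([self.distances, other.distances]),
        )


@dataclass
class MedianDistanceMatrix:
    """S x S population-median distances (nm); NaN marks masked pairs."""

    genotype: str
    matrix: np.ndarray
    n_observations: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("matrix must be square")
        if not np.allclose(
            np.nan_to_num(self.matrix), np.nan_to_num(self.matrix.T)
        ):
            raise ValueError("matrix must be symmetric")


@dataclass
class CaptureCProfile:
    """Viewpoint-anchored restriction-fragment counts for one replicate."""

    replicate_id: str
    genotype: str
    fragments: pd.DataFrame  # columns: chrom, start, end, count
    viewpoint: int
    tad: tuple[int, int]
    layer: str = "raw"

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "count"}
        if required - set(self.fragments.columns):
            raise ValueError("fragments need chrom/start/end/count columns")
        if (self.fragments["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.tad[0] <= self.viewpoint < self.tad[1]:
            raise ValueError("viewpoint must lie inside the TAD interval")
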