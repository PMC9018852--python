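"""Peak-matrix normalization chain.

The pipeline order is fixed: optional paired-end doubling, median-of-ratios
library-size normalization, covariate residualization, rank-based inverse
normal transform. Each stage stamps a layer tag and refuses wrong-layer
input, so stages cannot be silently reordered.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .containers import CovariateTable, PeakSignalMatrix

__all__ = [
    "size_factors",
    "normalize_counts",
    "regress_covariates",
    "rank_inverse_normal",
]


def _require_layer(matrix: PeakSignalMatrix, allowed: tuple[str, ...], op: str) -> None:
    if matrix.layer not in allowed:
        raise ValueError(
            f"{op} expects layer in {allowed}, got {matrix.layer!r}; "
            "run the normalization chain in order"
        )


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (one per sample).

    Per sample, the factor is the median across peaks of the ratio of the
    count to the per-peak geometric mean; peaks with any zero count are
    excluded from factor estimation (their geometric mean is zero).
    """
    counts = np.asarray(counts, dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no peak has all-positive counts; size factors are undefined"
        )
    log_counts = np.log(counts[all_positive])
    log_geomean = log_counts.mean(axis=1, keepdims=True)
    return np.exp(np.median(log_counts - log_geomean, axis=0))


def normalize_counts(
    matrix: PeakSignalMatrix, paired_end: bool = False
) -> PeakSignalMatrix:
    """Library-size normalize a raw count matrix.

    Paired-end counts produced by half-fragment counting are doubled before
    factor estimation. Values are divided by per-sample median-of-ratios
    size factors.
    """
    _require_layer(matrix, ("raw",), "normalize_counts")
    counts = matrix.values * 2.0 if paired_end else matrix.values.copy()
    factors = size_factors(counts)
    return matrix.with_values(counts / factors, layer="size-normalized")


def regress_covariates(
    matrix: PeakSignalMatrix, covariates: CovariateTable
) -> PeakSignalMatrix:
    """Replace each peak's signal by OLS residuals on intercept + covariates."""
    _require_layer(matrix, ("size-normalized",), "regress_covariates")
    if covariates.sample_ids != matrix.sample_ids:
        raise ValueError("covariate sample order must match the matrix")
    n = matrix.n_samples
    design = np.column_stack([np.ones(n), covariates.values])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name offending columns for the caller
        bad = []
        for j, name in enumerate(["intercept"] + covariates.names):
            others = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(name)
        raise ValueError(f"rank-deficient covariate matrix; collinear: {bad}")
    # hat residuals for all peaks at once: R = Y - Y X (X'X)^-1 X'
    coef, *_ = np.linalg.lstsq(design, matrix.values.T, rcond=None)
    residuals = matrix.values - (design @ coef).T
    return matrix.with_values(residuals, layer="residual")


def _blom_scores(row: np.ndarray) -> np.ndarray:
    n = row.size
    ranks = stats.rankdata(row, method="average")
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))


def rank_inverse_normal(
    matrix: PeakSignalMatrix, per_sample: bool = False
) -> PeakSignalMatrix:
    """Rank-based inverse normal transform, Blom offset 3/8.

    Values are replaced by normal quantiles of (rank - 3/8)/(n + 1/4), ties
    broken by average rank. Default: per peak across samples (the form a QTL
    regression needs); ``per_sample=True`` transforms each sample's column
    across peaks instead.
    """
    _require_layer(
        matrix, ("residual", "size-normalized"), "rank_inverse_normal"
    )
    values = matrix.values
    axis_rows = values if not per_sample else values.T
    out = np.empty_like(axis_rows, dtype=float)
    for i, row in enumerate(axis_rows):
        if np.ptp(row) == 0:
            raise ValueError(
                "constant row encountered; the inverse normal transform "
                "is undefined"
            )
        out[i] = _blom_scores(row)
    if per_sample:
        out = out.T
    return matrix.with_values(out, layer="int-transformed")
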