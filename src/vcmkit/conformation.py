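"""Chromosome-conformation statistics.

Chromatin-tracing ensembles (per-cell pairwise segment distances in nm)
are summarized as population-median distance matrices and contact-fraction
maps; genotype comparisons subtract REF medians from ALT and test the sign
balance of the nonzero differences with an exact binomial test. Capture-C
fragment counts around a viewpoint are normalized to the TAD total after
viewpoint exclusion, binned into fixed windows, and compared between
genotypes as per-bin log2 fold changes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CaptureCProfile, DistanceEnsemble, MedianDistanceMatrix

__all__ = [
    "median_distance_matrix",
    "contact_fraction",
    "diff_matrix_test",
    "ensemble_concordance",
    "capturec_bin_normalize",
    "capturec_fold_changes",
    "distances_from_coordinates",
]

#: contact-fraction distance threshold (nm)
DEFAULT_CONTACT_NM = 150.0

#: pairs observed in fewer cells than this are masked from medians
DEFAULT_MIN_OBS = 20


def median_distance_matrix(
    ensemble: DistanceEnsemble, min_obs: int = DEFAULT_MIN_OBS
) -> MedianDistanceMatrix:
    """Population-median distance per segment pair, ignoring missing values.

    Pairs observed in fewer than ``min_obs`` cells are masked (NaN); the
    diagonal is NaN by construction.
    """
    if ensemble.n_cells < 1:
        raise ValueError("ensemble has no cells")
    S = ensemble.n_segments
    matrix = np.full((S, S), np.nan)
    n_obs = np.zeros((S, S), dtype=int)
    counts = np.sum(~np.isnan(ensemble.distances), axis=0)
    with np.errstate(all="ignore"):
        medians = np.nanmedian(ensemble.distances, axis=0)
    any_kept = False
    for col, (i, j) in enumerate(ensemble.pairs):
        n_obs[i, j] = n_obs[j, i] = counts[col]
        if counts[col] >= min_obs:
            matrix[i, j] = matrix[j, i] = medians[col]
            any_kept = True
    if not any_kept:
        raise ValueError("all pairs masked: too few observations per pair")
    return MedianDistanceMatrix(
        genotype=ensemble.genotype, matrix=matrix, n_observations=n_obs
    )


def contact_fraction(
    ensemble: DistanceEnsemble, threshold_nm: float = DEFAULT_CONTACT_NM
) -> MedianDistanceMatrix:
    """Fraction of cells with pair distance strictly below the threshold.

    Missing values are excluded from the denominator. Returned in the same
    matrix container as medians, with ``n_observations`` the denominators.
    """
    if threshold_nm <= 0:
        raise ValueError("threshold_nm must be positive")
    S = ensemble.n_segments
    matrix = np.full((S, S), np.nan)
    n_obs = np.zeros((S, S), dtype=int)
    observed = ~np.isnan(ensemble.distances)
    below = (ensemble.distances < threshold_nm) & observed
    denom = observed.sum(axis=0)
    any_kept = False
    for col, (i, j) in enumerate(ensemble.pairs):
        n_obs[i, j] = n_obs[j, i] = denom[col]
        if denom[col] > 0:
            matrix[i, j] = matrix[j, i] = below[:, col].sum() / denom[col]
            any_kept = True
    if not any_kept:
        raise ValueError("no pair has any observation")
    return MedianDistanceMatrix(
        genotype=ensemble.genotype, matrix=matrix, n_observations=n_obs
    )


def diff_matrix_test(
    alt: MedianDistanceMatrix, ref: MedianDistanceMatrix
) -> dict:
    """ALT - REF median-distance differences and a sign-balance test.

    Over pairs unmasked in both matrices, reports the difference matrix,
    its median, the counts of closer (negative) and further (positive)
    pairs, and a two-sided exact binomial p at success probability 0.5 on
    those counts (zero differences excluded; p = 1 when no nonzero
    differences exist).
    """
    if alt.matrix.shape != ref.matrix.shape:
        raise ValueError("segment sets differ between matrices")
    diff = alt.matrix - ref.matrix
    iu = np.triu_indices(diff.shape[0], k=1)
    vals = diff[iu]
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise ValueError("fewer than 2 unmasked shared pairs")
    n_closer = int((vals < 0).sum())
    n_further = int((vals > 0).sum())
    n_nonzero = n_closer + n_further
    if n_nonzero == 0:
        p = 1.0
    else:
        p = float(
            stats.binomtest(n_closer, n_nonzero, 0.5, alternative="two-sided").pvalue
        )
    return {
        "difference": diff,
        "median_diff": float(np.median(vals)),
        "n_closer": n_closer,
        "n_further": n_further,
        "p": p,
    }


def ensemble_concordance(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r over the shared unmasked off-diagonal entries of two matrices."""
    if a.shape != b.shape:
        raise ValueError("matrices must share a shape")
    iu = np.triu_indices(a.shape[0], k=1)
    x, y = a[iu], b[iu]
    keep = ~np.isnan(x) & ~np.isnan(y)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 shared unmasked entries")
    return float(np.corrcoef(x[keep], y[keep])[0, 1])


def distances_from_coordinates(xyz: np.ndarray) -> np.ndarray:
    """Euclidean pairwise distances from per-segment 3D coordinates.

    ``xyz`` is cells x segments x 3 with NaN rows for undetected segments;
    returns cells x n_pairs in upper-triangle order.
    """
    S = xyz.shape[1]
    iu, ju = np.triu_indices(S, k=1)
    return np.linalg.norm(xyz[:, iu, :] - xyz[:, ju, :], axis=2)


def capturec_bin_normalize(
    profile: CaptureCProfile,
    bin_bp: int = 5000,
    viewpoint_exclusion_bp: int = 1000,
) -> CaptureCProfile:
    """Viewpoint-excluded, TAD-normalized, binned Capture-C profile.

    Fragments whose midpoint lies within ±``viewpoint_exclusion_bp`` of the
    viewpoint are removed; remaining counts are scaled so the TAD total is
    1, then summed into fixed ``bin_bp`` bins tiled from the TAD start (by
    fragment midpoint, half-open).
    """
    if profile.layer != "raw":
        raise ValueError("capturec_bin_normalize expects a raw profile")
    frags = profile.fragments.copy()
    mid = (frags["start"] + frags["end"]) / 2.0
    tad_lo, tad_hi = profile.tad
    in_tad = (mid >= tad_lo) & (mid < tad_hi)
    excluded = np.abs(mid - profile.viewpoint) <= viewpoint_exclusion_bp
    kept = frags[in_tad & ~excluded]
    total = kept["count"].sum()
    if total <= 0:
        raise ValueError("TAD total is zero after viewpoint exclusion")
    norm = kept["count"] / total

    edges = np.arange(tad_lo, tad_hi, bin_bp)
    kept_mid = ((kept["start"] + kept["end"]) / 2.0).to_numpy()
    bin_idx = ((kept_mid - tad_lo) // bin_bp).astype(int)
    sums = np.zeros(len(edges))
    np.add.at(sums, bin_idx, norm.to_numpy())

    binned = pd.DataFrame(
        {
            "chrom": profile.fragments["chrom"].iloc[0],
            "start": edges,
            "end": np.minimum(edges + bin_bp, tad_hi),
            "count": sums,
        }
    )
    return CaptureCProfile(
        replicate_id=profile.replicate_id,
        genotype=profile.genotype,
        fragments=binned,
        viewpoint=profile.viewpoint,
        tad=profile.tad,
        layer="binned",
    )


def capturec_fold_changes(
    alt_profiles: list[CaptureCProfile],
    ref_profiles: list[CaptureCProfile],
) -> dict:
    """Per-bin log2 fold change of mean normalized ALT over REF counts.

    Both genotypes must be binned on the same grid. A pseudo-signal epsilon
    equal to the smallest positive normalized value across both genotypes
    keeps the log finite on empty bins. Also reports, per replicate, the
    fraction of TAD signal falling in the viewpoint-containing bin.
    """
    if not alt_profiles or not ref_profiles:
        raise ValueError("need at least one profile per genotype")
    grids = [
        tuple(p.fragments["start"]) for p in alt_profiles + ref_profiles
    ]
    if len(set(grids)) != 1:
        raise ValueError("bin grids differ between profiles")
    for p in alt_profiles + ref_profiles:
        if p.layer != "binned":
            raise ValueError("profiles must be binned (run capturec_bin_normalize)")

    alt = np.vstack([p.fragments["count"].to_numpy() for p in alt_profiles])
    ref = np.vstack([p.fragments["count"].to_numpy() for p in ref_profiles])
    pooled = np.concatenate([alt.ravel(), ref.ravel()])
    positive = pooled[pooled > 0]
    eps = positive.min() if positive.size else 1.0

    log2fc = np.log2((alt.mean(axis=0) + eps) / (ref.mean(axis=0) + eps))

    def viewpoint_fraction(profile: CaptureCProfile) -> float:
        starts = profile.fragments["start"].to_numpy()
        ends = profile.fragments["end"].to_numpy()
        inside = (starts <= profile.viewpoint) & (profile.viewpoint < ends)
        return float(profile.fragments["count"].to_numpy()[inside].sum())

    return {
        "bins": alt_profiles[0].fragments[["chrom", "start", "end"]].copy(),
        "log2fc": log2fc,
        "viewpoint_bin_fraction": {
            p.replicate_id: viewpoint_fraction(p)
            for p in alt_profiles + ref_profiles
        },
    }
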