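"""Module activity scoring and linear-regression QTL scanning.

The activity of a module (aVCM) is the first principal component of its
member peaks' normalized signals across individuals, sign-oriented so that
higher scores mean more active chromatin. QTL scans regress any per-sample
target (module activity, single peaks, gene expression, TF binding) on
additive genotype dosage, with Benjamini-Hochberg FDR over an explicitly
declared test universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ActivityScore,
    ChromatinModule,
    GenotypeVector,
    PeakSignalMatrix,
)

__all__ = ["compute_avcm", "qtl_scan", "fdr_adjust", "screen_variants"]


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def compute_avcm(
    matrix: PeakSignalMatrix, module: ChromatinModule
) -> ActivityScore:
    """Module activity score: standardized, sign-fixed PC1 of member peaks.

    Member peak rows are standardized, PC1 is taken over the samples x peaks
    submatrix, and the sign is fixed so the score correlates positively with
    the mean standardized member signal (higher score = more active
    chromatin). The returned score has mean 0 and variance 1.
    """
    if matrix.layer != "int-transformed":
        raise ValueError("compute_avcm expects the int-transformed layer")
    members = sorted(module.member_peaks)
    present = set(matrix.peak_ids)
    absent = [m for m in members if m not in present]
    if absent:
        raise ValueError(f"module members missing from matrix: {absent}")
    if len(members) < 2:
        raise ValueError("module must have at least 2 members")

    sub = matrix.subset_peaks(members)
    x = sub.values  # peaks x samples
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    # PC1 over samples x peaks
    u, s, _ = np.linalg.svd(x.T - x.T.mean(axis=0), full_matrices=False)
    score = u[:, 0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))

    mean_signal = x.mean(axis=0)
    orient = 1
    if np.corrcoef(score, mean_signal)[0, 1] < 0:
        orient = -1
        score = -score
    score = (score - score.mean()) / score.std()
    return ActivityScore(
        module_id=module.module_id,
        sample_ids=list(matrix.sample_ids),
        score=score,
        variance_explained=min(var_explained, 1.0),
        orientation=orient,
    )


def _ols_dosage(target: np.ndarray, dosage: np.ndarray) -> tuple[float, float, float, int]:
    """OLS of target on dosage with intercept: (beta, se, p, n)."""
    keep = ~np.isnan(dosage) & ~np.isnan(target)
    y, g = target[keep], dosage[keep]
    n = y.size
    vg = g.var()
    if n < 10 or vg == 0:
        return np.nan, np.nan, np.nan, n
    beta = np.cov(g, y, ddof=1)[0, 1] / g.var(ddof=1)
    alpha = y.mean() - beta * g.mean()
    resid = y - alpha - beta * g
    df = n - 2
    sigma2 = resid @ resid / df
    se = float(np.sqrt(sigma2 / (g.var(ddof=1) * (n - 1))))
    if se == 0:
        p = 0.0
    else:
        p = float(2.0 * stats.t.sf(abs(beta) / se, df=df))
    return float(beta), se, p, n


def qtl_scan(
    targets: pd.DataFrame,
    genotypes: list[GenotypeVector],
    universe: str = "declared",
) -> pd.DataFrame:
    """Per-(variant, target) linear QTL scan with BH FDR over the universe.

    ``targets`` is samples x targets (index = sample ids). Each test drops
    samples with missing dosage; constant-dosage tests are flagged
    untestable and excluded from the FDR universe.

    Returns columns ``variant_id``, ``target_id``, ``beta``, ``se``, ``p``,
    ``q``, ``n``, ``testable``, ``universe``.
    """
    rows = []
    for gv in genotypes:
        if list(targets.index) != list(gv.sample_ids):
            raise ValueError(
                f"sample order mismatch between targets and {gv.variant_id}"
            )
        for target_id in targets.columns:
            beta, se, p, n = _ols_dosage(
                targets[target_id].to_numpy(dtype=float), gv.dosage
            )
            rows.append(
                {
                    "variant_id": gv.variant_id,
                    "target_id": target_id,
                    "beta": beta,
                    "se": se,
                    "p": p,
                    "n": n,
                    "testable": np.isfinite(p) if p == p else False,
                }
            )
    result = pd.DataFrame(rows)
    result["testable"] = result["p"].notna()
    result["q"] = np.nan
    testable = result["testable"].to_numpy()
    if testable.any():
        result.loc[testable, "q"] = fdr_adjust(
            result.loc[testable, "p"].to_numpy()
        )
    result["universe"] = universe
    return result


def screen_variants(
    vcmqtl: pd.DataFrame,
    eqtl: pd.DataFrame,
    bqtl: pd.DataFrame,
    modules: list[ChromatinModule],
    module_of_variant: dict[str, str],
    fdr: float = 0.10,
) -> list[str]:
    """Three-way screen: variants significant in all three QTL scans.

    A variant passes if q <= ``fdr`` (default 10%) in the module-activity,
    expression and TF-binding scans, and its associated module coordinates
    at least 2 cis-regulatory elements. Ordered by the minimum q across the
    three scans (ties by variant id).
    """
    module_size = {m.module_id: m.size for m in modules}

    def sig(df: pd.DataFrame) -> dict[str, float]:
        hit = df[(df["q"] <= fdr) & df["testable"]]
        return hit.groupby("variant_id")["q"].min().to_dict()

    s1, s2, s3 = sig(vcmqtl), sig(eqtl), sig(bqtl)
    passed = []
    for variant in set(s1) & set(s2) & set(s3):
        mod_id = module_of_variant.get(variant)
        if mod_id is None or module_size.get(mod_id, 0) < 2:
            continue
        passed.append((min(s1[variant], s2[variant], s3[variant]), variant))
    return [v for _, v in sorted(passed)]
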