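"""PWM scanning and top-site Z-score calibration.

PWMs (4 x L log-odds, rows A,C,G,T) are scored at every offset on both
strands of a sequence. To compare scores across TFs with different motif
lengths and information content, each TF's maximum ("top-site") score over
a sequence is transformed into a Z-score using the mean and standard
deviation of its top-site scores over a large set of background accessible
regions. The allele comparison scans equal flanks around a variant on the
REF and ALT sequences and ranks TFs by the Z difference (ALT - REF), which
nominates binding sites gained or lost at the variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AlleleScanResult, BackgroundCalibration, PositionWeightModel

__all__ = [
    "counts_to_log_odds",
    "pwm_scan",
    "top_scores",
    "calibrate_background",
    "allele_max_zscores",
    "rank_allele_deltas",
    "extract_window",
]

#: scan window around the variant for the allele comparison (bp)
DEFAULT_SCAN_WINDOW = 757

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_NEG = -1e9  # sentinel for windows containing non-ACGT bases


def counts_to_log_odds(
    tf_id: str,
    counts: np.ndarray,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 1.0,
    source: str = "",
) -> PositionWeightModel:
    """Convert a 4 x L count matrix to log-odds.

    The pseudocount is split across bases proportionally to the background
    before normalizing columns to probabilities; log-odds are natural-log
    probability ratios against the background.
    """
    counts = np.asarray(counts, dtype=float)
    bg = np.asarray(background, dtype=float)[:, None]
    probs = (counts + pseudocount * bg) / (counts.sum(axis=0) + pseudocount)
    return PositionWeightModel(
        tf_id=tf_id, matrix=np.log(probs / bg), source=source
    )


def encode(sequence: str) -> np.ndarray:
    """DNA string -> int codes (A,C,G,T = 0..3; anything else = 4)."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.size, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def _scan_codes(matrix: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Forward-strand window scores; windows with non-ACGT -> -inf."""
    L = matrix.shape[1]
    n_win = codes.size - L + 1
    if n_win < 1:
        return np.empty(0)
    padded = np.vstack([matrix, np.full(L, _NEG)])  # row 4 poisons the window
    scores = np.zeros(n_win)
    for offset in range(L):
        scores += padded[codes[offset : offset + n_win], offset]
    scores[scores < _NEG / 2] = -np.inf
    return scores


_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def pwm_scan(pwm: PositionWeightModel, sequence: str) -> pd.DataFrame:
    """Score a PWM at every offset of both strands of a sequence.

    Positions are 0-based offsets of the window start on the forward
    sequence for both strands; windows containing non-ACGT bases are
    skipped. Returns columns ``position``, ``strand``, ``score``.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if len(sequence) < pwm.length:
        raise ValueError(
            f"sequence shorter than PWM ({len(sequence)} < {pwm.length})"
        )
    codes = encode(sequence)
    fwd = _scan_codes(pwm.matrix, codes)
    rev = _scan_codes(pwm.matrix, encode(reverse_complement(sequence)))[::-1]
    n = fwd.size
    df = pd.DataFrame(
        {
            "position": np.concatenate([np.arange(n), np.arange(n)]),
            "strand": ["+"] * n + ["-"] * n,
            "score": np.concatenate([fwd, rev]),
        }
    )
    return df[np.isfinite(df["score"])].reset_index(drop=True)


def top_scores(pwm: PositionWeightModel, regions: list[str]) -> np.ndarray:
    """Maximum two-strand score of a PWM per region (vectorized over regions)."""
    out = np.empty(len(regions))
    for i, region in enumerate(regions):
        codes = encode(region)
        fwd = _scan_codes(pwm.matrix, codes)
        rev = _scan_codes(pwm.matrix, encode(reverse_complement(region)))
        best = max(
            fwd.max() if fwd.size else -np.inf,
            rev.max() if rev.size else -np.inf,
        )
        out[i] = best
    return out


def calibrate_background(
    pwm_set: list[PositionWeightModel], regions: list[str]
) -> dict[str, BackgroundCalibration]:
    """Per-TF top-site score distribution over background regions.

    For each PWM, the maximum score per region is collected and its mean
    and sd (n-1 denominator) stored. Calibrations with zero sd are kept but
    flagged degenerate.
    """
    if len(regions) < 2:
        raise ValueError("need at least 2 background regions")
    out = {}
    for pwm in pwm_set:
        short = [r for r in regions if len(r) < pwm.length]
        if short:
            raise ValueError(
                f"{len(short)} background regions shorter than PWM {pwm.tf_id}"
            )
        tops = top_scores(pwm, regions)
        out[pwm.tf_id] = BackgroundCalibration(
            tf_id=pwm.tf_id,
            n_regions=len(regions),
            mean_top_score=float(tops.mean()),
            sd_top_score=float(tops.std(ddof=1)),
        )
    return out


def zscore(score: float, calib: BackgroundCalibration) -> float:
    if calib.degenerate:
        if score == calib.mean_top_score:
            return 0.0
        raise ValueError(
            f"degenerate calibration for {calib.tf_id}: Z undefined for "
            "scores away from the mean"
        )
    return (score - calib.mean_top_score) / calib.sd_top_score


def allele_max_zscores(
    pwm_set: list[PositionWeightModel],
    calibration: dict[str, BackgroundCalibration],
    ref_sequence: str,
    alt_sequence: str,
) -> list[AlleleScanResult]:
    """Per-TF maximum score and calibrated Z for each allele sequence."""
    missing = [p.tf_id for p in pwm_set if p.tf_id not in calibration]
    if missing:
        raise ValueError(f"missing background calibration for: {missing}")
    results = []
    for pwm in pwm_set:
        calib = calibration[pwm.tf_id]
        per_allele = []
        for seq in (ref_sequence, alt_sequence):
            scan = pwm_scan(pwm, seq)
            best = scan.loc[scan["score"].idxmax()]
            per_allele.append(
                (float(best["score"]), (int(best["position"]), str(best["strand"])))
            )
        (score_ref, best_ref), (score_alt, best_alt) = per_allele
        results.append(
            AlleleScanResult(
                tf_id=pwm.tf_id,
                max_score_ref=score_ref,
                max_score_alt=score_alt,
                z_ref=zscore(score_ref, calib),
                z_alt=zscore(score_alt, calib),
                best_ref=best_ref,
                best_alt=best_alt,
            )
        )
    return results


def extract_window(
    sequence: str, variant_pos: int, window_bp: int = DEFAULT_SCAN_WINDOW
) -> str:
    """Equal flanks of ``window_bp`` total around a variant position.

    Both alleles are windowed the same way (centered on the variant with
    equal flank lengths), so the ALT window is shorter in genomic span by
    the indel length.
    """
    half = window_bp // 2
    lo = max(0, variant_pos - half)
    hi = min(len(sequence), variant_pos + (window_bp - half))
    return sequence[lo:hi]


def rank_allele_deltas(
    results: list[AlleleScanResult],
    expression: pd.DataFrame | None = None,
    min_expression: float = 0.5,
) -> pd.DataFrame:
    """Rank TFs by delta Z (ALT - REF), optionally filtered by expression.

    ``expression`` (optional) has columns ``tf_id`` and ``mean_fpkm``; when
    supplied, TFs below ``min_expression`` (default mean FPKM 0.5) are
    dropped. Sorted by delta_z descending, ties broken by tf_id.
    """
    if expression is not None and expression.empty:
        raise ValueError(
            "expression table supplied but empty; omit it to skip filtering"
        )
    df = pd.DataFrame(
        {
            "tf_id": [r.tf_id for r in results],
            "z_ref": [r.z_ref for r in results],
            "z_alt": [r.z_alt for r in results],
            "delta_z": [r.delta_z for r in results],
        }
    )
    if expression is not None:
        expressed = expression.loc[
            expression["mean_fpkm"] >= min_expression, "tf_id"
        ]
        df = df[df["tf_id"].isin(set(expressed))]
    return df.sort_values(
        ["delta_z", "tf_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
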