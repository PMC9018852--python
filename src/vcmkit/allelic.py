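"""Phased-haplotype allele-specific binding analysis.

Per-variant ALT/REF read counts from ChIP-seq assays aligned to phased
personal genomes are summed over a region of interest, then tested for
imbalance with an exact two-sided binomial test whose null success
probability is taken from the matched input (correcting reference bias),
with a minimum-read filter, per-region BH FDR, and a log2 fold change of
the assay ALT percentage over the input ALT percentage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "aggregate_region_counts",
    "imbalance_test",
    "log2fc_over_input",
    "tf_binding_density",
    "INPUT_ASSAY",
]

#: reserved assay id for the sequencing input (the imbalance null)
INPUT_ASSAY = "input"

#: assays with summed ALT+REF reads below this are not tested
DEFAULT_MIN_READS = 6


def aggregate_region_counts(
    table: pd.DataFrame,
    regions: pd.DataFrame,
    variant_positions: pd.DataFrame,
) -> pd.DataFrame:
    """Sum per-variant ALT/REF counts over the heterozygous variants in each region.

    ``table`` has columns ``assay_id``, ``variant_id``, ``alt_reads``,
    ``ref_reads`` (the input is one assay with id ``input``); ``regions``
    has ``region_id``, ``chrom``, ``start``, ``end`` (half-open);
    ``variant_positions`` has ``variant_id``, ``chrom``, ``pos`` (0-based).
    Regions with no contained variant yield (0, 0) for every assay.
    """
    if table.duplicated(["assay_id", "variant_id"]).any():
        dups = table[table.duplicated(["assay_id", "variant_id"], keep=False)]
        raise ValueError(
            "duplicate (assay, variant) rows would double-count reads: "
            f"{sorted(set(map(tuple, dups[['assay_id', 'variant_id']].values)))[:5]}"
        )
    missing = set(table["variant_id"]) - set(variant_positions["variant_id"])
    if missing:
        raise ValueError(f"no position for variants: {sorted(missing)[:5]}")

    pos = variant_positions.set_index("variant_id")
    assays = sorted(table["assay_id"].unique())
    rows = []
    for _, region in regions.iterrows():
        inside = pos[
            (pos["chrom"] == region["chrom"])
            & (pos["pos"] >= region["start"])
            & (pos["pos"] < region["end"])
        ].index
        sub = table[table["variant_id"].isin(inside)]
        sums = sub.groupby("assay_id")[["alt_reads", "ref_reads"]].sum()
        for assay in assays:
            alt, ref = (
                (int(sums.loc[assay, "alt_reads"]), int(sums.loc[assay, "ref_reads"]))
                if assay in sums.index
                else (0, 0)
            )
            rows.append(
                {
                    "assay_id": assay,
                    "region_id": region["region_id"],
                    "alt_reads": alt,
                    "ref_reads": ref,
                }
            )
    return pd.DataFrame(rows)


def binomial_two_sided(k: int, n: int, p0: float, rule: str = "minlike") -> float:
    """Exact two-sided binomial p-value.

    ``minlike`` sums the probabilities of all outcomes no more likely than
    the observed one (the common exact-test convention); ``double`` doubles
    the smaller one-sided tail, capped at 1.
    """
    if rule == "minlike":
        return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)
    if rule == "double":
        lo = stats.binom.cdf(k, n, p0)
        hi = stats.binom.sf(k - 1, n, p0)
        return float(min(1.0, 2.0 * min(lo, hi)))
    raise ValueError(f"unknown two-sided rule {rule!r}")


def imbalance_test(
    region_counts: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
    rule: str = "minlike",
) -> pd.DataFrame:
    """Input-corrected exact binomial imbalance test per (assay, region).

    The null ALT fraction p0 is the input assay's ALT share in the region
    (0.5 with a warning flag if the input has no reads). Assays whose total
    reads fall below ``min_reads`` (default 6) are filtered, not tested.
    BH FDR is applied across the tested assays within each region.

    Returns columns ``assay_id``, ``region_id``, ``n_total``,
    ``alt_fraction``, ``p0``, ``p``, ``q``, ``log2fc_over_input``,
    ``status``, ``input_fallback``.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    out_frames = []
    for region_id, group in region_counts.groupby("region_id", sort=False):
        inp = group[group["assay_id"] == INPUT_ASSAY]
        if inp.empty:
            raise ValueError(f"region {region_id!r} has no input assay row")
        ia, ir = int(inp["alt_reads"].iloc[0]), int(inp["ref_reads"].iloc[0])
        fallback = (ia + ir) == 0
        p0 = 0.5 if fallback else ia / (ia + ir)

        rows = []
        for _, rec in group[group["assay_id"] != INPUT_ASSAY].iterrows():
            alt, ref = int(rec["alt_reads"]), int(rec["ref_reads"])
            n = alt + ref
            row = {
                "assay_id": rec["assay_id"],
                "region_id": region_id,
                "n_total": n,
                "alt_fraction": alt / n if n else np.nan,
                "p0": p0,
                "input_fallback": fallback,
            }
            if n < min_reads:
                row.update(p=np.nan, status="filtered_low_reads", log2fc_over_input=np.nan)
            else:
                row.update(
                    p=binomial_two_sided(alt, n, p0, rule=rule),
                    status="tested",
                    log2fc_over_input=log2fc_over_input(alt, ref, p0),
                )
            rows.append(row)
        df = pd.DataFrame(rows)
        df["q"] = np.nan
        tested = df["status"] == "tested"
        if tested.any():
            from .qtl import fdr_adjust

            df.loc[tested, "q"] = fdr_adjust(df.loc[tested, "p"].to_numpy())
        out_frames.append(df)
    return pd.concat(out_frames, ignore_index=True)


def log2fc_over_input(alt: int, ref: int, input_alt_fraction: float) -> float:
    """log2 of the assay ALT percentage over the input ALT percentage.

    If either allele of the assay has zero reads, one read is first added to
    both alleles so the log is finite.
    """
    if input_alt_fraction <= 0:
        raise ValueError("input ALT fraction must be positive for a fold change")
    if alt == 0 or ref == 0:
        alt, ref = alt + 1, ref + 1
    return float(np.log2((alt / (alt + ref)) / input_alt_fraction))


def tf_binding_density(
    peak_sets: dict[str, pd.DataFrame],
    window: tuple[int, int],
    bin_bp: int = 10,
) -> pd.DataFrame:
    """Per-bin count of assays with at least one peak overlapping the bin.

    The window is partitioned into ``bin_bp`` bins (default 10 bp, last bin
    may be short); each assay contributes at most 1 to a bin regardless of
    how many of its peaks overlap it. Peak frames need ``start``/``end``
    (half-open).

    Returns columns ``bin_start``, ``bin_end``, ``count``.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    start, end = window
    edges = np.arange(start, end, bin_bp)
    bin_start = edges
    bin_end = np.minimum(edges + bin_bp, end)
    counts = np.zeros(len(edges), dtype=int)
    for assay, peaks in peak_sets.items():
        hit = np.zeros(len(edges), dtype=bool)
        for s, e in zip(peaks["start"], peaks["end"]):
            # overlap with half-open bin [bs, be): s < be and e > bs
            hit |= (s < bin_end) & (e > bin_start)
        counts += hit
    return pd.DataFrame({"bin_start": bin_start, "bin_end": bin_end, "count": counts})
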