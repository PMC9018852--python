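"""Variable chromatin module (VCM) calling.

A VCM is a set of >=2 cis-regulatory peaks whose normalized signals covary
across individuals. Modules are called from same-chromosome pairwise Pearson
correlations within a genomic window, by either an FDR cut on the pair
p-values, a fixed correlation threshold, or an average-linkage hierarchical
clustering variant; calls from different datasets can be merged into
consensus modules by span overlap.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import ChromatinModule, PeakSignalMatrix
from .qtl import fdr_adjust

__all__ = [
    "pairwise_correlations",
    "call_vcms_fdr",
    "call_vcms_rthreshold",
    "call_vcms_hclust",
    "consensus_vcms",
]

#: default cis window for the pair-test universe (brackets the TAD scale)
DEFAULT_WINDOW_BP = 2_000_000


def correlation_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson r from the exact t distribution, df = n-2."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def pairwise_correlations(
    matrix: PeakSignalMatrix, window_bp: int = DEFAULT_WINDOW_BP
) -> pd.DataFrame:
    """Pearson correlations for same-chromosome peak pairs within a window.

    Pairs are unordered, restricted to peaks whose interval midpoints lie
    within ``window_bp`` of each other. Benjamini-Hochberg q-values are
    computed per chromosome over the emitted pairs.

    Returns a DataFrame with columns ``peak_a``, ``peak_b``, ``chrom``,
    ``r``, ``p``, ``q``.
    """
    if matrix.layer != "int-transformed":
        raise ValueError("pairwise_correlations expects the int-transformed layer")
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    n = matrix.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples for pair correlation tests")

    records: list[pd.DataFrame] = []
    peaks = matrix.peaks
    for chrom, idx in peaks.groupby("chrom", sort=False).groups.items():
        pos = peaks.index.get_indexer(idx)
        sub = matrix.values[pos]
        mids = (
            peaks.loc[idx, "start"].to_numpy() + peaks.loc[idx, "end"].to_numpy()
        ) / 2.0
        ids = peaks.loc[idx, "peak_id"].to_numpy()
        m = len(pos)
        if m < 2:
            continue
        corr = np.corrcoef(sub)
        iu, ju = np.triu_indices(m, k=1)
        keep = np.abs(mids[iu] - mids[ju]) <= window_bp
        iu, ju = iu[keep], ju[keep]
        if iu.size == 0:
            continue
        r = corr[iu, ju]
        p = correlation_pvalue(r, n)
        df = pd.DataFrame(
            {
                "peak_a": ids[iu],
                "peak_b": ids[ju],
                "chrom": chrom,
                "r": r,
                "p": p,
            }
        )
        df["q"] = fdr_adjust(df["p"].to_numpy())
        records.append(df)
    if not records:
        return pd.DataFrame(
            columns=["peak_a", "peak_b", "chrom", "r", "p", "q"]
        )
    return pd.concat(records, ignore_index=True)


def _modules_from_edges(
    edges: pd.DataFrame, peaks: pd.DataFrame, method: str
) -> list[ChromatinModule]:
    """Connected components of the kept-edge graph -> ChromatinModule list."""
    if edges.empty:
        return []
    nodes = pd.unique(pd.concat([edges["peak_a"], edges["peak_b"]], ignore_index=True))
    index = {p: i for i, p in enumerate(nodes)}
    row = edges["peak_a"].map(index).to_numpy()
    col = edges["peak_b"].map(index).to_numpy()
    graph = sparse.coo_matrix(
        (np.ones(len(edges)), (row, col)), shape=(len(nodes), len(nodes))
    )
    n_comp, labels = sparse.csgraph.connected_components(graph, directed=False)

    meta = peaks.set_index("peak_id")
    # mean pairwise r among members, over the emitted pairs
    edge_r: dict[int, list[float]] = defaultdict(list)
    for a, b, r in zip(edges["peak_a"], edges["peak_b"], edges["r"]):
        edge_r[labels[index[a]]].append(r)

    out: list[ChromatinModule] = []
    for comp in range(n_comp):
        members = [nodes[i] for i in np.flatnonzero(labels == comp)]
        if len(members) < 2:
            continue
        rows = meta.loc[members]
        chroms = rows["chrom"].unique()
        if len(chroms) != 1:  # cannot happen for cis pairs; guard anyway
            raise ValueError("module members span multiple chromosomes")
        out.append(
            ChromatinModule(
                module_id="",
                member_peaks=frozenset(members),
                chromosome=str(chroms[0]),
                span=(int(rows["start"].min()), int(rows["end"].max())),
                method=method,
                mean_r=float(np.mean(edge_r[comp])),
            )
        )
    # deterministic ordering and ids: by chromosome then span start
    out.sort(key=lambda mod: (mod.chromosome, mod.span, sorted(mod.member_peaks)))
    return [
        ChromatinModule(
            module_id=f"{method}_{k}",
            member_peaks=mod.member_peaks,
            chromosome=mod.chromosome,
            span=mod.span,
            method=mod.method,
            mean_r=mod.mean_r,
        )
        for k, mod in enumerate(out)
    ]


def call_vcms_fdr(
    pairs: pd.DataFrame,
    peaks: pd.DataFrame,
    fdr: float = 0.001,
    positive_only: bool = True,
) -> list[ChromatinModule]:
    """Group peaks into modules via pairs significant at a BH FDR cut.

    Edges are pairs with q <= ``fdr`` (and r > 0 unless ``positive_only`` is
    off); modules are the connected components with >=2 members. The default
    0.1% FDR is the original module-calling threshold.
    """
    if pairs.empty:
        return []
    if "q" not in pairs.columns:
        raise ValueError("pair table must carry BH q-values")
    kept = pairs[pairs["q"] <= fdr]
    if positive_only:
        kept = kept[kept["r"] > 0]
    return _modules_from_edges(kept, peaks, method="fdr")


def call_vcms_rthreshold(
    pairs: pd.DataFrame, peaks: pd.DataFrame, r_min: float = 0.5
) -> list[ChromatinModule]:
    """Group peaks into modules via pairs with r >= ``r_min`` (default 0.5)."""
    if not 0.0 < r_min < 1.0:
        raise ValueError("r_min must lie in (0, 1)")
    if pairs.empty:
        return []
    kept = pairs[pairs["r"] >= r_min]
    return _modules_from_edges(kept, peaks, method="r-threshold")


def call_vcms_hclust(
    matrix: PeakSignalMatrix,
    window_bp: int = DEFAULT_WINDOW_BP,
    mean_abs_r_cut: float = 0.5,
) -> list[ChromatinModule]:
    """Hierarchical-clustering module calls (average linkage on 1 - r).

    Peaks on each chromosome are clustered on distance 1 - r; the maximal
    tree nodes whose mean within-node \\|r\\| meets ``mean_abs_r_cut`` are
    reported as modules. This delineates nested substructure that a flat
    threshold merges.
    """
    if matrix.layer != "int-transformed":
        raise ValueError("call_vcms_hclust expects the int-transformed layer")
    if matrix.n_samples < 4:
        raise ValueError("need at least 4 samples")

    out: list[ChromatinModule] = []
    peaks = matrix.peaks
    for chrom, idx in peaks.groupby("chrom", sort=False).groups.items():
        pos = peaks.index.get_indexer(idx)
        order = np.argsort(peaks.loc[idx, "start"].to_numpy(), kind="stable")
        pos = pos[order]
        ids = peaks.loc[idx, "peak_id"].to_numpy()[order]
        m = len(pos)
        if m < 2:
            continue
        mids = (
            peaks.iloc[pos]["start"].to_numpy() + peaks.iloc[pos]["end"].to_numpy()
        ) / 2.0
        corr = np.corrcoef(matrix.values[pos])
        np.fill_diagonal(corr, 1.0)
        # out-of-window pairs get zero correlation: they never pull peaks together
        in_window = np.abs(mids[:, None] - mids[None, :]) <= window_bp
        corr = np.where(in_window, corr, 0.0)
        dist = squareform(1.0 - np.clip(corr, -1.0, 1.0), checks=False)
        link = hierarchy.linkage(dist, method="average")

        tree = hierarchy.to_tree(link)
        abs_r = np.abs(corr)

        def mean_abs_r(leaves: list[int]) -> float:
            sub = abs_r[np.ix_(leaves, leaves)]
            iu = np.triu_indices(len(leaves), k=1)
            return float(sub[iu].mean())

        def collect(node) -> None:
            leaves = node.pre_order(lambda leaf: leaf.id)
            if len(leaves) >= 2 and mean_abs_r(leaves) >= mean_abs_r_cut:
                members = [ids[i] for i in leaves]
                rows = peaks.set_index("peak_id").loc[members]
                out.append(
                    ChromatinModule(
                        module_id="",
                        member_peaks=frozenset(members),
                        chromosome=str(chrom),
                        span=(int(rows["start"].min()), int(rows["end"].max())),
                        method="hclust",
                        mean_r=float(
                            corr[np.ix_(leaves, leaves)][
                                np.triu_indices(len(leaves), k=1)
                            ].mean()
                        ),
                    )
                )
                return  # maximal node found; do not descend further
            if not node.is_leaf():
                collect(node.left)
                collect(node.right)

        collect(tree)

    out.sort(key=lambda mod: (mod.chromosome, mod.span, sorted(mod.member_peaks)))
    return [
        ChromatinModule(
            module_id=f"hclust_{k}",
            member_peaks=mod.member_peaks,
            chromosome=mod.chromosome,
            span=mod.span,
            method=mod.method,
            mean_r=mod.mean_r,
        )
        for k, mod in enumerate(out)
    ]


def consensus_vcms(
    calls: list[list[ChromatinModule]],
    genome_builds: list[str] | None = None,
) -> list[ChromatinModule]:
    """Merge module calls from multiple datasets by span overlap.

    Modules whose spans overlap on the same chromosome (across or within
    call sets) are merged: member union, span union, method ``consensus``;
    the provenance of the source calls is kept in ``sources``.
    """
    if len(calls) < 2:
        raise ValueError("consensus requires at least 2 call sets")
    if genome_builds is not None and len(set(genome_builds)) > 1:
        raise ValueError(f"mixed genome builds: {sorted(set(genome_builds))}")

    tagged = [
        (f"set{k}", mod) for k, call in enumerate(calls) for mod in call
    ]
    merged: list[ChromatinModule] = []
    by_chrom: dict[str, list[tuple[str, ChromatinModule]]] = defaultdict(list)
    for tag, mod in tagged:
        by_chrom[mod.chromosome].append((tag, mod))

    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda t: t[1].span)
        # sweep: overlapping spans coalesce into one consensus module
        cur_members: set[str] = set()
        cur_span: tuple[int, int] | None = None
        cur_sources: list[str] = []
        cur_r: list[float] = []

        def flush() -> None:
            if cur_span is None:
                return
            merged.append(
                ChromatinModule(
                    module_id="",
                    member_peaks=frozenset(cur_members),
                    chromosome=chrom,
                    span=cur_span,
                    method="consensus",
                    mean_r=float(np.mean(cur_r)),
                    sources=tuple(cur_sources),
                )
            )

        for tag, mod in items:
            if cur_span is not None and mod.span[0] < cur_span[1]:
                cur_span = (cur_span[0], max(cur_span[1], mod.span[1]))
                cur_members |= mod.member_peaks
                cur_sources.append(f"{tag}:{mod.module_id}")
                cur_r.append(mod.mean_r)
            else:
                flush()
                cur_span = mod.span
                cur_members = set(mod.member_peaks)
                cur_sources = [f"{tag}:{mod.module_id}"]
                cur_r = [mod.mean_r]
        flush()

    return [
        ChromatinModule(
            module_id=f"consensus_{k}",
            member_peaks=mod.member_peaks,
            chromosome=mod.chromosome,
            span=mod.span,
            method=mod.method,
            mean_r=mod.mean_r,
            sources=mod.sources,
        )
        for k, mod in enumerate(merged)
    ]
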