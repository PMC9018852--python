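"""Readers and writers for the plain-text formats the pipeline exchanges.

Matrices travel as TSV with a sidecar JSON recording the normalization
layer; intervals as BED-like TSV; sequences as FASTA (via Biopython); PWMs
as JASPAR-style text or a simple 4 x L TSV; distance ensembles and fragment
counts as long-format TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import (
    CaptureCProfile,
    ChromatinModule,
    DistanceEnsemble,
    GenotypeVector,
    PeakSignalMatrix,
    PositionWeightModel,
)
from .motif import counts_to_log_odds

__all__ = [
    "write_peak_matrix",
    "read_peak_matrix",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_minimal_vcf",
    "write_fasta",
    "read_fasta",
    "write_pwm_tsv",
    "read_pwm_tsv",
    "read_jaspar_pwms",
    "write_modules",
    "write_distance_ensemble",
    "read_distance_ensemble",
    "write_capturec_profile",
    "read_capturec_profile",
    "write_bedgraph",
    "load_config_file",
]

_META_COLS = ["chrom", "start", "end", "peak_id", "assay"]


def write_peak_matrix(matrix: PeakSignalMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.to_frame().to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"layer": matrix.layer, "genome_build": matrix.genome_build})
    )


def read_peak_matrix(path: str | Path) -> PeakSignalMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sample_ids = [c for c in df.columns if c not in _META_COLS]
    sidecar = path.with_suffix(path.suffix + ".json")
    layer, build = "raw", None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        layer = meta.get("layer", "raw")
        build = meta.get("genome_build")
    return PeakSignalMatrix(
        peaks=df[_META_COLS].copy(),
        sample_ids=sample_ids,
        values=df[sample_ids].to_numpy(dtype=float),
        layer=layer,
        genome_build=build,
    )


def write_genotype_tsv(genotypes: list[GenotypeVector], path: str | Path) -> None:
    rows = []
    for gv in genotypes:
        for sample, dose in zip(gv.sample_ids, gv.dosage):
            rows.append(
                {
                    "variant_id": gv.variant_id,
                    "chrom": gv.chrom,
                    "position": gv.position,
                    "ref": gv.ref_allele,
                    "alt": gv.alt_allele,
                    "sample_id": sample,
                    "dosage": "" if np.isnan(dose) else int(dose),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path: str | Path) -> list[GenotypeVector]:
    df = pd.read_csv(path, sep="\t", dtype={"dosage": "Float64"})
    out = []
    for variant_id, group in df.groupby("variant_id", sort=False):
        out.append(
            GenotypeVector(
                variant_id=str(variant_id),
                chrom=str(group["chrom"].iloc[0]),
                position=int(group["position"].iloc[0]),
                ref_allele=str(group["ref"].iloc[0]),
                alt_allele=str(group["alt"].iloc[0]),
                sample_ids=group["sample_id"].tolist(),
                dosage=group["dosage"].to_numpy(dtype=float),
            )
        )
    return out


def write_minimal_vcf(genotypes: list[GenotypeVector], path: str | Path) -> None:
    """Minimal unphased VCF 4.2 with GT calls derived from dosage."""
    if not genotypes:
        raise ValueError("nothing to write")
    samples = genotypes[0].sample_ids
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for gv in genotypes:
        if gv.sample_ids != samples:
            raise ValueError("all variants must share the sample set")
        calls = [
            "./." if np.isnan(d) else gt[float(d)] for d in gv.dosage
        ]
        lines.append(
            f"{gv.chrom}\t{gv.position}\t{gv.variant_id}\t{gv.ref_allele}\t"
            f"{gv.alt_allele}\t.\t.\t.\tGT\t" + "\t".join(calls)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_pwm_tsv(pwms: list[PositionWeightModel], path: str | Path) -> None:
    """Simple text PWM format: one '>tf_id' header then 4 rows A/C/G/T."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.tf_id}\n")
            for base, row in zip("ACGT", pwm.matrix):
                fh.write(base + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_pwm_tsv(path: str | Path) -> list[PositionWeightModel]:
    pwms = []
    tf_id, rows = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if tf_id is not None:
                    pwms.append(
                        PositionWeightModel(tf_id, np.array(rows), source=str(path))
                    )
                tf_id, rows = line[1:].split()[0], []
            else:
                parts = line.split("\t")
                rows.append([float(v) for v in parts[1:]])
    if tf_id is not None:
        pwms.append(PositionWeightModel(tf_id, np.array(rows), source=str(path)))
    return pwms


def read_jaspar_pwms(
    path: str | Path,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 1.0,
) -> list[PositionWeightModel]:
    """JASPAR-format count matrices, converted to log-odds."""
    out = []
    with open(path) as fh:
        for m in motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            out.append(
                counts_to_log_odds(
                    m.name or m.matrix_id,
                    counts,
                    background=background,
                    pseudocount=pseudocount,
                    source=str(path),
                )
            )
    return out


def write_modules(
    modules: list[ChromatinModule], bed_path: str | Path, members_path: str | Path
) -> None:
    """Module spans as BED; membership as a TSV of (module_id, peak_id)."""
    with open(bed_path, "w") as fh:
        for mod in modules:
            fh.write(
                f"{mod.chromosome}\t{mod.span[0]}\t{mod.span[1]}\t"
                f"{mod.module_id}\t{mod.mean_r:.4f}\t.\n"
            )
    rows = [
        {
            "module_id": mod.module_id,
            "peak_id": pid,
            "method": mod.method,
            "mean_r": mod.mean_r,
        }
        for mod in modules
        for pid in sorted(mod.member_peaks)
    ]
    pd.DataFrame(rows, columns=["module_id", "peak_id", "method", "mean_r"]).to_csv(
        members_path, sep="\t", index=False
    )


def write_distance_ensemble(ensemble: DistanceEnsemble, path: str | Path) -> None:
    """Long format: cell_id, seg_i, seg_j, nm (missing entries omitted)."""
    cells, cols = np.nonzero(~np.isnan(ensemble.distances))
    pairs = np.asarray(ensemble.pairs)
    df = pd.DataFrame(
        {
            "cell_id": cells,
            "seg_i": pairs[cols, 0],
            "seg_j": pairs[cols, 1],
            "nm": ensemble.distances[cells, cols],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    seg_path = Path(path).with_suffix(".segments.bed")
    ensemble.segments[["chrom", "start", "end", "index"]].to_csv(
        seg_path, sep="\t", index=False, header=False
    )
    meta = Path(path).with_suffix(Path(path).suffix + ".json")
    meta.write_text(
        json.dumps(
            {"genotype": ensemble.genotype, "n_cells": int(ensemble.n_cells)}
        )
    )


def read_distance_ensemble(path: str | Path) -> DistanceEnsemble:
    df = pd.read_csv(path, sep="\t")
    seg_path = Path(path).with_suffix(".segments.bed")
    segments = pd.read_csv(
        seg_path, sep="\t", names=["chrom", "start", "end", "index"]
    )[["index", "chrom", "start", "end"]]
    meta_path = Path(path).with_suffix(Path(path).suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    S = len(segments)
    iu, ju = np.triu_indices(S, k=1)
    pairs = list(zip(iu.tolist(), ju.tolist()))
    col_of = {pair: k for k, pair in enumerate(pairs)}
    n_cells = meta.get("n_cells", int(df["cell_id"].max()) + 1 if len(df) else 0)
    distances = np.full((n_cells, len(pairs)), np.nan)
    cols = [col_of[(i, j)] for i, j in zip(df["seg_i"], df["seg_j"])]
    distances[df["cell_id"].to_numpy(), cols] = df["nm"].to_numpy()
    return DistanceEnsemble(
        genotype=meta.get("genotype", ""),
        segments=segments,
        pairs=pairs,
        distances=distances,
    )


def write_capturec_profile(profile: CaptureCProfile, path: str | Path) -> None:
    profile.fragments.to_csv(path, sep="\t", index=False)
    meta = Path(path).with_suffix(Path(path).suffix + ".json")
    meta.write_text(
        json.dumps(
            {
                "replicate_id": profile.replicate_id,
                "genotype": profile.genotype,
                "viewpoint": profile.viewpoint,
                "tad": list(profile.tad),
                "layer": profile.layer,
            }
        )
    )


def read_capturec_profile(path: str | Path) -> CaptureCProfile:
    frags = pd.read_csv(path, sep="\t")
    meta = json.loads(
        Path(path).with_suffix(Path(path).suffix + ".json").read_text()
    )
    return CaptureCProfile(
        replicate_id=meta["replicate_id"],
        genotype=meta["genotype"],
        fragments=frags,
        viewpoint=meta["viewpoint"],
        tad=tuple(meta["tad"]),
        layer=meta["layer"],
    )


def write_bedgraph(
    bins: pd.DataFrame, values: np.ndarray, chrom: str, path: str | Path
) -> None:
    with open(path, "w") as fh:
        for (_, row), v in zip(bins.iterrows(), values):
            fh.write(f"{chrom}\t{int(row['bin_start'])}\t{int(row['bin_end'])}\t{v}\n")


def load_config_file(path: str | Path) -> dict:
    """JSON or YAML key/value config."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)
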