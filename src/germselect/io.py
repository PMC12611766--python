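"""Readers and writers for the on-disk interchange formats.

Everything is plain text: FASTA for the reference, BED for exon models
(0-based half-open on disk, converted to the package's 1-based inclusive
convention on read), bedGraph for coverage and methylation tracks, and TSV
for variant tables and sample metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .context import encode
from .coverage import CoverageTrack
from .reference import GeneModel, ReferenceBundle

VARIANT_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "vartype",
    "mutant_duplex_reads",
    "site_duplex_coverage",
]

METADATA_COLUMNS = [
    "sample_id",
    "donor_id",
    "tissue",
    "age_years",
    "time_point",
    "sperm_count_per_ml",
    "contamination_alpha",
    "bmi",
    "pack_years",
    "drink_years",
    "twin_pair_id",
]


def write_fasta(path: str | Path, chrom: str, sequence: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")


def read_fasta(path: str | Path) -> tuple[str, np.ndarray]:
    fa = Fasta(str(path), build_index=True, rebuild=True)
    chrom = list(fa.keys())[0]
    seq = str(fa[chrom][:]).upper()
    return chrom, encode(seq)


def write_exon_bed(path: str | Path, chrom: str, genes: list[GeneModel]) -> None:
    """One BED line per exon; score column unused (0)."""
    with open(path, "w") as fh:
        for gene in genes:
            for start, end in gene.exons:
                fh.write(f"{chrom}\t{start - 1}\t{end}\t{gene.gene_id}\t0\t{gene.strand}\n")


def read_exon_bed(path: str | Path) -> list[GeneModel]:
    rows = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
    )
    genes = []
    for gene_id, grp in rows.groupby("gene_id", sort=False):
        grp = grp.sort_values("start")
        exons = [(int(s) + 1, int(e)) for s, e in zip(grp["start"], grp["end"])]
        genes.append(GeneModel(str(gene_id), grp["strand"].iloc[0], exons))
    return genes


def write_bedgraph(path: str | Path, chrom: str, values: np.ndarray) -> None:
    """Run-length encoded bedGraph of a per-base track (zeros included)."""
    values = np.asarray(values)
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(values)]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            v = values[s]
            fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path: str | Path, length: int, dtype=np.float64) -> np.ndarray:
    out = np.zeros(length, dtype=dtype)
    with open(path) as fh:
        for line in fh:
            chrom, start, end, value = line.rstrip("\n").split("\t")
            out[int(start) : int(end)] = float(value)
    return out


def write_methylation_bedgraph(path: str | Path, ref: ReferenceBundle) -> None:
    """Single-base bedGraph intervals at CpG cytosines."""
    with open(path, "w") as fh:
        for pos, m in zip(ref.cpg_positions, ref.methylation):
            fh.write(f"{ref.chrom}\t{pos - 1}\t{pos}\t{m:.6g}\n")


def read_methylation_bedgraph(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    rows = pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "value"])
    return rows["start"].to_numpy() + 1, rows["value"].to_numpy(dtype=float)


def write_coverage_dir(outdir: str | Path, coverage: CoverageTrack) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sid, arr in coverage.depths.items():
        write_bedgraph(outdir / f"{sid}.coverage.bedgraph", coverage.chrom, arr)


def read_coverage_dir(indir: str | Path, chrom: str, length: int) -> CoverageTrack:
    indir = Path(indir)
    depths = {}
    for path in sorted(indir.glob("*.coverage.bedgraph")):
        sid = path.name.replace(".coverage.bedgraph", "")
        depths[sid] = read_bedgraph(path, length, dtype=np.int32)
    return CoverageTrack(chrom, length, depths)


def write_variants(path: str | Path, variants: pd.DataFrame) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_variants(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_metadata(path: str | Path, meta: pd.DataFrame) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(path: str | Path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
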