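"""Readers and writers for the small text formats the pipeline exchanges.

MAF parsing goes through Biopython's MAF support; BED, BedGraph and GFF3
are simple enough that pandas round-trips them. All genomic intervals are
0-based half-open internally; GFF3 is converted at the boundary.
"""

from __future__ import annotations

import io as _io
from typing import Iterable, Sequence

import pandas as pd


def write_maf(blocks, path, src_sizes=None) -> None:
    """Write alignment blocks to MAF.

    ``blocks``: iterable of (chrom, start, {taxon: gapped_seq}); sequence
    names are written as ``taxon.chrom``. ``src_sizes`` maps chrom to the
    source-sequence length (defaults to the running maximum end).
    """
    blocks = list(blocks)
    sizes = dict(src_sizes or {})
    if not sizes:
        for chrom, start, seqs in blocks:
            span = max(len(s.replace("-", "")) for s in seqs.values())
            sizes[chrom] = max(sizes.get(chrom, 0), start + span)
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=none\n")
        for chrom, start, seqs in blocks:
            fh.write("\na score=0.0\n")
            for taxon, seq in seqs.items():
                size = len(seq) - seq.count("-")
                fh.write(f"s {taxon}.{chrom} {start} {size} + {sizes[chrom]} {seq}\n")


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df.astype({"start": int, "end": int})


def write_bed(intervals: Iterable[Sequence], path, extra_cols=()) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def write_bedgraph(rows, path) -> None:
    """rows: iterable of (chrom, start, end, value)."""
    with open(path, "w") as fh:
        for chrom, start, end, value in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    return df.astype({"start": int, "end": int})


GFF3_COLUMNS = ["seqid", "source", "type", "start", "end", "score",
                "strand", "phase", "attributes"]


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene features as (gene_id, chrom, start, end), 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=GFF3_COLUMNS)
    genes = df[df["type"] == "gene"].copy()
    genes["gene_id"] = genes["attributes"].str.extract(r"ID=([^;]+)")
    out = genes[["gene_id", "seqid", "start", "end"]].rename(columns={"seqid": "chrom"})
    out["start"] = out["start"].astype(int) - 1  # GFF3 is 1-based inclusive
    out["end"] = out["end"].astype(int)
    return out.reset_index(drop=True)


def write_gff3_genes(genes, path) -> None:
    """genes: iterable of (gene_id, chrom, start0, end) half-open."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, chrom, start, end in genes:
            fh.write(f"{chrom}\tdiscordia\tgene\t{start + 1}\t{end}\t.\t+\t.\t"
                     f"ID={gene_id}\n")


CONTIG_HIT_COLUMNS = ["contig", "chrom", "start", "end", "identity",
                      "gene_id", "gene_coverage", "best", "reciprocal_best"]


def read_contig_hits(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CONTIG_HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"contig hit table missing columns: {sorted(missing)}")
    return df


def write_contig_hits(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=CONTIG_HIT_COLUMNS)


def read_vcf_positions(path) -> list[tuple[str, int]]:
    """(chrom, pos0) for every record of a VCF (0-based positions)."""
    from cyvcf2 import VCF
    return [(v.CHROM, v.POS - 1) for v in VCF(str(path))]


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
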