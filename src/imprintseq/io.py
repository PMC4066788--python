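"""File-format boundaries: FASTA/FASTQ via Biopython, BED/TSV via pandas.

Internal coordinates are 0-based half-open everywhere; 1-based positions
appear only in TSV/VCF columns that are documented as such.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with _open(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    with _open(path, "rt") as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fastq(path, reads: Iterable[tuple[str, str]], quality: int = 40) -> None:
    """Write (read_id, sequence) pairs with a flat quality value."""
    with _open(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{chr(quality + 33) * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    with _open(path, "rt") as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fastq")]


def write_bed(path, df: pd.DataFrame, cols=("scaffold", "start", "end", "name", "score", "strand")) -> None:
    """BED (0-based half-open); missing optional columns are filled."""
    out = df.copy()
    if "name" not in out.columns:
        out["name"] = "."
    if "score" not in out.columns:
        out["score"] = 0
    if "strand" not in out.columns:
        out["strand"] = "."
    out[list(cols)].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, names=("scaffold", "start", "end", "name", "score", "strand")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = list(names)[: df.shape[1]]
    return df


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_snp_vcf(path, snps: pd.DataFrame, reference_name: str = "parent1") -> None:
    """Minimal VCF 4.2 with the parent-2 allele as ALT.

    Expects columns scaffold, pos (0-based), allele_p1, allele_p2.
    """
    with _open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={reference_name}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in snps.itertuples():
            fh.write(
                f"{row.scaffold}\t{row.pos + 1}\t.\t{row.allele_p1}\t{row.allele_p2}\t.\tPASS\t.\n"
            )
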