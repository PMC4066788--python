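"""Homozygous SNP calling between two inbred parental lines.

Works from per-site pileup summaries built by the in-repo read placer.
A site becomes a SNP when, in each parent separately, at least
``min_coverage`` quality-passing bases remain after discarding bases
near read ends, the parent is effectively homozygous, and the two
parental consensus bases differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seqmatch import GenomeMapper, revcomp, seq_to_u8

logger = logging.getLogger(__name__)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class Pileup:
    """Per-scaffold (4, L) base-count arrays for one sample.

    ``interior`` counts quality-passing bases lying at least
    ``end_margin_bp`` from both ends of their read; ``margin`` counts
    the bases that were discarded for lying within the end margin.
    """

    interior: dict[str, np.ndarray]
    margin: dict[str, np.ndarray]
    end_margin_bp: int
    min_quality: int


def place_reads(reads, genome: dict[str, str], max_mismatch: int = 4, unique_only: bool = True):
    """Ungapped bounded-mismatch placement of RNA reads on a genome.

    Returns (read_id, Placement, genome-oriented sequence) triples.
    Multi-mapping reads (several equally good placements) are dropped
    when ``unique_only``.
    """
    mapper = GenomeMapper(genome, max_mismatch=max_mismatch)
    out = []
    for rid, seq in reads:
        best = mapper.place_best(seq)
        if not best or (unique_only and len(best) > 1):
            continue
        p = best[0]
        out.append((rid, p, seq if p.strand == "+" else revcomp(seq)))
    return out


def build_pileup(
    placements,
    genome: dict[str, str],
    end_margin_bp: int = 5,
    min_quality: int = 20,
    qualities: dict[str, np.ndarray] | None = None,
) -> Pileup:
    """Accumulate placed reads into per-site base counts.

    ``qualities`` optionally maps read id to a per-base Phred array (in
    original read orientation); bases at or below ``min_quality`` are
    not counted at all.  Synthetic reads carry no quality ramp, so by
    default every base passes.
    """
    interior = {s: np.zeros((4, len(seq)), dtype=np.int32) for s, seq in genome.items()}
    margin = {s: np.zeros((4, len(seq)), dtype=np.int32) for s, seq in genome.items()}
    for rid, placement, oriented in placements:
        codes = _CODE[seq_to_u8(oriented)]
        L = len(codes)
        pos = placement.start + np.arange(L)
        dist_end = np.minimum(np.arange(L), L - 1 - np.arange(L))
        ok = codes < 4
        if qualities is not None and rid in qualities:
            q = qualities[rid]
            if placement.strand == "-":
                q = q[::-1]
            ok &= q > min_quality
        in_margin = dist_end < end_margin_bp
        tgt = interior[placement.scaffold]
        sel = ok & ~in_margin
        np.add.at(tgt, (codes[sel], pos[sel]), 1)
        sel = ok & in_margin
        np.add.at(margin[placement.scaffold], (codes[sel], pos[sel]), 1)
    return Pileup(interior, margin, end_margin_bp, min_quality)


def pileup_table(pileups: dict[str, Pileup]) -> pd.DataFrame:
    """Tidy per-site summary (one row per covered site per parent)."""
    rows = []
    for parent, pu in pileups.items():
        for scaffold, counts in pu.interior.items():
            cov = counts.sum(axis=0)
            for pos in np.flatnonzero(cov):
                a, c, g, t = counts[:, pos]
                ea, ec, eg, et = pu.margin[scaffold][:, pos]
                rows.append((scaffold, int(pos), parent, a, c, g, t, ea, ec, eg, et))
    return pd.DataFrame(
        rows,
        columns=[
            "scaffold", "pos", "parent",
            "A", "C", "G", "T", "A_end", "C_end", "G_end", "T_end",
        ],
    )


def call_snps(
    pileups: dict[str, Pileup],
    min_coverage: int = 5,
    max_minor_fraction: float = 0.1,
    min_minor_count: int = 2,
) -> pd.DataFrame:
    """Emit homozygous parental differences.

    A parent is heterozygous at a site when its minor-allele fraction
    exceeds ``max_minor_fraction`` AND the minor allele has at least
    ``min_minor_count`` reads (a single discordant read is treated as a
    sequencing error).  Heterozygous sites in either parent are excluded.
    Returns a table with 0-based ``pos``, both alleles and coverages.
    """
    p1, p2 = pileups["p1"], pileups["p2"]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    rows = []
    for scaffold in p1.interior:
        c1 = p1.interior[scaffold]
        c2 = p2.interior[scaffold]
        cov1 = c1.sum(axis=0)
        cov2 = c2.sum(axis=0)
        candidate = (cov1 >= max(min_coverage, 1)) & (cov2 >= max(min_coverage, 1))
        for pos in np.flatnonzero(candidate):
            site = []
            ok = True
            for counts, cov in ((c1[:, pos], cov1[pos]), (c2[:, pos], cov2[pos])):
                major = int(np.argmax(counts))
                minor = int(cov - counts[major])
                if minor / cov > max_minor_fraction and minor >= min_minor_count:
                    ok = False
                    break
                site.append((major, int(cov)))
            if not ok:
                continue
            (b1, n1), (b2, n2) = site
            if b1 != b2:
                rows.append((scaffold, int(pos), chr(bases[b1]), chr(bases[b2]), n1, n2))
    snps = pd.DataFrame(
        rows, columns=["scaffold", "pos", "allele_p1", "allele_p2", "cov_p1", "cov_p2"]
    )
    return snps.sort_values(["scaffold", "pos"], ignore_index=True)


def snps_from_reads(
    reads_by_parent: dict[str, list],
    genome: dict[str, str],
    max_mismatch: int = 4,
    end_margin_bp: int = 5,
    min_quality: int = 20,
    min_coverage: int = 5,
    max_minor_fraction: float = 0.1,
) -> pd.DataFrame:
    """Convenience wrapper: place both parents' reads and call SNPs."""
    pileups = {}
    for parent, reads in reads_by_parent.items():
        placements = place_reads(reads, genome, max_mismatch=max_mismatch)
        pileups[parent] = build_pileup(
            placements, genome, end_margin_bp=end_margin_bp, min_quality=min_quality
        )
    return call_snps(
        pileups, min_coverage=min_coverage, max_minor_fraction=max_minor_fraction
    )


def write_snp_table(path, snps: pd.DataFrame) -> None:
    out = snps.copy()
    out["pos_1based"] = out["pos"] + 1
    cols = ["scaffold", "pos_1based", "allele_p1", "allele_p2", "cov_p1", "cov_p2"]
    out[[c for c in cols if c in out.columns]].to_csv(path, sep="\t", index=False)


def read_snp_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos_1based"] - 1
    return df.drop(columns=["pos_1based"])
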