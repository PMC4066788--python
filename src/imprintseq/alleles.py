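"""Allele-specific read counting around informative SNPs.

For every SNP between the parental lines, a pair of 191-nt windows
(SNP +/- 90 bp) is extracted from the reference, one carrying each
parental allele.  Endosperm reads are matched to the windows ungapped,
fully contained, in either orientation, with a bounded mismatch count;
a read overlapping the SNP position is assigned to whichever allele's
base it carries.  Per-locus parent-1/parent-2 counts are then oriented
into maternal/paternal counts using the cross direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seqmatch import revcomp, seq_to_u8

logger = logging.getLogger(__name__)


@dataclass
class AlleleWindow:
    scaffold: str
    pos: int  # 0-based SNP position on the scaffold
    allele_p1: str
    allele_p2: str
    start: int  # window start on the scaffold (0-based)
    seq_p1: str
    seq_p2: str
    snp_offset: int  # 0-based SNP position within the window


def build_windows(
    genome: dict[str, str],
    snps: pd.DataFrame,
    flank: int = 90,
    window_len: int = 191,
) -> list[AlleleWindow]:
    """One allele-window pair per SNP (default 191 nt, SNP at offset 90).

    The window spans ``flank`` bases left of the SNP and
    ``window_len - flank - 1`` bases right of it; the reference
    nucleotide at the SNP is replaced by each parental variant.
    Windows are truncated at scaffold edges with the SNP offset
    adjusted; a SNP position outside its scaffold is an error.
    """
    windows = []
    for snp in snps.itertuples():
        seq = genome[snp.scaffold]
        if not 0 <= snp.pos < len(seq):
            raise ValueError(f"SNP position {snp.pos} outside scaffold {snp.scaffold}")
        start = max(0, snp.pos - flank)
        end = min(len(seq), snp.pos + (window_len - flank))
        core = seq[start:end].upper()
        off = snp.pos - start
        windows.append(
            AlleleWindow(
                snp.scaffold,
                int(snp.pos),
                snp.allele_p1,
                snp.allele_p2,
                start,
                core[:off] + snp.allele_p1 + core[off + 1 :],
                core[:off] + snp.allele_p2 + core[off + 1 :],
                off,
            )
        )
    return windows


class _WindowIndex:
    def __init__(self, windows: list[AlleleWindow], k: int = 18):
        self.k = k
        self.windows = windows
        self._u8 = [(seq_to_u8(w.seq_p1), seq_to_u8(w.seq_p2)) for w in windows]
        self._index: dict[str, set[tuple[int, int]]] = {}
        for wi, w in enumerate(windows):
            for seq in (w.seq_p1, w.seq_p2):
                for off in range(len(seq) - k + 1):
                    self._index.setdefault(seq[off : off + k], set()).add((wi, off))

    def candidates(self, read: str, n_seeds: int):
        k = self.k
        L = len(read)
        if L < k:
            return
        seed_pos = [i * k for i in range(n_seeds) if i * k + k <= L]
        tail = L - k
        if tail not in seed_pos:
            seed_pos.append(tail)
        seen = set()
        for sp in seed_pos:
            for wi, off in self._index.get(read[sp : sp + k], ()):
                cand = (wi, off - sp)
                if cand not in seen:
                    seen.add(cand)
                    yield cand


def assign_reads(
    reads,
    windows: list[AlleleWindow],
    max_mismatch: int = 4,
) -> tuple[pd.DataFrame, dict]:
    """Count reads per parental allele at each SNP window.

    A read is assigned at a window when it aligns ungapped and fully
    contained (either orientation, at most ``max_mismatch`` mismatches
    against the better-matching allele sequence), the alignment covers
    the SNP offset, and the read base at the SNP equals one parental
    allele.  Among candidate placements within a window only
    minimal-mismatch placements are kept, ties broken leftmost.  A read
    assignable at several distinct SNPs is counted at each, unless its
    parental assignments conflict, in which case it is discarded
    everywhere (chimera/error guard).

    Returns a per-locus count table and a stats dict
    (n_reads, n_assigned, n_unassigned, n_conflict).
    """
    index = _WindowIndex(windows)
    n_seeds = max_mismatch + 1
    count_p1 = np.zeros(len(windows), dtype=np.int64)
    count_p2 = np.zeros(len(windows), dtype=np.int64)
    n_assigned = n_conflict = 0
    for _rid, seq in reads:
        per_window: dict[int, tuple] = {}
        for orient_i, oriented in enumerate((seq, revcomp(seq))):
            r = seq_to_u8(oriented)
            L = len(r)
            for wi, start in index.candidates(oriented, n_seeds):
                w = windows[wi]
                if start < 0 or start + L > len(w.seq_p1):
                    continue
                if not start <= w.snp_offset < start + L:
                    continue
                w1, w2 = index._u8[wi]
                mm1 = int(np.count_nonzero(w1[start : start + L] != r))
                mm2 = int(np.count_nonzero(w2[start : start + L] != r))
                mm = min(mm1, mm2)
                if mm > max_mismatch:
                    continue
                key = (mm, orient_i, start)
                prev = per_window.get(wi)
                if prev is None or key < prev[0]:
                    base = chr(r[w.snp_offset - start])
                    per_window[wi] = (key, base)
        assignments = {}
        for wi, (_key, base) in per_window.items():
            w = windows[wi]
            if base == w.allele_p1:
                assignments[wi] = "p1"
            elif base == w.allele_p2:
                assignments[wi] = "p2"
        if not assignments:
            continue
        if len(set(assignments.values())) > 1:
            n_conflict += 1
            continue
        n_assigned += 1
        for wi, parent in assignments.items():
            (count_p1 if parent == "p1" else count_p2)[wi] += 1
    counts = pd.DataFrame(
        {
            "scaffold": [w.scaffold for w in windows],
            "pos": [w.pos for w in windows],
            "count_p1": count_p1,
            "count_p2": count_p2,
        }
    )
    n_reads = len(reads)
    stats = {
        "n_reads": n_reads,
        "n_assigned": n_assigned,
        "n_conflict": n_conflict,
        "n_unassigned": n_reads - n_assigned - n_conflict,
    }
    return counts, stats


def counts_by_cross(
    counts_axb: pd.DataFrame,
    counts_bxa: pd.DataFrame,
    min_reads: int = 10,
) -> pd.DataFrame:
    """Joint locus x cross table with maternal/paternal orientation.

    In cross AxB parent 1 is the mother, in BxA parent 2 is.  Loci must
    be informative (>= 1 assigned read) in both crosses to enter the
    joint table; the ``high_quality`` flag marks loci with more than
    ``min_reads`` reads in both crosses.
    """
    a = counts_axb.rename(columns={"count_p1": "p1_AxB", "count_p2": "p2_AxB"})
    b = counts_bxa.rename(columns={"count_p1": "p1_BxA", "count_p2": "p2_BxA"})
    merged = a.merge(b, on=["scaffold", "pos"], how="inner")
    merged["mat_AxB"] = merged["p1_AxB"]
    merged["pat_AxB"] = merged["p2_AxB"]
    merged["mat_BxA"] = merged["p2_BxA"]
    merged["pat_BxA"] = merged["p1_BxA"]
    merged["n_AxB"] = merged["mat_AxB"] + merged["pat_AxB"]
    merged["n_BxA"] = merged["mat_BxA"] + merged["pat_BxA"]
    merged = merged[(merged["n_AxB"] > 0) & (merged["n_BxA"] > 0)].reset_index(drop=True)
    merged["high_quality"] = (merged["n_AxB"] > min_reads) & (merged["n_BxA"] > min_reads)
    return merged


def write_count_table(path, counts: pd.DataFrame) -> None:
    out = counts.copy()
    out["pos_1based"] = out["pos"] + 1
    cols = [
        "scaffold", "pos_1based",
        "mat_AxB", "pat_AxB", "mat_BxA", "pat_BxA",
        "p1_AxB", "p2_AxB", "p1_BxA", "p2_BxA",
        "n_AxB", "n_BxA", "high_quality",
    ]
    out[[c for c in cols if c in out.columns]].to_csv(path, sep="\t", index=False)
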