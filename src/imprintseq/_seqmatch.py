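"""Deterministic k-mer-seeded ungapped read placement.

Replaces external short-read aligners for the unspliced, desk-scale data
this package works on.  A read is placed by looking up ``max_mismatch + 1``
disjoint seeds in a k-mer index of the target (pigeonhole: any ungapped
placement with at most ``max_mismatch`` mismatches leaves at least one seed
exact) and verifying every candidate diagonal with a full mismatch count.

Bisulfite placement uses the standard three-letter trick: seeds are drawn
from C->T (Watson) and G->A (Crick) converted sequences, and verification
treats genome-C/read-T (plus strand) or genome-G/read-A (minus strand) as a
non-mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_C, _G, _T, _A = (ord(x) for x in "CGTA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def seq_to_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


class KmerIndex:
    """Exact k-mer index over a set of named sequences."""

    def __init__(self, sequences: dict[str, str], k: int):
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in sequences.items():
            for pos in range(len(seq) - k + 1):
                self._index.setdefault(seq[pos : pos + k], []).append((name, pos))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def _seed_positions(read_len: int, k: int, n_seeds: int) -> list[int]:
    if read_len < k:
        return []
    pos = [i * k for i in range(n_seeds) if i * k + k <= read_len]
    tail = read_len - k
    if tail not in pos:
        pos.append(tail)
    return pos


@dataclass(frozen=True)
class Placement:
    scaffold: str
    start: int  # 0-based on the target
    strand: str  # '+' read as given, '-' reverse complement
    mismatches: int


def _candidates(read: str, index: KmerIndex, n_seeds: int):
    k = index.k
    seen = set()
    for sp in _seed_positions(len(read), k, n_seeds):
        for scaffold, pos in index.lookup(read[sp : sp + k]):
            start = pos - sp
            if (scaffold, start) not in seen:
                seen.add((scaffold, start))
                yield scaffold, start


def count_mismatches(target: np.ndarray, read: np.ndarray, mode: str = "plain") -> int:
    """Hamming distance; 'bs_plus'/'bs_minus' apply the bisulfite allowance."""
    diff = target != read
    if mode == "bs_plus":
        diff &= ~((target == _C) & (read == _T))
    elif mode == "bs_minus":
        diff &= ~((target == _G) & (read == _A))
    return int(np.count_nonzero(diff))


class GenomeMapper:
    """Places reads on a genome, trying both orientations."""

    def __init__(self, genome: dict[str, str], k: int = 18, max_mismatch: int = 4):
        self.genome = genome
        self.max_mismatch = max_mismatch
        self.k = k
        self._u8 = {name: seq_to_u8(seq) for name, seq in genome.items()}
        self._index = KmerIndex(genome, k)

    def place(self, read: str) -> list[Placement]:
        n_seeds = self.max_mismatch + 1
        out = []
        for strand, oriented in (("+", read), ("-", revcomp(read))):
            r = seq_to_u8(oriented)
            for scaffold, start in _candidates(oriented, self._index, n_seeds):
                tgt = self._u8[scaffold]
                if start < 0 or start + len(r) > len(tgt):
                    continue
                mm = count_mismatches(tgt[start : start + len(r)], r)
                if mm <= self.max_mismatch:
                    out.append(Placement(scaffold, start, strand, mm))
        return out

    def place_best(self, read: str) -> list[Placement]:
        """Minimal-mismatch placements only (ties all returned)."""
        hits = self.place(read)
        if not hits:
            return []
        best = min(p.mismatches for p in hits)
        return [p for p in hits if p.mismatches == best]


class BisulfiteMapper:
    """Bisulfite-aware ungapped placement on a reference genome.

    Plus-strand candidates are seeded in the C->T-converted genome with the
    C->T-converted read; minus-strand candidates in the G->A genome with the
    G->A-converted reverse complement.  Verification counts true mismatches
    with the strand-appropriate conversion allowance.
    """

    def __init__(self, genome: dict[str, str], k: int = 24, max_mismatch: int = 2):
        self.genome = genome
        self.max_mismatch = max_mismatch
        self._u8 = {name: seq_to_u8(seq) for name, seq in genome.items()}
        ct = {n: s.replace("C", "T") for n, s in genome.items()}
        ga = {n: s.replace("G", "A") for n, s in genome.items()}
        self._ct_index = KmerIndex(ct, k)
        self._ga_index = KmerIndex(ga, k)

    def place(self, read: str) -> list[tuple[Placement, str]]:
        """Returns (placement, genome-oriented read sequence) pairs."""
        n_seeds = self.max_mismatch + 1
        out = []
        rc = revcomp(read)
        for strand, oriented, conv, index, mode in (
            ("+", read, read.replace("C", "T"), self._ct_index, "bs_plus"),
            ("-", rc, rc.replace("G", "A"), self._ga_index, "bs_minus"),
        ):
            r = seq_to_u8(oriented)
            for scaffold, start in _candidates(conv, index, n_seeds):
                tgt = self._u8[scaffold]
                if start < 0 or start + len(r) > len(tgt):
                    continue
                mm = count_mismatches(tgt[start : start + len(r)], r, mode)
                if mm <= self.max_mismatch:
                    out.append((Placement(scaffold, start, strand, mm), oriented))
        return out

    def place_unique(self, read: str) -> tuple[Placement, str] | None:
        """Best placement, or None if unplaced or ambiguous (multi-mapping)."""
        hits = self.place(read)
        if not hits:
            return None
        best = min(p.mismatches for p, _ in hits)
        best_hits = [h for h in hits if h[0].mismatches == best]
        if len(best_hits) > 1:
            return None
        return best_hits[0]
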