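"""Bisulfite methylome analysis: CpG calls, profiles, DMRs.

Methylation level at a cytosine is c/(c+t) over reads covering it,
where a read-C means the cytosine resisted conversion (methylated) and
a read-T means it converted.  Endosperm-vs-embryo DMRs are segments of
nearby CpGs satisfying five criteria: enough methylated sites, enough
reads per cytosine, minimum length with bounded gaps between member
sites, a mean level difference of at least 0.5, and a Pearson chi-square
P <= 0.05 on the pooled counts.  Allele-specific DMRs use reads whose
SNP bases identify their parental haplotype, scored in sliding 200-bp
windows under a <40% / >70% two-allele rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seqmatch import BisulfiteMapper, Placement, seq_to_u8

logger = logging.getLogger(__name__)

_C, _G, _T, _A = (ord(x) for x in "CGTA")


def map_bisulfite_reads(
    reads,
    genome: dict[str, str],
    max_mismatch: int = 2,
    unique_only: bool = True,
):
    """Bisulfite-aware ungapped placement (C->T / G->A tolerant).

    Returns (read_id, Placement, genome-oriented sequence) triples;
    reads with several equally good placements are removed when
    ``unique_only``.
    """
    mapper = BisulfiteMapper(genome, max_mismatch=max_mismatch)
    out = []
    for rid, seq in reads:
        if unique_only:
            hit = mapper.place_unique(seq)
            if hit is None:
                continue
            placement, oriented = hit
        else:
            hits = mapper.place(seq)
            if not hits:
                continue
            placement, oriented = min(hits, key=lambda h: h[0].mismatches)
        out.append((rid, placement, oriented))
    return out


def assign_parent_of_origin(
    placements,
    snps: pd.DataFrame,
    maternal_line: str = "p1",
) -> dict[str, str]:
    """Label each placed read maternal/paternal/unknown via SNP bases.

    Bisulfite conversion makes some SNPs uninformative on one strand
    (C/T on plus, G/A on minus); a read base compatible with both
    alleles casts no vote, and conflicting votes give 'unknown'.
    """
    by_scaffold = {}
    for s, d in snps.groupby("scaffold"):
        d = d.sort_values("pos")
        by_scaffold[s] = (
            d["pos"].to_numpy(),
            d["allele_p1"].to_numpy(),
            d["allele_p2"].to_numpy(),
        )
    lines = ("p1", "p2") if maternal_line == "p1" else ("p2", "p1")
    labels = {}
    for rid, placement, oriented in placements:
        entry = by_scaffold.get(placement.scaffold)
        votes = {"p1": 0, "p2": 0}
        if entry is not None:
            pos_arr, a1_arr, a2_arr = entry
            L = len(oriented)
            lo = np.searchsorted(pos_arr, placement.start)
            hi = np.searchsorted(pos_arr, placement.start + L)
            for i in range(lo, hi):
                b = oriented[pos_arr[i] - placement.start]
                m1 = _allele_matches(a1_arr[i], b, placement.strand)
                m2 = _allele_matches(a2_arr[i], b, placement.strand)
                if m1 and not m2:
                    votes["p1"] += 1
                elif m2 and not m1:
                    votes["p2"] += 1
        mat, pat = lines
        if votes[mat] > 0 and votes[pat] == 0:
            labels[rid] = "maternal"
        elif votes[pat] > 0 and votes[mat] == 0:
            labels[rid] = "paternal"
        else:
            labels[rid] = "unknown"
    return labels


def _allele_matches(allele: str, base: str, strand: str) -> bool:
    if base == allele:
        return True
    if strand == "+" and allele == "C" and base == "T":
        return True
    if strand == "-" and allele == "G" and base == "A":
        return True
    return False


def call_cytosines(
    placements,
    genome: dict[str, str],
    parent_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-CpG methylated/unmethylated read counts.

    For each genomic C on the read's reference strand, a read base C
    increments ``c_count`` and T increments ``t_count``; other bases are
    ignored.  CpG context comes from the reference; symmetric-strand
    merging is not applied (plus- and minus-strand cytosines of one CpG
    are separate rows).  With ``parent_labels``, counts are split by
    parental origin and reads labelled 'unknown' are dropped.
    """
    genome_u8 = {s: seq_to_u8(seq) for s, seq in genome.items()}
    parents = ("maternal", "paternal") if parent_labels is not None else ("all",)
    acc = {
        p: {
            s: np.zeros((4, len(g)), dtype=np.int32)  # c+, t+, c-, t-
            for s, g in genome_u8.items()
        }
        for p in parents
    }
    for rid, placement, oriented in placements:
        if parent_labels is not None:
            p = parent_labels.get(rid, "unknown")
            if p == "unknown":
                continue
        else:
            p = "all"
        g = genome_u8[placement.scaffold]
        L = len(oriented)
        seg = g[placement.start : placement.start + L]
        r = seq_to_u8(oriented)
        a = acc[p][placement.scaffold]
        if placement.strand == "+":
            base_c, read_c, read_t, rows = _C, _C, _T, (0, 1)
        else:
            base_c, read_c, read_t, rows = _G, _G, _A, (2, 3)
        np.add.at(a[rows[0]], placement.start + np.flatnonzero((seg == base_c) & (r == read_c)), 1)
        np.add.at(a[rows[1]], placement.start + np.flatnonzero((seg == base_c) & (r == read_t)), 1)

    frames = []
    for p in parents:
        for s, a in acc[p].items():
            g = genome_u8[s]
            watson_cpg = np.zeros(len(g), dtype=bool)
            watson_cpg[:-1] = (g[:-1] == _C) & (g[1:] == _G)
            crick_cpg = np.zeros(len(g), dtype=bool)
            crick_cpg[1:] = (g[1:] == _G) & (g[:-1] == _C)
            for strand, c_arr, t_arr, ctx in (
                ("+", a[0], a[1], watson_cpg),
                ("-", a[2], a[3], crick_cpg),
            ):
                covered = np.flatnonzero(((c_arr + t_arr) > 0) & ctx)
                if not len(covered):
                    continue
                frames.append(
                    pd.DataFrame(
                        {
                            "scaffold": s,
                            "pos": covered,
                            "strand": strand,
                            "context": "CpG",
                            "c_count": c_arr[covered],
                            "t_count": t_arr[covered],
                            "parent": p,
                        }
                    )
                )
    if not frames:
        return pd.DataFrame(
            columns=["scaffold", "pos", "strand", "context", "c_count", "t_count", "parent", "level"]
        )
    calls = pd.concat(frames, ignore_index=True)
    calls["level"] = calls["c_count"] / (calls["c_count"] + calls["t_count"])
    if parent_labels is None:
        calls = calls.drop(columns=["parent"])
    return calls.sort_values(["scaffold", "pos", "strand"], ignore_index=True)


def metagene_profile(
    calls: pd.DataFrame,
    features: pd.DataFrame,
    flank: int = 2000,
    bin_size: int = 200,
    anchor: str = "five_prime",
) -> pd.DataFrame:
    """Average CpG methylation in fixed bins around feature anchors.

    Features are oriented by strand and aligned at their 5' or 3' end;
    bins span ``flank`` bp outside the feature plus the proximal part
    of the feature body (positions past the far end are excluded).  The
    per-bin value is the unweighted mean of per-cytosine levels within
    the bin for one feature, averaged over features with data.
    """
    if anchor not in ("five_prime", "three_prime"):
        raise ValueError(f"unknown anchor: {anchor!r}")
    by_scaffold = {
        s: (d["pos"].to_numpy(), d["level"].to_numpy())
        for s, d in calls.sort_values("pos").groupby("scaffold")
    }
    n_bins = 2 * (flank // bin_size)
    bin_lo = -(flank // bin_size)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for f in features.itertuples():
        entry = by_scaffold.get(f.scaffold)
        if entry is None:
            continue
        pos, level = entry
        lo = np.searchsorted(pos, f.start - flank)
        hi = np.searchsorted(pos, f.end + flank)
        if hi <= lo:
            continue
        p = pos[lo:hi]
        v = level[lo:hi]
        sign = 1 if f.strand == "+" else -1
        if anchor == "five_prime":
            a = f.start if f.strand == "+" else f.end - 1
        else:
            a = f.end - 1 if f.strand == "+" else f.start
        rel = (p - a) * sign
        feat_len = f.end - f.start
        if anchor == "five_prime":
            keep = (rel >= -flank) & (rel < flank) & (rel < feat_len)
        else:
            keep = (rel > -flank) & (rel <= flank) & (rel > -feat_len)
            rel = rel - 1  # shift so the anchor base falls in bin -1 (body side)
        rel, v = rel[keep], v[keep]
        if not len(rel):
            continue
        bins = np.floor_divide(rel, bin_size) - bin_lo
        fsum = np.zeros(n_bins)
        fcnt = np.zeros(n_bins, dtype=int)
        np.add.at(fsum, bins, v)
        np.add.at(fcnt, bins, 1)
        has = fcnt > 0
        sums[has] += fsum[has] / fcnt[has]
        counts[has] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    edges = (np.arange(n_bins) + bin_lo) * bin_size
    return pd.DataFrame(
        {"bin_start": edges, "bin_end": edges + bin_size, "mean_level": mean, "n_features": counts}
    )


def _chi2_p(c_a: int, t_a: int, c_b: int, t_b: int) -> float:
    table = np.array([[c_a, t_a], [c_b, t_b]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.chi2_contingency(table, correction=False).pvalue)


def call_dmrs(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    min_meth_sites: int = 5,
    min_reads: int = 10,
    min_len: int = 40,
    max_gap: int = 200,
    min_diff: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differentially methylated regions between two samples.

    Seed-and-chain segmentation: (1) restrict to CpGs with more than
    ``min_reads`` reads in both samples; (2) seed on sites whose level
    difference reaches ``min_diff``; (3) chain seeds closer than
    ``max_gap`` bp; (4) keep segments longer than ``min_len`` bp with
    more than ``min_meth_sites`` methylated CpGs in at least one
    sample, mean level difference >= ``min_diff`` and Pearson
    chi-square P <= ``alpha`` on the pooled counts (no continuity
    correction).  Site statistics use every qualifying CpG inside the
    segment span.  ``diff`` is sample A minus sample B.
    """
    merged = calls_a.merge(
        calls_b, on=["scaffold", "pos", "strand"], suffixes=("_a", "_b")
    )
    cov_a = merged["c_count_a"] + merged["t_count_a"]
    cov_b = merged["c_count_b"] + merged["t_count_b"]
    merged = merged[(cov_a > min_reads) & (cov_b > min_reads)]
    if merged.empty:
        return _empty_dmrs()
    merged = merged.sort_values(["scaffold", "pos"]).reset_index(drop=True)
    merged["level_a"] = merged["c_count_a"] / (merged["c_count_a"] + merged["t_count_a"])
    merged["level_b"] = merged["c_count_b"] / (merged["c_count_b"] + merged["t_count_b"])
    merged["site_diff"] = merged["level_a"] - merged["level_b"]

    rows = []
    for scaffold, d in merged.groupby("scaffold"):
        seeds = d[np.abs(d["site_diff"]) >= min_diff]
        if seeds.empty:
            continue
        pos = seeds["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) >= max_gap)
        for chunk in np.split(np.arange(len(pos)), breaks + 1):
            start = int(pos[chunk[0]])
            end = int(pos[chunk[-1]]) + 1
            if end - start <= min_len:
                continue
            span = d[(d["pos"] >= start) & (d["pos"] < end)]
            n_meth_a = int((span["c_count_a"] >= 1).sum())
            n_meth_b = int((span["c_count_b"] >= 1).sum())
            if max(n_meth_a, n_meth_b) <= min_meth_sites:
                continue
            meth_a = float(span["level_a"].mean())
            meth_b = float(span["level_b"].mean())
            if abs(meth_a - meth_b) < min_diff:
                continue
            p = _chi2_p(
                int(span["c_count_a"].sum()),
                int(span["t_count_a"].sum()),
                int(span["c_count_b"].sum()),
                int(span["t_count_b"].sum()),
            )
            if p > alpha:
                continue
            rows.append(
                {
                    "scaffold": scaffold,
                    "start": start,
                    "end": end,
                    "length": end - start,
                    "n_sites": len(span),
                    "meth_A": meth_a,
                    "meth_B": meth_b,
                    "diff": meth_a - meth_b,
                    "chi2_p": p,
                }
            )
    return pd.DataFrame(rows) if rows else _empty_dmrs()


def _empty_dmrs() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["scaffold", "start", "end", "length", "n_sites", "meth_A", "meth_B", "diff", "chi2_p"]
    )


def audit_dmrs(
    dmrs: pd.DataFrame,
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    min_meth_sites: int = 5,
    min_reads: int = 10,
    min_len: int = 40,
    max_gap: int = 200,
    min_diff: float = 0.5,
    alpha: float = 0.05,
) -> list[str]:
    """Independently re-check every reported DMR against all criteria.

    Returns a list of human-readable violations (empty when clean).
    """
    merged = calls_a.merge(calls_b, on=["scaffold", "pos", "strand"], suffixes=("_a", "_b"))
    cov_a = merged["c_count_a"] + merged["t_count_a"]
    cov_b = merged["c_count_b"] + merged["t_count_b"]
    merged = merged[(cov_a > min_reads) & (cov_b > min_reads)]
    violations = []
    for seg in dmrs.itertuples():
        tag = f"{seg.scaffold}:{seg.start}-{seg.end}"
        if seg.length != seg.end - seg.start:
            violations.append(f"{tag}: length != end - start")
        if seg.length <= min_len:
            violations.append(f"{tag}: length {seg.length} <= {min_len}")
        span = merged[
            (merged["scaffold"] == seg.scaffold)
            & (merged["pos"] >= seg.start)
            & (merged["pos"] < seg.end)
        ].sort_values("pos")
        if span.empty:
            violations.append(f"{tag}: no qualifying sites in span")
            continue
        la = span["c_count_a"] / (span["c_count_a"] + span["t_count_a"])
        lb = span["c_count_b"] / (span["c_count_b"] + span["t_count_b"])
        seed_pos = span["pos"].to_numpy()[np.abs(la.to_numpy() - lb.to_numpy()) >= min_diff]
        if len(seed_pos) and np.any(np.diff(seed_pos) >= max_gap):
            violations.append(f"{tag}: member-site gap >= {max_gap}")
        n_meth = max(int((span["c_count_a"] >= 1).sum()), int((span["c_count_b"] >= 1).sum()))
        if n_meth <= min_meth_sites:
            violations.append(f"{tag}: methylated sites {n_meth} <= {min_meth_sites}")
        if abs(la.mean() - lb.mean()) < min_diff:
            violations.append(f"{tag}: mean difference below {min_diff}")
        p = _chi2_p(
            int(span["c_count_a"].sum()),
            int(span["t_count_a"].sum()),
            int(span["c_count_b"].sum()),
            int(span["t_count_b"].sum()),
        )
        if p > alpha:
            violations.append(f"{tag}: chi2 P {p:.3g} > {alpha}")
    return violations


def dmr_gene_overlap(dmrs: pd.DataFrame, genes: pd.DataFrame, flank: int = 2000) -> pd.DataFrame:
    """Link DMRs to genes they overlap within gene body +/- ``flank``.

    The link is labelled upstream / gene_body / downstream by the
    position of the DMR midpoint relative to the stranded gene.
    """
    rows = []
    for g in genes.itertuples():
        hits = dmrs[
            (dmrs["scaffold"] == g.scaffold)
            & (dmrs["end"] > g.start - flank)
            & (dmrs["start"] < g.end + flank)
        ]
        for seg in hits.itertuples():
            mid = (seg.start + seg.end) // 2
            if g.start <= mid < g.end:
                region = "gene_body"
            elif mid < g.start:
                region = "upstream" if g.strand == "+" else "downstream"
            else:
                region = "downstream" if g.strand == "+" else "upstream"
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "scaffold": seg.scaffold,
                    "start": seg.start,
                    "end": seg.end,
                    "region": region,
                    "meth_A": seg.meth_A,
                    "meth_B": seg.meth_B,
                    "diff": seg.diff,
                    "chi2_p": seg.chi2_p,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "scaffold", "start", "end", "region", "meth_A", "meth_B", "diff", "chi2_p"],
    )


def call_allele_dmrs(
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 200,
    step: int = 100,
    min_informative: int = 5,
    min_reads: int = 5,
    low_pct: float = 40.0,
    high_pct: float = 70.0,
    flank: int = 2000,
) -> pd.DataFrame:
    """Allele-specific DMRs around genes from parent-labelled CpG calls.

    ``calls`` must carry a ``parent`` column (maternal/paternal).  For
    each gene, 200-bp windows stepped by 100 bp slide over the gene body
    +/- 2 kb; a window qualifies when each allele has more than
    ``min_reads`` reads and at least ``min_informative`` informative
    methylcytosines, and one allele's percent methylation is below
    ``low_pct`` while the other's is above ``high_pct``.  Overlapping
    qualifying windows merge into maximal regions, reported in both
    scaffold-absolute and gene-relative (TSS = 0, upstream negative)
    coordinates.
    """
    by_parent = {
        p: d.sort_values("pos").reset_index(drop=True)
        for p, d in calls.groupby("parent")
        if p in ("maternal", "paternal")
    }
    if set(by_parent) != {"maternal", "paternal"}:
        logger.info("no parent-labelled calls for at least one allele; no allele DMRs")
        return _empty_allele_dmrs()
    arrays = {
        p: {
            s: (
                d["pos"].to_numpy(),
                d["c_count"].to_numpy(),
                d["t_count"].to_numpy(),
            )
            for s, d in df.groupby("scaffold")
        }
        for p, df in by_parent.items()
    }
    rows = []
    for g in genes.itertuples():
        span_lo, span_hi = g.start - flank, g.end + flank
        qualifying = []
        for wstart in range(span_lo, span_hi - window + step, step):
            stats_by_parent = {}
            ok = True
            for p in ("maternal", "paternal"):
                entry = arrays[p].get(g.scaffold)
                if entry is None:
                    ok = False
                    break
                pos, c, t = entry
                lo = np.searchsorted(pos, wstart)
                hi = np.searchsorted(pos, wstart + window)
                n_sites = hi - lo
                reads = int(c[lo:hi].sum() + t[lo:hi].sum())
                if n_sites < min_informative or reads <= min_reads:
                    ok = False
                    break
                level = 100 * c[lo:hi].sum() / reads
                stats_by_parent[p] = (n_sites, level)
            if not ok:
                continue
            lv = [stats_by_parent["maternal"][1], stats_by_parent["paternal"][1]]
            if min(lv) < low_pct and max(lv) > high_pct:
                qualifying.append(wstart)
        if not qualifying:
            continue
        qualifying = np.array(qualifying)
        breaks = np.flatnonzero(np.diff(qualifying) > window)
        for chunk in np.split(np.arange(len(qualifying)), breaks + 1):
            start = int(qualifying[chunk[0]])
            end = int(qualifying[chunk[-1]]) + window
            region_rows = {}
            for p in ("maternal", "paternal"):
                pos, c, t = arrays[p][g.scaffold]
                lo = np.searchsorted(pos, start)
                hi = np.searchsorted(pos, end)
                cc, tt = int(c[lo:hi].sum()), int(t[lo:hi].sum())
                region_rows[p] = (hi - lo, 100 * cc / (cc + tt))
            mid = (start + end) // 2
            if g.start <= mid < g.end:
                region = "gene_body"
            elif mid < g.start:
                region = "upstream" if g.strand == "+" else "downstream"
            else:
                region = "downstream" if g.strand == "+" else "upstream"
            if g.strand == "+":
                rel_start, rel_end = start - g.start, end - g.start
            else:
                rel_start, rel_end = g.end - end, g.end - start
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "region": region,
                    "start": start,
                    "end": end,
                    "rel_start": rel_start,
                    "rel_end": rel_end,
                    "length": end - start,
                    "meth_maternal": region_rows["maternal"][1],
                    "meth_paternal": region_rows["paternal"][1],
                    "n_informative": min(region_rows["maternal"][0], region_rows["paternal"][0]),
                }
            )
    return pd.DataFrame(rows) if rows else _empty_allele_dmrs()


def _empty_allele_dmrs() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "gene_id", "region", "start", "end", "rel_start", "rel_end",
            "length", "meth_maternal", "meth_paternal", "n_informative",
        ]
    )


def hypomethylation_association(
    imprinted: set[str],
    universe: set[str],
    hypomethylated: set[str],
):
    """Fisher test for imprinting vs endosperm hypomethylation.

    2x2 table over ``universe`` (genes informative in both crosses):
    imprinted or not x carrying an endosperm-hypomethylated DMR within
    gene body +/- 2 kb or not.  Returns (p_two_sided, table).
    """
    from .association import fisher_exact_2x2

    imp = imprinted & universe
    hypo = hypomethylated & universe
    a = len(imp & hypo)
    b = len(imp - hypo)
    c = len(hypo - imp)
    d = len(universe) - a - b - c
    table = [[a, b], [c, d]]
    p, _ = fisher_exact_2x2(table)
    return p, table


def write_cytosine_bedgraph(path, calls: pd.DataFrame) -> None:
    """bedGraph-like TSV: scaffold, pos0, pos0+1, level, c, t, strand."""
    out = pd.DataFrame(
        {
            "scaffold": calls["scaffold"],
            "start": calls["pos"],
            "end": calls["pos"] + 1,
            "level": calls["level"],
            "c_count": calls["c_count"],
            "t_count": calls["t_count"],
            "strand": calls["strand"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_allele_dmrs(path, dmrs: pd.DataFrame) -> None:
    """Allele-DMR TSV with length = end - start by construction."""
    cols = [
        "gene_id", "region", "start", "end", "rel_start", "rel_end",
        "length", "meth_paternal", "meth_maternal", "n_informative",
    ]
    dmrs[[c for c in cols if c in dmrs.columns]].to_csv(path, sep="\t", index=False)
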