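"""Synthetic reciprocal-cross endosperm data with known truth.

Emulates the experimental design this package analyses: two inbred
parental lines whose transcribed regions differ at biallelic SNPs,
reciprocal F1 endosperm transcriptomes in which every read descends from
a maternal or paternal genome copy (2m:1p dosage for biallelic genes),
and whole-genome bisulfite reads from endosperm and embryo with
region-level CpG methylation truth, including endosperm hypomethylation
and allele-differential methylation at a subset of maternally expressed
genes.

All randomness flows from ``SimConfig.seed`` through named substreams,
so identical configurations give byte-identical outputs regardless of
which generators are invoked or in what order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from ._seqmatch import revcomp

CROSSES = ("AxB", "BxA")  # AxB: parent1 is the mother; BxA: parent2 is the mother
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# substream tags for seed derivation
_STREAMS = {
    "genome": 0,
    "truth": 1,
    "reads_p1": 10,
    "reads_p2": 11,
    "endo_AxB": 20,
    "endo_BxA": 21,
    "bs_endosperm": 30,
    "bs_embryo": 31,
}


@dataclass(frozen=True)
class TeFamily:
    """A transposable-element family to scatter over the genome.

    ``meg_multiplier`` > 1 enriches extra copies in the 4-kb flanks of
    maternally expressed genes, the association the pipeline tests for.
    """

    name: str
    count: int
    length: int = 300
    meg_multiplier: float = 1.0


def _default_te_families() -> tuple[TeFamily, ...]:
    return (
        TeFamily("LTR/Gypsy", count=12, meg_multiplier=4.0),
        TeFamily("DNA/MuDR", count=8),
        TeFamily("CACTA", count=5),
    )


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_scaffolds: int = 2
    scaffold_len: int = 100_000
    snp_rate: float = 0.002
    n_genes: int = 40
    gene_len: int = 1_000
    frac_meg: float = 0.15
    frac_peg: float = 0.05
    frac_accession_biased: float = 0.05
    accession_bias_toward_p1: float = 0.85
    imprint_strength: float = 0.97
    accession_bias_strength: float = 0.97
    read_len: int = 90
    coverage_rna: float = 50.0
    coverage_bs: float = 30.0
    meth_endosperm: float = 0.7
    meth_embryo: float = 0.8
    meth_hypo: float = 0.05
    frac_meg_hypo: float = 0.5
    frac_other_hypo: float = 0.05
    frac_meg_allele_dmr: float = 0.3
    allele_meth_maternal: float = 0.05
    allele_meth_paternal: float = 0.9
    te_families: tuple[TeFamily, ...] = field(default_factory=_default_te_families)
    bisulfite_conversion_rate: float = 0.995
    error_rate: float = 0.0
    maternal_contamination: float = 0.0
    ensure_gene_snp: bool = True

    def validate(self) -> None:
        if self.frac_meg + self.frac_peg + self.frac_accession_biased > 1 + 1e-9:
            raise ValueError("class fractions must sum to at most 1")
        if not 0.5 < self.imprint_strength <= 1:
            raise ValueError("imprint_strength must be in (0.5, 1]")
        if self.scaffold_len < self.read_len:
            raise ValueError("scaffold_len must be at least read_len")
        if self.gene_len < self.read_len:
            raise ValueError("gene_len must be at least read_len")
        for p in (
            self.snp_rate,
            self.frac_meg,
            self.frac_peg,
            self.frac_accession_biased,
            self.meth_endosperm,
            self.meth_embryo,
            self.meth_hypo,
            self.allele_meth_maternal,
            self.allele_meth_paternal,
            self.bisulfite_conversion_rate,
            self.error_rate,
            self.maternal_contamination,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[stream], self.seed])


@dataclass
class TruthTable:
    """Ground truth for one simulated dataset.

    genes: gene_id, scaffold, start, end, strand, class_label,
           biased_line, hypo_endosperm, allele_dmr
    snps:  scaffold, pos (0-based), allele_p1, allele_p2, gene_id ('' if intergenic)
    tes:   scaffold, start, end, family
    meth_regions: scaffold, start, end, endo_mat, endo_pat, embryo
    haplotypes: {'p1': {scaffold: seq}, 'p2': ...}
    """

    config: SimConfig
    haplotypes: dict[str, dict[str, str]]
    snps: pd.DataFrame
    genes: pd.DataFrame
    tes: pd.DataFrame
    meth_regions: pd.DataFrame

    def maternal_line(self, cross: str) -> str:
        if cross == "AxB":
            return "p1"
        if cross == "BxA":
            return "p2"
        raise ValueError(f"unknown cross direction: {cross!r}")


def _random_genome(rng: np.random.Generator, config: SimConfig) -> dict[str, np.ndarray]:
    return {
        f"scaffold_{i + 1}": _BASES[rng.integers(0, 4, size=config.scaffold_len)]
        for i in range(config.n_scaffolds)
    }


def _place_genes(config: SimConfig) -> pd.DataFrame:
    """Genes laid out evenly, non-overlapping, round-robin over scaffolds."""
    per = [config.n_genes // config.n_scaffolds] * config.n_scaffolds
    for i in range(config.n_genes % config.n_scaffolds):
        per[i] += 1
    rows = []
    gid = 0
    for s, n_here in enumerate(per):
        if n_here == 0:
            continue
        if n_here * config.gene_len > config.scaffold_len:
            raise ValueError("genes do not fit on scaffold; increase scaffold_len")
        gap = (config.scaffold_len - n_here * config.gene_len) / (n_here + 1)
        for j in range(n_here):
            start = int(round(gap * (j + 1) + config.gene_len * j))
            rows.append((f"g{gid:04d}", f"scaffold_{s + 1}", start, start + config.gene_len))
            gid += 1
    return pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end"])


def gen_parental_genomes(config: SimConfig):
    """Two haplotypes identical except at randomly placed biallelic SNPs.

    SNPs are kept at least ``read_len`` bp from scaffold edges so every
    SNP supports a full +/-90 bp allele window.  Returns
    ``(haplotypes, snps)`` where haplotypes maps 'p1'/'p2' to
    {scaffold: sequence}.
    """
    config.validate()
    rng = config.rng("genome")
    hap1 = _random_genome(rng, config)
    genes = _place_genes(config)
    snp_rows = []
    margin = config.read_len
    for scaffold, seq in hap1.items():
        lo, hi = margin, len(seq) - margin
        if hi <= lo:
            continue
        hits = lo + np.flatnonzero(rng.random(hi - lo) < config.snp_rate)
        for pos in hits:
            snp_rows.append((scaffold, int(pos)))
    if config.ensure_gene_snp:
        have = {(s, p) for s, p in snp_rows}
        covered = set()
        for s, p in snp_rows:
            covered.add((s, p))
        for row in genes.itertuples():
            in_gene = [p for (s, p) in snp_rows if s == row.scaffold and row.start <= p < row.end]
            if not in_gene:
                lo = max(row.start, margin)
                hi = min(row.end, config.scaffold_len - margin)
                pos = int(rng.integers(lo, hi))
                while (row.scaffold, pos) in have:
                    pos = int(rng.integers(lo, hi))
                snp_rows.append((row.scaffold, pos))
                have.add((row.scaffold, pos))
    snp_rows.sort()
    hap2 = {s: seq.copy() for s, seq in hap1.items()}
    recs = []
    for scaffold, pos in snp_rows:
        ref = hap1[scaffold][pos]
        alt = ref
        while alt == ref:
            alt = _BASES[rng.integers(0, 4)]
        hap2[scaffold][pos] = alt
        recs.append((scaffold, pos, chr(ref), chr(alt)))
    snps = pd.DataFrame(recs, columns=["scaffold", "pos", "allele_p1", "allele_p2"])
    haps = {
        "p1": {s: seq.tobytes().decode() for s, seq in hap1.items()},
        "p2": {s: seq.tobytes().decode() for s, seq in hap2.items()},
    }
    return haps, snps


def make_truth(config: SimConfig) -> TruthTable:
    """Full ground truth: genomes, SNPs, gene classes, TEs, methylation."""
    haps, snps = gen_parental_genomes(config)
    rng = config.rng("truth")
    genes = _place_genes(config)
    n = len(genes)
    genes["strand"] = np.where(rng.random(n) < 0.5, "+", "-")

    n_meg = int(round(config.frac_meg * n))
    n_peg = int(round(config.frac_peg * n))
    n_acc = int(round(config.frac_accession_biased * n))
    labels = np.array(
        ["MEG"] * n_meg + ["PEG"] * n_peg + ["accession_biased"] * n_acc
        + ["biallelic"] * (n - n_meg - n_peg - n_acc)
    )
    rng.shuffle(labels)
    genes["class_label"] = labels
    biased_line = np.where(rng.random(n) < config.accession_bias_toward_p1, "p1", "p2")
    genes["biased_line"] = np.where(labels == "accession_biased", biased_line, "")

    is_meg = labels == "MEG"
    hypo = np.zeros(n, dtype=bool)
    hypo[is_meg] = rng.random(is_meg.sum()) < config.frac_meg_hypo
    other = ~is_meg & (labels != "PEG")
    hypo[other] = rng.random(other.sum()) < config.frac_other_hypo
    genes["hypo_endosperm"] = hypo
    adm = np.zeros(n, dtype=bool)
    adm[is_meg] = rng.random(is_meg.sum()) < config.frac_meg_allele_dmr
    genes["allele_dmr"] = adm

    # map SNPs to the gene body they fall in (genes are non-overlapping)
    gene_of = []
    by_scaffold = {s: df for s, df in genes.groupby("scaffold")}
    for row in snps.itertuples():
        g = ""
        df = by_scaffold.get(row.scaffold)
        if df is not None:
            hit = df[(df.start <= row.pos) & (row.pos < df.end)]
            if len(hit):
                g = hit.gene_id.iloc[0]
        gene_of.append(g)
    snps = snps.assign(gene_id=gene_of)

    tes = _place_tes(config, genes, rng)
    meth = _meth_regions(config, genes)
    return TruthTable(config, haps, snps, genes, tes, meth)


def _place_tes(config: SimConfig, genes: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    total_len = config.n_scaffolds * config.scaffold_len
    scaffolds = [f"scaffold_{i + 1}" for i in range(config.n_scaffolds)]
    rows = []
    megs = genes[genes.class_label == "MEG"]
    for fam in config.te_families:
        for _ in range(fam.count):
            s = scaffolds[rng.integers(0, len(scaffolds))]
            start = int(rng.integers(0, config.scaffold_len - fam.length))
            rows.append((s, start, start + fam.length, fam.name))
        if fam.meg_multiplier > 1 and len(megs):
            window = config.gene_len + 8_000
            lam = fam.count * window / total_len * (fam.meg_multiplier - 1)
            for g in megs.itertuples():
                for _ in range(rng.poisson(lam)):
                    lo = max(0, g.start - 4_000)
                    hi = min(config.scaffold_len - fam.length, g.end + 4_000 - fam.length)
                    if hi <= lo:
                        continue
                    start = int(rng.integers(lo, hi))
                    rows.append((g.scaffold, start, start + fam.length, fam.name))
    tes = pd.DataFrame(rows, columns=["scaffold", "start", "end", "family"])
    return tes.sort_values(["scaffold", "start"], ignore_index=True)


def _meth_regions(config: SimConfig, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-gene-body methylation truth; everything else takes the background."""
    rows = []
    for g in genes.itertuples():
        if g.allele_dmr:
            endo_mat, endo_pat = config.allele_meth_maternal, config.allele_meth_paternal
        elif g.hypo_endosperm:
            endo_mat = endo_pat = config.meth_hypo
        else:
            endo_mat = endo_pat = config.meth_endosperm
        rows.append((g.scaffold, g.start, g.end, endo_mat, endo_pat, config.meth_embryo))
    return pd.DataFrame(
        rows, columns=["scaffold", "start", "end", "endo_mat", "endo_pat", "embryo"]
    )


def methylation_levels(truth: TruthTable, sample: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-position true CpG methylation level arrays (maternal, paternal)."""
    config = truth.config
    out = {}
    for i in range(config.n_scaffolds):
        s = f"scaffold_{i + 1}"
        if sample == "endosperm":
            mat = np.full(config.scaffold_len, config.meth_endosperm)
            pat = mat.copy()
        elif sample == "embryo":
            mat = np.full(config.scaffold_len, config.meth_embryo)
            pat = mat.copy()
        else:
            raise ValueError(f"unknown sample: {sample!r}")
        out[s] = (mat, pat)
    for r in truth.meth_regions.itertuples():
        mat, pat = out[r.scaffold]
        if sample == "endosperm":
            mat[r.start : r.end] = r.endo_mat
            pat[r.start : r.end] = r.endo_pat
        else:
            mat[r.start : r.end] = r.embryo
            pat[r.start : r.end] = r.embryo
    return out


def _maternal_prob(class_label: str, biased_line: str, cross: str, config: SimConfig) -> float:
    if class_label == "MEG":
        return config.imprint_strength
    if class_label == "PEG":
        return 1 - config.imprint_strength
    if class_label == "accession_biased":
        mother = "p1" if cross == "AxB" else "p2"
        return (
            config.accession_bias_strength
            if biased_line == mother
            else 1 - config.accession_bias_strength
        )
    return 2 / 3


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hits:
        b = arr[i]
        while arr[i] == b:
            arr[i] = _BASES[rng.integers(0, 4)]
    return arr.tobytes().decode()


def gen_endosperm_reads(config: SimConfig, cross: str, truth: TruthTable):
    """Reciprocal-cross endosperm RNA reads with a per-read origin log.

    Per informative SNP and cross, ``Poisson(coverage_rna)`` reads are
    drawn covering the SNP; each read's parent-of-origin is maternal with
    probability 2/3 for biallelic genes, ``imprint_strength`` for MEGs
    (symmetric for PEGs), and line-directed for accession-biased genes.
    Optional maternal contamination adds purely maternal reads.

    Returns ``(reads, origin_log)`` where reads are (id, sequence) pairs
    and the origin log records gene, SNP, parent-of-origin and line.
    """
    if cross not in CROSSES:
        raise ValueError(f"unknown cross direction: {cross!r}")
    config.validate()
    rng = config.rng(f"endo_{cross}")
    mother = truth.maternal_line(cross)
    father = "p2" if mother == "p1" else "p1"
    gene_info = truth.genes.set_index("gene_id")
    reads, log = [], []
    counter = 0
    for snp in truth.snps.itertuples():
        if not snp.gene_id:
            continue
        g = gene_info.loc[snp.gene_id]
        p_mat = _maternal_prob(g.class_label, g.biased_line, cross, config)
        n_reads = rng.poisson(config.coverage_rna)
        n_cont = (
            rng.poisson(config.coverage_rna * config.maternal_contamination)
            if config.maternal_contamination > 0
            else 0
        )
        lo = max(g.start, snp.pos - config.read_len + 1)
        hi = min(snp.pos, g.end - config.read_len)
        if hi < lo:
            continue
        for j in range(n_reads + n_cont):
            contaminant = j >= n_reads
            maternal = True if contaminant else bool(rng.random() < p_mat)
            line = mother if maternal else father
            start = int(rng.integers(lo, hi + 1))
            seq = truth.haplotypes[line][snp.scaffold][start : start + config.read_len]
            seq = _mutate(seq, rng, config.error_rate)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            rid = f"{cross}:{counter:07d}"
            counter += 1
            reads.append((rid, seq))
            log.append(
                (
                    rid,
                    snp.gene_id,
                    snp.scaffold,
                    snp.pos,
                    "maternal" if maternal else "paternal",
                    line,
                    contaminant,
                )
            )
    origin = pd.DataFrame(
        log,
        columns=["read_id", "gene_id", "scaffold", "snp_pos", "parent", "line", "contaminant"],
    )
    return reads, origin


def gen_parental_reads(config: SimConfig, parent: str, truth: TruthTable, utr_flank: int | None = None):
    """RNA reads over transcribed regions from one parental line.

    Reads cover the gene body plus ``utr_flank`` bp on each side
    (default one read length), emulating transcripts whose UTRs extend
    past the annotated body, so SNPs near gene edges still receive
    read-interior coverage.
    """
    config.validate()
    if parent not in ("p1", "p2"):
        raise ValueError(f"unknown parent: {parent!r}")
    if utr_flank is None:
        utr_flank = config.read_len
    rng = config.rng(f"reads_{parent}")
    reads = []
    counter = 0
    for g in truth.genes.itertuples():
        lo = max(0, g.start - utr_flank)
        hi = min(config.scaffold_len, g.end + utr_flank)
        span = hi - lo - config.read_len
        if span < 0:
            continue
        n = rng.poisson(config.coverage_rna * (hi - lo) / config.read_len)
        for _ in range(n):
            start = lo + int(rng.integers(0, span + 1))
            seq = truth.haplotypes[parent][g.scaffold][start : start + config.read_len]
            seq = _mutate(seq, rng, config.error_rate)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append((f"{parent}:{counter:07d}", seq))
            counter += 1
    return reads


def gen_bisulfite_reads(config: SimConfig, sample: str, truth: TruthTable):
    """Whole-genome bisulfite reads for endosperm or embryo.

    Reads are drawn from the maternal haplotype with probability 2/3 in
    endosperm (triploid dosage) and 1/2 in embryo.  On the read's
    template strand every CpG-context cytosine is emitted as C with
    probability ``level + (1 - level) * (1 - conversion_rate)`` and as T
    otherwise; non-CpG cytosines are unmethylated and convert at the
    full conversion rate.

    Returns ``(reads, origin_log)``.
    """
    config.validate()
    if sample not in ("endosperm", "embryo"):
        raise ValueError(f"unknown sample: {sample!r}")
    rng = config.rng(f"bs_{sample}")
    p_mat = 2 / 3 if sample == "endosperm" else 1 / 2
    levels = methylation_levels(truth, sample)
    conv = config.bisulfite_conversion_rate
    L = config.read_len
    # bisulfite data comes from the AxB cross: maternal = p1
    line_of = {"maternal": "p1", "paternal": "p2"}
    hap_u8 = {
        p: {s: np.frombuffer(seq.encode(), dtype=np.uint8) for s, seq in haps.items()}
        for p, haps in truth.haplotypes.items()
    }
    C, G, T, A = (ord(x) for x in "CGTA")
    cpg_mask = {}
    for p, haps in hap_u8.items():
        cpg_mask[p] = {}
        for s, arr in haps.items():
            watson = np.zeros(len(arr), dtype=bool)
            watson[:-1] = (arr[:-1] == C) & (arr[1:] == G)
            crick = np.zeros(len(arr), dtype=bool)
            crick[1:] = (arr[1:] == G) & (arr[:-1] == C)
            cpg_mask[p][s] = (watson, crick)
    reads, log = [], []
    counter = 0
    for s in sorted(levels):
        mat_lvl, pat_lvl = levels[s]
        n = rng.poisson(config.coverage_bs * config.scaffold_len / L)
        starts = rng.integers(0, config.scaffold_len - L + 1, size=n)
        mats = rng.random(n) < p_mat
        strands = rng.random(n) < 0.5
        for start, is_mat, plus in zip(starts, mats, strands):
            parent = "maternal" if is_mat else "paternal"
            line = line_of[parent]
            arr = hap_u8[line][s][start : start + L].copy()
            lvl = (mat_lvl if is_mat else pat_lvl)[start : start + L]
            watson_cpg, crick_cpg = cpg_mask[line][s]
            if plus:
                cs = np.flatnonzero(arr == C)
                in_cpg = watson_cpg[start : start + L][cs]
            else:
                cs = np.flatnonzero(arr == G)
                in_cpg = crick_cpg[start : start + L][cs]
            if len(cs):
                meth = np.zeros(len(cs), dtype=bool)
                if in_cpg.any():
                    meth[in_cpg] = rng.random(int(in_cpg.sum())) < lvl[cs[in_cpg]]
                converted = ~meth & (rng.random(len(cs)) < conv)
                arr[cs[converted]] = T if plus else A
            seq = arr.tobytes().decode()
            if not plus:
                seq = revcomp(seq)
            rid = f"bs_{sample}:{counter:07d}"
            counter += 1
            reads.append((rid, seq))
            log.append((rid, s, int(start), "+" if plus else "-", parent, line))
    origin = pd.DataFrame(
        log, columns=["read_id", "scaffold", "start", "strand", "parent", "line"]
    )
    return reads, origin


def simulate_locus_counts(
    seed: int,
    n_null: int,
    n_imprinted: int,
    coverage: int = 50,
    null_maternal: float = 2 / 3,
    imprinted_maternal: float = 0.95,
) -> pd.DataFrame:
    """Direct per-locus allele counts for calibration studies.

    Skips read simulation: maternal counts in each cross are independent
    ``Binomial(coverage, f)`` draws with f = ``null_maternal`` for null
    loci and ``imprinted_maternal`` for maternally imprinted loci.
    Returns a count table with a ``true_imprinted`` column.
    """
    rng = np.random.default_rng(seed)
    n = n_null + n_imprinted
    frac = np.r_[np.full(n_null, null_maternal), np.full(n_imprinted, imprinted_maternal)]
    mat_axb = rng.binomial(coverage, frac)
    mat_bxa = rng.binomial(coverage, frac)
    return pd.DataFrame(
        {
            "scaffold": "sim",
            "pos": np.arange(n),
            "mat_AxB": mat_axb,
            "pat_AxB": coverage - mat_axb,
            "mat_BxA": mat_bxa,
            "pat_BxA": coverage - mat_bxa,
            "n_AxB": coverage,
            "n_BxA": coverage,
            "true_imprinted": np.r_[np.zeros(n_null, bool), np.ones(n_imprinted, bool)],
        }
    )
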