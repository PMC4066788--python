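"""End-to-end orchestration: simulate -> SNPs -> allele counts ->
imprinting -> methylome -> feature association.

Every stage reads its parameters from one block of
:class:`PipelineConfig`, whose defaults are the study settings the
package implements (base quality > 20, coverage >= 5, +/-90 bp allele
windows, <= 4 mismatches, 2m:1p null, FDR <= 0.05, >= 90% uniparental
filter, the five DMR criteria, 200-bp allele windows with the 40/70
rule, 4-kb TE flanks).  Reruns with an identical config and seed are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alleles, association, imprinting, io, methylation, snps
from .simulate import CROSSES, SimConfig, TruthTable, gen_bisulfite_reads, gen_endosperm_reads, gen_parental_reads, make_truth

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str | Path = "imprintseq_run"
    seed: int = 0
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)

    # file inputs (used when simulate is False)
    genome_fasta: str | None = None
    reads_p1: str | None = None
    reads_p2: str | None = None
    reads_axb: str | None = None
    reads_bxa: str | None = None
    bs_endosperm: str | None = None
    bs_embryo: str | None = None
    genes_bed: str | None = None
    tes_bed: str | None = None

    # SNP calling
    snp_min_quality: int = 20
    snp_min_coverage: int = 5
    snp_end_margin: int = 5
    snp_max_minor_fraction: float = 0.1
    snp_max_mismatch: int = 4

    # allele counting
    window_flank: int = 90
    assign_max_mismatch: int = 4
    min_reads_hq: int = 10

    # imprinting test
    fdr_threshold: float = 0.05
    uniparental_fraction: float = 0.90
    null_maternal: float = 2 / 3
    bias_fraction: float = 0.90

    # methylome
    bs_max_mismatch: int = 2
    dmr_min_meth_sites: int = 5
    dmr_min_reads: int = 10
    dmr_min_len: int = 40
    dmr_max_gap: int = 200
    dmr_min_diff: float = 0.5
    dmr_alpha: float = 0.05
    allele_window: int = 200
    allele_step: int = 100
    allele_min_informative: int = 5
    allele_min_reads: int = 5
    allele_low_pct: float = 40.0
    allele_high_pct: float = 70.0
    gene_flank: int = 2000

    # association
    te_flank: int = 4000
    cluster_n_perm: int = 1000

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Flat key = value text config; keys 'sim.*' set SimConfig fields."""
        cfg = cls()
        sim_kwargs = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key.startswith("sim."):
                sim_kwargs[key[4:]] = value
                continue
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key: {key}")
            current = getattr(cfg, key)
            setattr(cfg, key, _coerce(value, current))
        if sim_kwargs:
            base = dataclasses.asdict(cfg.sim)
            base.pop("te_families", None)
            for k, v in sim_kwargs.items():
                if k not in base:
                    raise ValueError(f"unknown sim config key: {k}")
                base[k] = _coerce(v, base[k])
            cfg.sim = SimConfig(**base)
        cfg.sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        return cfg


def _coerce(value: str, current):
    if isinstance(current, bool):
        return value.lower() in ("1", "true", "yes")
    if isinstance(current, int) and not isinstance(current, bool):
        return int(value)
    if isinstance(current, float):
        return float(value)
    if current is None or isinstance(current, (str, Path)):
        return value
    raise ValueError(f"cannot set config value {value!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the summary dict.

    Writes stage outputs and ``summary.json`` under ``config.outdir``.
    Methylome stages are skipped with a notice when bisulfite input is
    absent (file mode without bisulfite read paths).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": []}

    truth = None
    if config.simulate:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        truth = make_truth(sim)
        genome = truth.haplotypes["p1"]
        genes = truth.genes
        tes = truth.tes
        io.write_fasta(out / "genome_p1.fasta", truth.haplotypes["p1"])
        io.write_fasta(out / "genome_p2.fasta", truth.haplotypes["p2"])
        io.write_bed(out / "genes.bed", genes.assign(name=genes.gene_id))
        io.write_bed(out / "tes.bed", tes.assign(name=tes.family))
        io.write_tsv(out / "truth_genes.tsv", genes)
        io.write_tsv(out / "truth_snps.tsv", truth.snps)
        reads_parent = {p: gen_parental_reads(sim, p, truth) for p in ("p1", "p2")}
        endo_reads = {c: gen_endosperm_reads(sim, c, truth) for c in CROSSES}
        for c, (reads, origin) in endo_reads.items():
            io.write_fastq(out / f"endosperm_{c}.fastq", reads)
            io.write_tsv(out / f"origin_{c}.tsv", origin)
        bs_reads = {s: gen_bisulfite_reads(sim, s, truth) for s in ("endosperm", "embryo")}
        for s, (reads, origin) in bs_reads.items():
            io.write_fastq(out / f"bisulfite_{s}.fastq", reads)
        summary["stages"].append("simulate")
    else:
        if not (config.genome_fasta and config.reads_p1 and config.reads_p2):
            raise ValueError("file mode requires genome_fasta, reads_p1 and reads_p2")
        genome = io.read_fasta(config.genome_fasta)
        genes = _genes_from_bed(config.genes_bed) if config.genes_bed else None
        tes = _tes_from_bed(config.tes_bed) if config.tes_bed else None
        reads_parent = {
            "p1": io.read_fastq(config.reads_p1),
            "p2": io.read_fastq(config.reads_p2),
        }
        endo_reads = {}
        if config.reads_axb and config.reads_bxa:
            endo_reads = {
                "AxB": (io.read_fastq(config.reads_axb), None),
                "BxA": (io.read_fastq(config.reads_bxa), None),
            }
        bs_reads = {}
        if config.bs_endosperm and config.bs_embryo:
            bs_reads = {
                "endosperm": (io.read_fastq(config.bs_endosperm), None),
                "embryo": (io.read_fastq(config.bs_embryo), None),
            }

    # --- SNP discovery -------------------------------------------------
    called = snps.snps_from_reads(
        reads_parent,
        genome,
        max_mismatch=config.snp_max_mismatch,
        end_margin_bp=config.snp_end_margin,
        min_quality=config.snp_min_quality,
        min_coverage=config.snp_min_coverage,
        max_minor_fraction=config.snp_max_minor_fraction,
    )
    snps.write_snp_table(out / "snps.tsv", called)
    io.write_snp_vcf(out / "snps.vcf", called)
    summary["n_snps_called"] = int(len(called))
    summary["stages"].append("call_snps")

    # --- allele counting ----------------------------------------------
    counts = None
    if endo_reads:
        windows = alleles.build_windows(genome, called, flank=config.window_flank)
        per_cross = {}
        assign_stats = {}
        for c in CROSSES:
            reads_c = endo_reads[c][0]
            tab, st = alleles.assign_reads(
                reads_c, windows, max_mismatch=config.assign_max_mismatch
            )
            per_cross[c] = tab
            assign_stats[c] = st
        counts = alleles.counts_by_cross(
            per_cross["AxB"], per_cross["BxA"], min_reads=config.min_reads_hq
        )
        alleles.write_count_table(out / "allele_counts.tsv", counts)
        summary["n_windows"] = len(windows)
        summary["assignment"] = assign_stats
        summary["n_loci_joint"] = int(len(counts))
        summary["n_loci_high_quality"] = int(counts["high_quality"].sum())
        summary["stages"].append("count_alleles")

    # --- imprinting test ----------------------------------------------
    gene_calls = intergenic = loci = None
    if counts is not None and len(counts):
        hq = counts[counts["high_quality"]].reset_index(drop=True)
        loci = imprinting.classify_loci(
            hq,
            fdr_threshold=config.fdr_threshold,
            uniparental_fraction=config.uniparental_fraction,
            null_maternal=config.null_maternal,
        )
        loci = imprinting.detect_accession_bias(
            loci,
            bias_fraction=config.bias_fraction,
            fdr_threshold=config.fdr_threshold,
            null_maternal=config.null_maternal,
        )
        imprinting.write_results(out / "imprinting.tsv", loci)
        io.write_tsv(out / "scatter_log2_counts.tsv", imprinting.scatter_export(loci))
        summary["n_meg_loci"] = int((loci["class"] == "MEG").sum())
        summary["n_peg_loci"] = int((loci["class"] == "PEG").sum())
        summary["n_accession_biased_loci"] = int((loci["biased_line"] != "").sum())
        if genes is not None:
            gene_calls, intergenic = imprinting.aggregate_to_genes(loci, genes)
            io.write_tsv(out / "gene_calls.tsv", gene_calls)
            io.write_tsv(out / "intergenic_loci.tsv", intergenic)
            summary["n_meg_genes"] = int((gene_calls["class"] == "MEG").sum())
            summary["n_peg_genes"] = int((gene_calls["class"] == "PEG").sum())
            summary["n_intergenic_loci"] = int(len(intergenic))
        summary["stages"].append("imprinting")

    # --- methylome ------------------------------------------------------
    if bs_reads:
        placements = {
            s: methylation.map_bisulfite_reads(
                reads, genome, max_mismatch=config.bs_max_mismatch
            )
            for s, (reads, _origin) in bs_reads.items()
        }
        calls = {s: methylation.call_cytosines(p, genome) for s, p in placements.items()}
        for s, c in calls.items():
            methylation.write_cytosine_bedgraph(out / f"cpg_{s}.tsv", c)
        dmr_kwargs = dict(
            min_meth_sites=config.dmr_min_meth_sites,
            min_reads=config.dmr_min_reads,
            min_len=config.dmr_min_len,
            max_gap=config.dmr_max_gap,
            min_diff=config.dmr_min_diff,
            alpha=config.dmr_alpha,
        )
        dmrs = methylation.call_dmrs(calls["endosperm"], calls["embryo"], **dmr_kwargs)
        io.write_tsv(out / "dmrs.tsv", dmrs)
        summary["n_dmrs"] = int(len(dmrs))
        if genes is not None:
            profile = methylation.metagene_profile(
                calls["endosperm"], genes, flank=config.gene_flank
            )
            io.write_tsv(out / "metagene_endosperm.tsv", profile)
            profile_em = methylation.metagene_profile(
                calls["embryo"], genes, flank=config.gene_flank
            )
            io.write_tsv(out / "metagene_embryo.tsv", profile_em)
            linked = methylation.dmr_gene_overlap(dmrs, genes, flank=config.gene_flank)
            io.write_tsv(out / "dmr_gene_links.tsv", linked)
            # allele-specific methylation from SNP-labelled endosperm reads
            labels = methylation.assign_parent_of_origin(
                placements["endosperm"], called, maternal_line="p1"
            )
            allele_calls = methylation.call_cytosines(
                placements["endosperm"], genome, parent_labels=labels
            )
            target_genes = genes
            if gene_calls is not None and len(gene_calls):
                imprinted_ids = set(
                    gene_calls.loc[gene_calls["class"].isin(["MEG", "PEG"]), "gene_id"]
                )
                target_genes = genes[genes["gene_id"].isin(imprinted_ids)]
            allele_dmrs = methylation.call_allele_dmrs(
                allele_calls,
                target_genes,
                window=config.allele_window,
                step=config.allele_step,
                min_informative=config.allele_min_informative,
                min_reads=config.allele_min_reads,
                low_pct=config.allele_low_pct,
                high_pct=config.allele_high_pct,
                flank=config.gene_flank,
            )
            methylation.write_allele_dmrs(out / "allele_dmrs.tsv", allele_dmrs)
            summary["n_allele_dmrs"] = int(len(allele_dmrs))
            if gene_calls is not None and counts is not None:
                universe = _informative_gene_ids(counts, genes)
                hypo_genes = set(linked.loc[linked["diff"] < 0, "gene_id"])
                imprinted_ids = set(
                    gene_calls.loc[gene_calls["class"].isin(["MEG", "PEG"]), "gene_id"]
                )
                p, table = methylation.hypomethylation_association(
                    imprinted_ids, universe, hypo_genes
                )
                summary["hypomethylation_fisher_p"] = p
                summary["hypomethylation_table"] = table
        summary["stages"].append("methylome")
    else:
        logger.info("no bisulfite reads provided; methylome stages skipped")
        summary["methylome_skipped"] = True

    # --- feature association -------------------------------------------
    if gene_calls is not None and genes is not None and tes is not None and counts is not None:
        universe = _informative_gene_ids(counts, genes)
        imprinted_ids = set(
            gene_calls.loc[gene_calls["class"].isin(["MEG", "PEG"]), "gene_id"]
        )
        imp_genes = genes[genes["gene_id"].isin(imprinted_ids)]
        bg_genes = genes[genes["gene_id"].isin(universe - imprinted_ids)]
        enrich = association.te_enrichment(imp_genes, bg_genes, tes, flank=config.te_flank)
        io.write_tsv(out / "te_enrichment.tsv", enrich)
        if len(enrich):
            overall = enrich[enrich["contrast"] == "any_TE"]
            if len(overall):
                summary["te_overall_fisher_p"] = float(overall["p_value"].iloc[0])
        info_genes = genes[genes["gene_id"].isin(universe)]
        try:
            cl = association.cluster_test(
                imp_genes, info_genes, n_perm=config.cluster_n_perm, seed=config.seed
            )
            summary["cluster_p"] = cl["p_value"]
            summary["cluster_observed_mean_distance"] = cl["observed_mean_distance"]
            summary["n_mini_clusters"] = len(cl["mini_clusters"])
        except ValueError as exc:
            summary["cluster_p"] = None
            logger.info("cluster test not run: %s", exc)
        summary["stages"].append("association")

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _informative_gene_ids(counts: pd.DataFrame, genes: pd.DataFrame) -> set[str]:
    """Genes containing >= 1 high-quality locus informative in both crosses."""
    hq = counts[counts["high_quality"]]
    ids = set()
    by_scaffold = {s: d.sort_values("start") for s, d in genes.groupby("scaffold")}
    for row in hq.itertuples():
        d = by_scaffold.get(row.scaffold)
        if d is None:
            continue
        i = np.searchsorted(d["start"].to_numpy(), row.pos, side="right") - 1
        if i >= 0 and row.pos < d["end"].iloc[i]:
            ids.add(d["gene_id"].iloc[i])
    return ids


def _genes_from_bed(path) -> pd.DataFrame:
    df = io.read_bed(path)
    return df.rename(columns={"name": "gene_id"})[["gene_id", "scaffold", "start", "end", "strand"]]


def _tes_from_bed(path) -> pd.DataFrame:
    df = io.read_bed(path)
    return df.rename(columns={"name": "family"})[["scaffold", "start", "end", "family"]]


def validate_outputs(run_dir) -> dict:
    """Audit a completed run directory against the selection rules.

    Re-checks every DMR against the five criteria, every MEG/PEG locus
    against the FDR and 90% rules, and every allele-specific DMR
    against the 40/70 thresholds and the length arithmetic.  Returns a
    report dict with per-file violations; ``ok`` is True when no file
    is missing and nothing is violated.
    """
    run = Path(run_dir)
    report: dict = {"missing": [], "violations": [], "ok": True}

    def _need(name):
        path = run / name
        if not path.exists():
            report["missing"].append(name)
            return None
        return path

    imp_path = _need("imprinting.tsv")
    if imp_path is not None:
        loci = pd.read_csv(imp_path, sep="\t")
        for row in loci.itertuples():
            cls = loci.loc[row.Index, "class"]
            tag = f"imprinting.tsv:{row.scaffold}:{row.pos_1based}"
            if cls == "MEG":
                if not (
                    row.fdr_mat <= 0.05
                    and row.mat_frac_AxB >= 0.90
                    and row.mat_frac_BxA >= 0.90
                ):
                    report["violations"].append(f"{tag}: MEG fails FDR/90% rules")
            elif cls == "PEG":
                if not (
                    row.fdr_pat <= 0.05
                    and 1 - row.mat_frac_AxB >= 0.90
                    and 1 - row.mat_frac_BxA >= 0.90
                ):
                    report["violations"].append(f"{tag}: PEG fails FDR/90% rules")

    dmr_path = _need("dmrs.tsv")
    cpg_en = _need("cpg_endosperm.tsv")
    cpg_em = _need("cpg_embryo.tsv")
    if dmr_path is not None and cpg_en is not None and cpg_em is not None:
        dmrs = pd.read_csv(dmr_path, sep="\t")
        if len(dmrs):
            calls_a = _calls_from_bedgraph(cpg_en)
            calls_b = _calls_from_bedgraph(cpg_em)
            report["violations"].extend(
                f"dmrs.tsv: {v}" for v in methylation.audit_dmrs(dmrs, calls_a, calls_b)
            )

    adm_path = _need("allele_dmrs.tsv")
    if adm_path is not None:
        adm = pd.read_csv(adm_path, sep="\t")
        for row in adm.itertuples():
            tag = f"allele_dmrs.tsv:{row.gene_id}:{row.start}"
            if row.length != row.end - row.start:
                report["violations"].append(f"{tag}: length != end - start")
            lo = min(row.meth_maternal, row.meth_paternal)
            hi = max(row.meth_maternal, row.meth_paternal)
            if not (lo < 40 and hi > 70):
                report["violations"].append(f"{tag}: fails 40/70 rule")

    report["ok"] = not report["missing"] and not report["violations"]
    return report


def _calls_from_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return pd.DataFrame(
        {
            "scaffold": df["scaffold"],
            "pos": df["start"],
            "strand": df["strand"],
            "context": "CpG",
            "c_count": df["c_count"],
            "t_count": df["t_count"],
            "level": df["level"],
        }
    )
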