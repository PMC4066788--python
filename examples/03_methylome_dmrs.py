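"""Call CpG methylation, endosperm-vs-embryo DMRs and allele-specific DMRs.

Bisulfite reads are placed with conversion-aware matching, per-CpG
levels are counted, and segments satisfying the five DMR criteria
(methylated-site count, coverage, length/gap, a mean difference of at
least 0.5, chi-square P <= 0.05) are reported.  Endosperm reads
overlapping parental SNPs are split by allele to score the <40%/>70%
allele-methylation rule around imprinted genes.
"""

from imprintseq import (
    SimConfig,
    assign_parent_of_origin,
    call_allele_dmrs,
    call_cytosines,
    call_dmrs,
    dmr_gene_overlap,
    gen_bisulfite_reads,
    make_truth,
    map_bisulfite_reads,
    metagene_profile,
)

config = SimConfig(seed=1)
truth = make_truth(config)
genome = truth.haplotypes["p1"]

placements, calls = {}, {}
for sample in ("endosperm", "embryo"):
    reads, _ = gen_bisulfite_reads(config, sample, truth)
    placements[sample] = map_bisulfite_reads(reads, genome)
    calls[sample] = call_cytosines(placements[sample], genome)
    mean = calls[sample].level.mean()
    print(f"{sample}: {len(calls[sample]):,} CpG calls, mean level {mean:.3f}")
print("— the endosperm is globally hypomethylated relative to the embryo.")

profile = metagene_profile(calls["endosperm"], truth.genes)
print(f"\nmetagene profile bins with data: {(profile.n_features > 0).sum()}")

dmrs = call_dmrs(calls["endosperm"], calls["embryo"])
print(f"endosperm-vs-embryo DMRs: {len(dmrs)}")
links = dmr_gene_overlap(dmrs, truth.genes)
hypo_genes = sorted(set(links.loc[links["diff"] < 0, "gene_id"]))
print(f"genes with an endosperm-hypomethylated DMR within +/-2 kb: {hypo_genes}")

labels = assign_parent_of_origin(placements["endosperm"], truth.snps)
allele_calls = call_cytosines(placements["endosperm"], genome, parent_labels=labels)
imprinted = truth.genes[truth.genes.class_label.isin(["MEG", "PEG"])]
allele_dmrs = call_allele_dmrs(allele_calls, imprinted)
print(f"\nallele-specific DMRs at imprinted genes: {len(allele_dmrs)}")
if len(allele_dmrs):
    row = allele_dmrs.iloc[0]
    print(
        f"example: {row.gene_id} {row.region} {row.start}-{row.end} "
        f"maternal {row.meth_maternal:.0f}% vs paternal {row.meth_paternal:.0f}%"
    )
    print(
        "— maternal hypomethylation with paternal hypermethylation is the "
        "signature expected when demethylation of the maternal genome "
        "underlies imprinted expression."
    )
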