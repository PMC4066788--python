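"""Generate a reciprocal-cross endosperm dataset with known truth.

Two parental haplotypes differing at biallelic SNPs, gene models with
MEG/PEG/accession-biased/biallelic class labels, TE annotations, and
RNA plus bisulfite reads, all written as plain FASTA/FASTQ/BED/TSV.
"""

from imprintseq import SimConfig, gen_endosperm_reads, make_truth

config = SimConfig(seed=1)
truth = make_truth(config)

print(f"scaffolds: {config.n_scaffolds} x {config.scaffold_len:,} bp")
print(f"SNPs between parental lines: {len(truth.snps)}")
print("gene classes:", truth.genes.class_label.value_counts().to_dict())
print("TE families:", truth.tes.family.value_counts().to_dict())

reads, origin = gen_endosperm_reads(config, "AxB", truth)
maternal = (origin.parent == "maternal").mean()
print(f"\nAxB endosperm reads: {len(reads):,}")
print(f"maternal read fraction: {maternal:.3f}")
print(
    "— close to 2/3 overall because most genes are biallelic and a "
    "triploid endosperm carries two maternal genome copies per paternal one."
)
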