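"""Test imprinted genes for TE proximity and physical clustering.

TE presence within 4-kb flanks is compared between imprinted and
background (informative, non-imprinted) genes with Fisher's exact test,
overall and per family; gene clustering is assessed by permuting the
informative gene set.
"""

from imprintseq import SimConfig, TeFamily, cluster_test, make_truth, te_enrichment

config = SimConfig(
    seed=3,
    n_scaffolds=4,
    scaffold_len=200_000,
    n_genes=400,
    gene_len=400,
    frac_meg=0.15,
    frac_peg=0.0,
    frac_accession_biased=0.0,
    te_families=(
        TeFamily("LTR/Gypsy", count=25, meg_multiplier=8.0),
        TeFamily("DNA/MuDR", count=25),
    ),
)
truth = make_truth(config)
imprinted = truth.genes[truth.genes.class_label == "MEG"]
background = truth.genes[truth.genes.class_label == "biallelic"]

enrich = te_enrichment(imprinted, background, truth.tes)
print(enrich.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
print(
    "\n— the generator placed extra LTR/Gypsy copies near MEGs "
    "(8x multiplier), and only that family shows a small Fisher P; "
    "per-family P-values are also BH-adjusted."
)

result = cluster_test(imprinted, truth.genes, n_perm=2000, seed=3)
print(
    f"\nmean distance between consecutive imprinted genes: "
    f"{result['observed_mean_distance']:,.0f} bp "
    f"(permutation P = {result['p_value']:.3f}, "
    f"{len(result['mini_clusters'])} mini-clusters)"
)
print(
    "— imprinted labels were assigned independently of position here, so "
    "no significant clustering is expected."
)
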