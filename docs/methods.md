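# Methods

This note records the models implemented by `imprintseq`, the choices
made where the procedure admitted more than one reasonable reading, and
what the synthetic data does and does not establish about real data.

## Coordinates and conventions

All internal coordinates are 0-based, half-open; 1-based positions
appear only in TSV/VCF columns named `pos_1based`.  Interval lengths are
therefore always `end − start`, which is also the convention the
allele-DMR writer emits (both scaffold-absolute and gene-relative
frames; gene-relative puts the TSS at 0 with upstream negative,
oriented by gene strand).  Cross `AxB` means parent 1 is the mother;
maternal/paternal counts are derived from parent-1/parent-2 counts by
this orientation map.

## The imprinting test

Per locus and direction, the test is the exact binomial tail (scipy's
`binom.sf`/`cdf`; no normal approximation) against the triploid dosage
null: maternal probability 2/3, paternal 1/3.  The two reciprocal
P-values are combined as `P = max(p1, p2)²` — the CDF transform of the
second-order statistic of two independent uniforms, hence itself
uniform under the null (asserted by a KS test at 10⁵ draws).  The rank
FDR is the literal `P·n/i` over the ascending-sorted list, computed
separately for the maternal and paternal candidate lists; the
Benjamini–Hochberg step-up pass (cumulative minimum from the bottom) is
available as `monotone=True` but off by default, because the plain
ratio is what the selection rule as stated uses.  Selection requires
`FDR ≤ 0.05` *and* a uniparental read fraction ≥ 0.90 in both crosses.
At coverage ≈ 50 the 90% filter dominates the null error rate: a
dosage-null locus needs ≥ 45/50 maternal reads in both crosses
(probability ≈ 5·10⁻¹⁰), which is why the measured false-discovery
proportion in the calibration simulation is essentially zero.

Ambiguities resolved here: the FDR is computed over loci (not genes);
gene classification is the unanimous class of a gene's significant
loci, with conflicts flagged `discordant` and excluded from MEG/PEG
totals, and pooled per-gene counts reported for inspection only.
Imprinted loci outside every gene body are reported per locus as
`intergenic_*_like` with the distance and stranded side of the nearest
gene.  A locus is annotated `complete` (strict monoallelic) when the
minor parent has zero reads in both crosses, `partial` otherwise.

Accession bias is the direction-independent analogue: line-X read
fraction > 0.90 in both crosses with the per-cross binomial deviation
(null 2/3 when X is the mother of that cross, 1/3 otherwise) FDR-
significant in both per-cross lists.  It is disjoint from MEG/PEG by
construction, since a fraction cannot exceed 0.9 for both the same line
and the same parent across reciprocal crosses.

## SNP calling and allele counting

SNP calling consumes pileup summaries built by an in-repo k-mer-seeded
ungapped placer (seed pigeonhole: `max_mismatch + 1` disjoint seeds
guarantee detection of any qualifying diagonal).  Filters: bases with
quality ≤ 20 are not counted; bases within 5 bp of either read end are
tallied separately and excluded ("read ends" is not quantified in the
original protocol; 5 bp is standard end-artifact trimming); each parent
needs ≥ 5 remaining bases; a parent is heterozygous — and the site
dropped — when the minor allele exceeds 10% *and* has ≥ 2 reads (a
single discordant read is treated as sequencing error).  Consensus
bases must differ.

Allele windows: the protocol describes a "191-nt" window as "SNP
± 90 bp", which is arithmetically 181 nt.  We keep length 191 with the
SNP at offset 90 (90 bp left flank, 100 bp right), truncating at
scaffold edges with the offset adjusted.  Read assignment is ungapped,
fully contained, both orientations, ≤ 4 mismatches against the better
allele sequence; among placements within a window only minimal-mismatch
placements are kept (ties leftmost).  A read is assigned only if its
alignment covers the SNP offset and its base there equals one parental
allele; a read covering several SNPs is counted at each locus unless
its parental assignments conflict, in which case it is discarded
everywhere (chimera/error guard — whether the original analysis kept
such reads is unknowable, so the choice is surfaced in the assignment
stats).  Loci need > 10 reads in both crosses to be flagged
high-quality and enter the joint test.

## Methylome

Bisulfite placement uses the standard three-letter scheme (C→T seeds on
the Watson attempt, G→A on the Crick attempt) with ≤ 2 true mismatches
after the conversion allowance, dropping reads with more than one best
placement.  Per-CpG counts are per strand; symmetric CpG merging is not
applied (the two strand cytosines of a CpG are independent rows), so at
genome coverage *c* each CpG row sees about *c*/2 reads — the DMR
coverage rule (> 10 reads in both samples) should be read against that.

DMR segmentation is a reconstruction: the five criteria are stated by
the protocol but no algorithm is, so we (1) restrict to CpGs with > 10
reads in both samples, (2) seed on sites with level difference ≥ 0.5,
(3) chain seeds with gaps < 200 bp, and (4) keep chains with span
> 40 bp, > 5 methylated CpGs (c_count ≥ 1 — "methylated site" is not
quantified either) in at least one sample, mean per-site level
difference ≥ 0.5 over all covered sites in the span, and a Pearson χ²
P ≤ 0.05 on the pooled (methylated, unmethylated) counts, 2×2 without
continuity correction.  `audit_dmrs` re-checks every emitted segment
against the criteria independently and is wired into
`validate_outputs`.

Allele-specific DMRs slide 200-bp windows (step 100 bp — the overlap
step is unstated; half-window is the natural choice) over gene body
± 2 kb.  Reads are assigned a parental haplotype by SNP votes, skipping
SNP/base combinations that bisulfite conversion makes ambiguous (C/T on
plus-strand reads, G/A on minus).  A window qualifies with > 5 reads
and ≥ 5 informative methylcytosines per allele and pooled percent
levels on opposite sides of the 40%/70% thresholds; overlapping
qualifying windows merge into maximal regions re-scored over the merged
span.

Metagene profiles average per-cytosine levels in 200-bp bins around the
stranded 5′ or 3′ anchor, covering the 2-kb flank plus the proximal
feature body (positions beyond the far end of the feature are
excluded); per-feature bin means are averaged unweighted over features.

## Feature association

Fisher tests are two-sided by the probability-mass rule (sum of
hypergeometric probabilities ≤ the observed table's), matching exact
enumeration for every 2×2 table with N ≤ 40 in the tests; the reported
odds ratio is the cross-product estimate.  TE proximity counts a TE for
a gene when it overlaps gene body ± 4 kb, half-open (the gene body is
included; an `exclude_body` flag exists because "flanking" could be
read either way).  The enrichment background is genes with at least one
high-quality informative locus in both crosses, not the whole
annotation.  Clustering uses the mean distance between consecutive
imprinted genes per scaffold against a null of equally many genes drawn
uniformly without replacement from the informative set, with add-one
smoothing, `P = (1 + #{null ≤ obs}) / (n_perm + 1)`; mini-clusters are
runs of ≥ 2 imprinted genes with no intervening informative gene.

## The synthetic-data generator

The generator emulates the study design: two inbred parental haplotypes
differing only at biallelic SNPs (kept ≥ 90 bp from scaffold edges so
every SNP supports a full window, and with one SNP guaranteed per gene
so gene-level recall is measured against all of truth); single-end
90-bp error-free reads (an optional uniform per-base error rate exists;
paired-end layout is not modeled, as the mate adds no information to
counting alleles at a single locus); reciprocal
endosperm transcriptomes where each read's parent of origin is drawn
with maternal probability 2/3 (biallelic), `imprint_strength` = 0.97
(MEGs; symmetric for PEGs) or line-directed 0.97 (accession-biased,
85% of them toward line 1); parental RNA covering transcripts extended
one read length past the annotated body (UTR emulation); and bisulfite
reads drawn from the maternal haplotype with probability 2/3 in
endosperm and 1/2 in embryo, with each CpG cytosine surviving
conversion with probability `level + (1 − level)(1 − 0.995)`.
Methylation truth is regional: embryo 0.8 everywhere, endosperm 0.7
background (global hypomethylation), 0.05 in endosperm-hypomethylated
gene bodies (half of MEGs and 5% of other genes by default, which makes
the imprinting–hypomethylation Fisher test informative), and
maternal 0.05 / paternal 0.90 at allele-differentially-methylated MEGs.
TE families are scattered uniformly, with extra copies Poisson-placed
in MEG flanks according to a per-family multiplier (LTR/Gypsy 4× by
default).  An optional `maternal_contamination` fraction adds purely
maternal reads per locus to let tests demonstrate how seed-coat RNA
mimics MEGs.

All randomness derives from `SimConfig.seed` through named substreams,
so identical configurations are byte-identical regardless of the order
in which generators are called.

What the generator does **not** model: sequencing error ramps, indels,
PCR duplicates, spliced transcripts, overdispersed allelic counts
(biological replicate variance), CHG/CHH methylation, partial bisulfite
conversion bias along reads, or reference mapping bias beyond the SNPs
themselves.  Passing tests therefore certify the statistical machinery
and its thresholds under clean dosage sampling — not robustness to
alignment artifacts or biological overdispersion, which on real data
would push toward beta-binomial alternatives explicitly left out of
scope.

## Problem sizes and numerics

Default simulations are desk-scale (two 100-kb scaffolds, 40 genes,
~50× RNA coverage per SNP, 30× bisulfite coverage), chosen so the whole
pipeline runs in seconds-to-minutes on one CPU while keeping every
per-locus decision at realistic coverage; the parameter-recovery
cohort scales the gene count to 2,220 (200 MEGs, 20 PEGs) with one SNP
per 200-bp gene, and the false-discovery simulation uses 5,000 null +
500 imprinted loci × 50 replicates drawn directly at the count level.
Degenerate inputs are defined rather than crashed on: empty read sets
give empty tables, zero-read loci are excluded with a log entry,
zero-margin Fisher tables return P = 1, and an undefined clustering
statistic (fewer than two imprinted genes per scaffold) raises.
Ties in the FDR ranking follow stable sort order; ties in window
placement break leftmost.
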