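# Methods

`haplobook` assembles a diploid genome from long reads into *haplotigs* —
contigs that each represent a single haplotype rather than a consensus of
both. The pipeline divides the read set into local clusters, phases each
cluster at its heterozygous SNPs, assembles each phase group into a *super
read*, and finally assembles the super reads genome-wide under strict
thresholds. This document describes each stage, the parameters that govern
it, and the numerical choices behind them.

## 1. Overlap detection and filtering

All-vs-all read overlaps are found with minimizer sketches (k = 15; window
w = 10 for HiFi, w = 5 for noisy platforms, whose errors thin out shared
minimizers). Shared minimizers between a read pair become anchors; the
longest strictly increasing anchor chain (longest-increasing-subsequence on
target positions within one strand) defines a candidate overlap, which is
then base-level verified with edlib and given exact coordinates and an
identity estimate.

Each overlap is classified in the style of miniasm: after computing the
unaligned *overhangs* on both reads, an overlap is

- **internal match** if the overhang exceeds `min(1000, 0.8 × overlap span)`
  on both sides — repeat-induced, discarded;
- **containment** if one read's aligned span covers essentially the whole
  read — recorded, and the contained read is absorbed in graph building;
- **dovetail** (suffix-of-one onto prefix-of-other) otherwise — the only
  class that creates graph edges.

Filters: minimum overlap length `min_ovlp_len` (1000 bp), minimum identity
`min_identity` (0.95 HiFi, 0.75 CLR/ONT — a true overlap between two reads
with ~10% independent errors has expected identity ≈ 0.9² ≈ 0.8, so 0.75
keeps true overlaps while rejecting noise), self-overlaps dropped, and each
pair kept once under a canonical (smaller-id-first) orientation.

## 2. Seed-centred clustering

Reads are sorted by length (ties broken by id). Repeatedly, the longest
unassigned read becomes a cluster *seed*, and every unassigned read sharing a
retained overlap with the seed joins that cluster. The result is a partition
of the read set; reads overlapping two seeds go to the earlier (longer) seed.
Worked example: reads R1 (10 kb) … R5 (5 kb) with overlaps {R1–R2, R1–R3,
R4–R5} yield clusters {R1, R2, R3} (seed R1) and {R4, R5} (seed R4).

## 3. Ad hoc reference and SNP calling

Each cluster's reads are laid out into a cluster-local backbone: overlap
graph → transitive reduction → cycle breaking (weakest edge by extension
length) → longest path → overlap-aware concatenation, followed by pileup
polishing. This backbone is *only* a coordinate system; it never reaches the
output.

All cluster reads are mapped back to the backbone and candidate heterozygous
SNPs are called from the pileup: depth ≥ 10 (`snp_min_depth`), minor allele
count ≥ 3 (`snp_min_allele_count`), allele frequency in [0.2, 0.8]
(`snp_af_low/high`). In a diploid cluster a true het site should sit near
0.5; the band admits coverage skew while rejecting sequencing errors
(expected frequency ≈ error rate / 3 per alternative base).

## 4. Phasing by weighted MEC

Reads × SNP sites form an allele matrix (0 = reference-like, 1 = alternative,
entries weighted by base quality; simulated reads default to weight 10). The
weighted Minimum Error Correction problem — bipartition the reads so that the
total weight of entries disagreeing with their side's per-column majority is
minimal — is solved *exactly* by a column-sweep dynamic program over the
reads active at each column (subset enumeration with per-column cost folding
and checkpointed backtrace). Columns are processed left to right, and the
state is the bipartition of the reads covering the current column, so the
cost is exponential only in local coverage, which is capped: if more than
`max_phasing_coverage` (20) reads cover a column, the longest reads are kept
for the DP and the rest are assigned afterwards to the side with the lower
disagreement weight (`assign_unphased`). The solution is canonicalised so
that H1 contains the lexicographically smallest phased read id.

Clusters with no called SNP sites stay unphased and produce a single group.

## 5. Group correction and super reads

For noisy platforms (`correct_raw_reads`, on by default for CLR/ONT), each
phase group is self-corrected: the group's reads build a group-local
backbone, its pileup majority is voted, and each read's aligned span is
replaced by the consensus segment. Correction happens *after* phasing, so
the vote never mixes haplotypes.

Each group is then assembled into a super read: overlap graph over the
(corrected) group reads, transitive reduction, longest path, concatenation,
then pileup polishing. Two numerical points matter here:

- **Polishing votes use the raw reads, not the corrected ones.** Correction
  splices one consensus into every read of the group, so corrected reads
  carry *correlated* errors — a mistake in the correction backbone is
  unanimous and majority voting cannot remove it (it can even fake a
  balanced variant downstream). Raw-read errors are independent, so voting
  them drives the error rate down.
- **Coverage trimming** (`sr_trim_min_cov`): the longest stretch with pileup
  coverage ≥ 2 (HiFi) or ≥ 5 (CLR/ONT) is kept. At ~10% per-base error, 2
  voters can tie and 4 can tie 2–2; 5 is the smallest depth at which a wrong
  majority needs three independent errors at one position. Super reads built
  from a single read (coverage 1 throughout, nothing to vote with) are
  exempt. Thinly covered super-read *ends* dominate residual error, which is
  why trimming is by coverage rather than a fixed margin.

## 6. Genome-wide super-read assembly

Super reads overlap each other under strict thresholds: `sr_min_ovlp_len`
(3000 bp) and `sr_min_identity` (0.98 HiFi, 0.95 CLR/ONT). Identity alone
cannot separate same-haplotype from cross-haplotype joins at ~1%
heterozygosity — the other haplotype is ~99% identical — so haplotype
fidelity rests on SNP genotyping of the overlap regions (`snp_edge_filter`):

- **Join screening** (`remove_spurious_edges_by_snps`): for each candidate
  edge the two super reads are concatenated along their overlap, the *raw*
  reads of both endpoint groups are mapped onto the joint sequence, and
  candidate het sites are called inside the overlap region with a tighter
  allele-frequency band [0.3, 0.7] (`join_af_low/high`). A candidate counts
  as *segregating* only if the reads private to each side agree on one
  allele at a ≥ 75% supermajority (≥ 2 informative reads per side) and the
  two sides' alleles differ. Alignment-wobble pseudo-het splits *within* a
  side and is ignored; a true cross-haplotype join segregates cleanly
  (observed 0–2 vs 26–264 segregating sites on the bundled studies). The
  edge survives iff the count is ≤ `snp_filter_k` (0).
- **Containment genotyping**: before absorbing a contained super read, its
  span on the container is genotyped the same way; a heterozygous
  containment means the contained super read is the *other* local haplotype
  that merely passed the identity gate, so it keeps its own node.

`snp_edge_filter` is off by default (its per-edge genotyping assumes
per-group read sets that cover the join region at callable depth) and is
enabled in the bundled small-genome studies.

The filtered graph then undergoes tip removal (dead-end chains of ≤
`tip_max_nodes` = 2 nodes hanging off a branching node, applied to
fixpoint), transitive reduction, cycle breaking, and merging of maximal
simple paths into contigs. Contigs are polished once more with the raw reads
of their constituent groups and filtered by `min_contig_len` (1000 bp).

## 7. Simulator

`simulate_diploid` generates haplotype 1 uniformly at random and derives
haplotype 2 by Bernoulli(`snp_rate`) substitutions (alternative alleles
uniform over the three other bases) and Bernoulli(`indel_rate`) indels
(half insertions, half deletions, lengths uniform on 1–10 bp), with the het
sites' coordinates tracked on both haplotypes. `simulate_reads` samples
reads per haplotype to a coverage target with lognormal lengths (clamped),
uniform starts, random strands, and i.i.d. per-base substitution /
insertion / deletion errors. Every read's true origin (haplotype, interval,
strand) is recorded. Both functions are byte-exact deterministic given their
seeds.

Calibration note: at 10% total error, minimal edit distance *undercounts*
the applied events (adjacent independent events merge into one edit), so
calibration is asserted per channel with exact event counts — substitutions
always change the base, and pure insertion/deletion runs shift the length by
exactly the event count.

## 8. Evaluation

Contigs are aligned to both truth haplotypes by minimizer chaining; chains
are split where the alignment diagonal jumps by > 1 kb (misassembly
breakpoints) and each block is base-level aligned. Reported metrics:

- **Haplotype coverage (HC)**: percent of truth bases (both haplotypes)
  covered by blocks of contigs assigned to that haplotype (each contig is
  assigned to the haplotype it matches best).
- **Switch error rate**: percent of adjacent het-site pairs within a contig
  whose observed alleles flip haplotype.
- **N50 / NG50 / NGA50**: contig lengths vs assembly size, vs genome size,
  and alignment-block lengths vs genome size.
- **Duplication ratio**: aligned contig bases / covered truth bases.
- **QV**: −10·log₁₀ (block edit distance / aligned bases).

## Limitations

- The exact wMEC column sweep is exponential in local coverage; the
  `max_phasing_coverage` cap keeps it tractable at the cost of exactness for
  the excluded (shortest) reads, which are assigned greedily afterwards.
- One round of seed-centred clustering phases *locally*; phase consistency
  across clusters is enforced only through the SNP-screened super-read
  joins, not by iterative cluster merging.
- The SNP edge filter needs callable depth from both endpoint groups inside
  the join region; at very low coverage it degrades to the identity gate.
- The simulator draws i.i.d. errors and uniform starts; it does not model
  homopolymer-dependent errors, chimeras, or coverage bias.
- Sex chromosomes, polyploidy, and structural variants beyond short indels
  are out of scope.
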