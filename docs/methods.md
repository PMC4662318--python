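# Methods

This note documents the models, rules and numerical choices behind
`amplimhc`: what the synthetic community emulates, how the replicate-
validation caller decides what an allele is, how the selection and spatial
statistics are computed, and where the genuinely open design decisions were
settled.

## The synthetic community

The generator is first-class, tested code, not a fixture. It emulates a
multi-locus MHC class II *DRB* exon-2 amplicon survey of 65 lesser anteaters
across five Brazilian biomes, at the parameter values that survey reports.

**Allele pool.** A random 65-codon (195-bp) stop-free ancestor is mutated
into 7 locus ancestors (≈15 accepted substitutions each) and each locus into
10 alleles (≈6 substitutions each), for 70 distinct nucleotide alleles.
Proposed substitutions are accepted with probability 0.5 if synonymous,
0.5·enrichment (capped at 1; default enrichment 5) if nonsynonymous in an
antigen-binding-site (ABS) codon, and 0.5·ω (default ω = 0.5) if
nonsynonymous elsewhere; stop-creating proposals are rejected. This plants
diversifying selection at ABS and purifying selection outside it. Ten
alleles are converted into single-base synonymous siblings of a same-locus
allele, so the 70 nucleotide alleles collapse to 60 amino-acid alleles and
the catalog exercises the letter-suffix nomenclature. One allele carries a
3-bp insertion (codon 5) and thirteen carry a 3-bp deletion (codon 57),
sibling groups moving together, mirroring the deposited indel alleles; all
indels are whole codons so every allele translates in frame 1. Pool-wide
nucleotide diversity lands near 0.15 with these mutation counts, the same
order as the surveyed gene (0.132).

**ABS mask.** The 21 ABS codons are a required, recorded input everywhere.
The shipped default is the set of HLA-DR1 β-chain peptide-contact positions
(Brown et al. homology) that fall inside a 65-codon fragment whose first
codon corresponds to β26: fragment codons
{1, 3, 5, 7, 12, 13, 22, 31, 32, 35, 36, 40, 42, 43, 45, 46, 49, 53, 56,
57, 61}. Any ABS-dependent result is sensitive to this choice; the mask is a
config value, never hard-wired into the statistics.

**Genotypes.** Biomes have the surveyed genotyped sample sizes
(29/9/16/3/8) and private-allele counts (12/11/5/3/2). Designated private
alleles are sampled only within their biome and force-planted if unsampled;
all other ("common") alleles use biome-specific gamma-weighted frequencies,
with five range-wide alleles up-weighted tenfold, and any carried common
allele is guaranteed carriers in at least two biomes so the planted private
split is recoverable exactly from the truth. Per-individual allele counts
are uniform on [2, 13]. Coordinates are uniform draws from per-biome
bounding boxes — the sampling is biome-structured, exact localities are not
modelled.

**Reads.** Each individual yields two replicate amplicons with distinct
(forward, reverse) 10-base MID pairs (generated with pairwise Hamming
distance ≥ 3, no homopolymer ≥ 3). A read is
adaptor + key(TCAG) + MID + primer + insert + reverse-complemented reverse
fusion primer (316 bp for a 195-bp insert; the QC length floor of 280
targets this geometry). Error model, applied per read: substitutions at
2×10⁻³ per base over the whole read; homopolymer-length indels inside the
insert, one ±1-base event per run with probability rate × run length
(default rate 5×10⁻⁴); PCR chimeras at 3 % per read as single-breakpoint
recombinants of two alleles of the same individual, breakpoint uniform;
2 % of reads get low Phred qualities (mean Q12 vs. Q33) to exercise the
quality filter; half the reads are emitted reverse-complemented.
Per-amplicon coverage is uniform on [110, 5344] by default (the surveyed
post-filter range); the bundled tests and the acceptance script run at a
constant 300 reads per amplicon, far above the 110-read genotyping floor,
to keep runtimes in seconds. Every read is recorded in a truth table
(individual, replicate, source allele or chimera parents and breakpoint,
error counts, frameshift flag).

**Microsatellites.** Eight diploid loci with 4–12 alleles; biome frequencies
are Balding–Nichols-style Dirichlet draws around global frequencies with a
divergence parameter (default 0.1; 0 gives identical biomes), 2 % missing
data.

What the generator does *not* emulate: flowgram-level 454 signal, quality
decay along the read, per-allele amplification-efficiency differences
(exposed as a weights knob, default uniform), intra-locus recombination
history, and realistic spatial autocorrelation within biomes. Passing tests
therefore show that the workflow's logic is correct under a faithful error
*structure*, not that it is robust to every real-data pathology.

## Read QC

Filters apply in a fixed order — length → MID → primer → quality → frame —
so every rejected read carries exactly one reason and assigned + rejected
partitions the input. MID matching is exact; primer matching is exact under
IUPAC degeneracy (the forward primer contains Y and S); both orientations
are tried and reads are stored in forward orientation. The quality rule is
strict: pass iff ≥ 95 % of bases have Q > 20. The frame filter requires the
insert length to differ from 195 by a multiple of 3 and, via a gapped global
alignment against the amplicon consensus (the modal insert), every indel run
to be a whole number of codons. The alignment scores substitutions cheaply
relative to gaps (match 2, mismatch −1, gap open −12, extend −2): divergence
between co-amplified alleles must never be explained with spurious 1-bp
indels, and a biological 3-bp gap must not be split to harvest mismatch
savings. One consequence is documented and tested: a read carrying balanced
+1/−1 indels in different homopolymers keeps its net length, and when the
shifted segment is short it is mathematically indistinguishable from a few
substitutions; such reads (≲0.1 % at default rates) pass the frame filter
and are removed downstream as singletons.

## Allele calling

Variants are identity clusters ranked by read count (ties broken
lexicographically); singletons are artifacts outright. Each remaining
variant is screened against the *clearly* more frequent variants — those at
least 3× its count (`artifact_ratio = 1/3`, configurable): first the chimera
test (exhaustive single-breakpoint recombination scan over ordered parent
pairs, internal breakpoints only), then the 1-edit test (Levenshtein, so a
substitution and a single-base indel count equally), else "gt 1 bp". The
ratio is the package's resolution of a genuine ambiguity: error and chimera
classes arise from parent templates at per-read rates far below one third of
the parent's count, while genuinely co-amplified alleles (including
synonymous siblings 1 bp apart) have comparable counts; without the ratio,
real sibling alleles would be misclassified as artifacts and error-free data
would not be recovered exactly. Alleles whose amplification efficiency truly
is poor fall below the ratio and are caught by the rescue rule below.

A variant is a **putative allele** in an individual iff it occurs in both
replicate amplicons and, in each replicate, outnumbers every artifact-
labelled variant there (artifact-labelled = singleton, chimera or 1-bp;
being artifact-labelled self-excludes, since no count exceeds itself). A
variant failing that rule is **unclassified** iff it recurs in other
individuals and is nowhere explicable as an artifact (only "gt 1 bp" labels
where it occurs); otherwise it is an artifact. Across individuals a sequence
is validated if putative anywhere, or unclassified in ≥ 2 individuals; when
unclassified calls outnumber putative ones it is flagged as a putative
allele with low amplification efficiency. Either route guarantees the
validation criterion of two independent reactions of one individual or two
distinct individuals. Individuals are genotyped only when both replicates
pass the coverage floor (default 110 QC-passed reads, the surveyed minimum).
Validated alleles are named serially by discovery order with zero-padded
numbers; nucleotide alleles with identical translations share a number and
take coverage-ordered letter suffixes. The minimum number of amplified loci
is estimated as ceil(max per-individual count / 2). Variants containing
internal stop codons are flagged in the audit log, not auto-rejected.

## Selection statistics

Nei–Gojobori counting: potential synonymous sites per codon are the summed
synonymous fractions of the three positions, with changes to stop codons
counted as nonsynonymous so S + N = 3 per codon exactly; observed
differences for multi-hit codons are averaged over all minimal mutational
pathways, excluding pathways through stop codons and renormalizing (all
61×61 sense-codon pairs are checked against exhaustive enumeration in the
tests). pS and pN are Jukes–Cantor corrected (undefined and reported as such
at p ≥ 3/4). dN and dS for an alignment are means of pairwise corrected
rates over all unordered pairs; the Z-test resamples codon columns within
the analyzed partition (1000 bootstrap replicates by default), uses the
bootstrap variances, and takes the two-tailed normal p-value. Gap and
ambiguous codons are skipped pairwise; for site classes, columns containing
any gap are excluded from the compared sites, and parsimony-informative
means ≥ 2 states each in ≥ 2 sequences. Nucleotide diversity is computed
over unique alleles, unweighted by carrier frequency, with Nei's (1987)
variance estimator. K2P and Poisson distances use pairwise deletion.
`codon_align` handles the package's own indel structure (whole-codon indels
against the longest allele as reference, codon-token Needleman–Wunsch);
arbitrary alignments should be built externally and imported. The ABS mask
is lifted onto alignment coordinates by treating majority-gapped codon
columns as insertion columns.

## Spatial statistics

Rarefaction richness draws g individuals without replacement (default
g = minimum group size; 10,000 replicates; an exact enumeration mode covers
small groups and the test oracles). Private alleles are alleles whose
carriers all fall in one group. The frequent/rare classification is strict:
frequent iff frequency > 0.10 (so 7 of 65 carriers qualifies), rare iff
≤ 2 carriers. Microsatellite He is the uncorrected 1 − Σp² (the GenAlEx
default; an unbiased option exists), Ho the observed heterozygote fraction,
with missing genotypes dropped per locus. Geographic distances default to
great-circle (haversine) on lat/lon — a planar Euclidean option exists for
strict fidelity to the "Euclidean" wording — in log₁₀ km with co-located
pairs floored at 0.1 km. The individual genetic distance for
presence/absence genotypes is 1 − 2·|shared| / (|A| + |B|) (the "raw
individual genetic distance" of the emulated study is not defined there;
this default is an interpretation and is flagged as such); microsatellite
distance is the proportion of unshared alleles across loci, pairwise-deleted.
Mantel tests permute rows/columns of one matrix simultaneously, two-tailed
on |r|, p = (hits + 1)/(n + 1) so p is never 0; the partial test regresses
both upper triangles on the conditioning matrix and permutes the residuals
of the response. The paired t-test is the standard two-tailed Student test
on per-subject differences.

## Problem sizes and numerical choices

The bundled tests and the acceptance script simulate 65 individuals × 2
replicates × 300 reads (≈39,000 reads), which the full pipeline processes in
roughly ten seconds; the statistics use 1000 bootstrap replicates, 1000
Mantel permutations and 10,000 rarefaction draws, the same replication the
emulated study reports. All randomness flows from explicit seeds
(`numpy.random.default_rng`); identical config + seed reproduces artifacts
byte for byte. Frequency ties in variant ranking break lexicographically;
chimera breakpoint search excludes the sequence ends; bootstrap partitions
of fewer than two codons warn and report an undefined p.

## Known limitations

* The ABS mask is a homology-based default, not an experimentally determined
  set; ABS-partitioned results shift with the mask.
* The detected-selection signal on simulated pools varies with the pool
  realization: with 21 ABS codons the bootstrap variance is large, and at
  the default 5× enrichment the ABS Z-test is significant for most but not
  all seeds — matching the marginal significance such studies report.
* `codon_align` only supports deletions relative to the longest sequence;
  catalogs with independent insertions need an external aligner.
* Amplification-efficiency variation defaults to uniform; the unclassified /
  low-efficiency rescue path is exercised by construction in unit tests, not
  by the default simulation.
* The Mantel permutation scheme is the classic full row/column permutation;
  residual permutation for the partial test follows common ecology practice,
  but other schemes exist and give slightly different p-values.
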