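# amplimhc

Replicate-validated MHC class II *DRB* exon-2 amplicon genotyping and the
downstream immunogenetic and spatial statistics used in landscape
immunogenetics, packaged as a tested, reusable pipeline with a ground-truthed
synthetic-data generator.

## The problem

MHC class II genes are multi-locus, highly polymorphic and under strong
diversifying selection, which makes them both the marker of choice for
studying pathogen-driven local adaptation and a genotyping nightmare: a
single PCR of *DRB* exon 2 in a species with duplicated loci co-amplifies
2–13 alleles per individual, and pyrosequencing adds substitution errors,
homopolymer indels and PCR chimeras at frequencies comparable to genuine
low-abundance alleles. The accepted remedy is replicate validation: every
individual is amplified and sequenced twice with different barcodes, reads
are clustered into variants within each amplicon, variants are screened
against the more frequent ones (chimera test, 1-bp-difference test,
singleton removal), and only variants that survive in both independent
replicates — or that recur across individuals — are accepted as alleles.

`amplimhc` implements that workflow end to end for the 242-bp *DRB* exon-2
fusion-primer design used in the lesser anteater (*Tamandua tetradactyla*)
survey across five Brazilian biomes, together with the analyses such a study
runs on the validated allele set:

* **QC / demultiplexing** — length, exact MID barcode, IUPAC-aware primer
  match, Phred filter (≥95 % of bases with Q > 20), and a reading-frame
  filter that rejects any indel that is not a whole number of codons;
* **allele calling** — identity clustering, frequency ranking, chimera /
  1-bp / singleton artifact screening, cross-replicate validation,
  cross-individual rescue of low-amplification alleles, and nomenclature
  (`TateDRB*01a`-style names, letter suffixes for synonymous alleles);
* **selection analysis** — Nei–Gojobori dN/dS with Jukes–Cantor correction
  and a codon-bootstrap Z-test, partitioned into antigen-binding sites (ABS,
  21 codons inferred from HLA-DR1 homology) and non-ABS; Kimura-2-parameter
  and Poisson-corrected distances; site classes and nucleotide diversity;
* **spatial statistics** — rarefaction allelic richness (multiple random
  reductions of N), private alleles, microsatellite Na/Ho/He, Mantel and
  partial Mantel tests on individual genetic vs. log-km geographic
  distances, and the paired t-test comparing genotyping methods;
* **synthetic community** — a generator that emulates the study's inputs
  (70 alleles over ≥7 loci, biome-structured frequencies with private
  alleles, two replicate amplicons per individual, 454-style errors and
  chimeras) with a full per-read truth table, so every stage is testable
  without any sequencing data.

## The statistics, briefly

For a codon pair the Nei–Gojobori counts are potential synonymous sites
*S* = Σᵢ fᵢ (fᵢ the synonymous fraction of changes at position *i*) and
*N* = 3 − *S* per codon, with observed differences averaged over all minimal
mutational pathways that avoid stop codons. Proportions are corrected for
multiple hits with Jukes–Cantor, d = −¾ ln(1 − 4p/3), and the neutrality
test is Z = (dN − dS)/√(Var dN + Var dS) with variances from 1000 bootstrap
resamples of codon columns. Distances: K2P
d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q); Poisson d = −ln(1 − p). Allelic
richness at standardized size *g* is the mean distinct-allele count over
10,000 random draws of *g* individuals. Mantel r is the Pearson correlation
of upper-triangle distances with a two-tailed permutation p-value
(add-one rule); the partial variant correlates residuals after regressing
both matrices on the conditioning matrix.

## Worked example

```python
from amplimhc import (
    generate_allele_pool, assign_genotypes, simulate_amplicon_reads,
    run_qc, QualityRead, mean_dn_ds, paired_t_test,
)
from amplimhc.calling import call_genotypes, estimate_min_loci
from amplimhc.simulate import ReadSimConfig, FWD_PRIMER, REV_PRIMER
from amplimhc.reference_data import SSCP_COUNTS, NGS_COUNTS

pool = generate_allele_pool(seed=1)          # 7 loci x 10 alleles
truth = assign_genotypes(pool, seed=2)       # 65 individuals, 5 biomes
cfg = ReadSimConfig(coverage=(300, 300, "uniform"), seed=3)
reads, truth_table, mids = simulate_amplicon_reads(truth, pool, cfg)
qreads = [QualityRead(r, s, [ord(c) - 33 for c in q]) for r, s, q in reads]
amplicons, rejects = run_qc(qreads, mids, (FWD_PRIMER, REV_PRIMER))
catalog, genotypes, audit = call_genotypes(amplicons)

print(f"reads simulated   : {len(reads)}")
print(f"reads past QC     : {sum(len(a.inserts) for a in amplicons.values())}")
print(f"validated alleles : {len(catalog.alleles)} nucleotide / {len(catalog.aa_groups)} amino acid")
print(f"min. loci bound   : {estimate_min_loci(genotypes)}")

aln = pool.alignment()
test = mean_dn_ds(aln, aln.abs_mask, n_boot=1000, seed=1)
print(f"ABS dN/dS         : {test.ratio:.2f} (p = {test.p_value:.4f})")

t = paired_t_test(list(SSCP_COUNTS), list(NGS_COUNTS))
print(f"SSCP vs NGS       : t = {t.t:.3f}, p = {t.p_value:.3f}")
```

prints

```
reads simulated   : 39000
reads past QC     : 31287
validated alleles : 70 nucleotide / 60 amino acid
min. loci bound   : 7
ABS dN/dS         : 2.16 (p = 0.0016)
SSCP vs NGS       : t = 3.772, p = 0.004
```

All 70 planted alleles come back (the catalog collapses to 60 amino-acid
alleles because ten are synonymous siblings), no chimera survives
validation, the maximum per-individual count of 13 implies at least
ceil(13/2) = 7 amplified loci, the ABS partition shows the planted excess of
nonsynonymous substitution, and NGS detects significantly more alleles per
individual than SSCP gels on the published ten-individual comparison.

The same chain is available from the shell:

```bash
amplimhc all --outdir run          # simulate -> qc -> call -> selection -> spatial
amplimhc qc --config run/config.yaml --outdir run   # or stage by stage
```

Every stage writes plain TSV/FASTA artifacts plus a header naming the stage,
config hash and seed; `amplimhc all` reproduces byte-identical artifacts for
an identical config and seed.

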