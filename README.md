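# afrocnv

Tools for analysing copy-number variant regions (CNVRs) called in population
cohorts by two programs of very different granularity — a fine-grained,
breakpoint-aware caller and a coarse read-depth caller.  The package builds
the high-confidence consensus between the two call sets and then asks the
population-genetic questions that follow: which regions are novel, how are
they shared between populations, do selection signatures concentrate in them,
can SNP haplotypes tag the copy number, and what population structure do the
copy states carry?

Everything runs on a synthetic cohort generated in-package, so the full
pipeline is reproducible on a laptop without access-controlled genomes.

## What it computes

**Consensus CNVRs.** Per caller, overlapping (≥ 1 bp) per-sample calls are
merged into CNVRs; samples with grossly inflated call counts (median + 5·MAD
on total calls) are removed; regions carried by fewer than two samples are
dropped; the fine caller's regions with ≥ 1 bp overlap in the coarse caller's
regions are retained.  A random-placement null — re-placing the observed
interval lengths uniformly in the genome, 100 replicates — estimates how much
shared length chance alone would produce.

**Tag haplotypes.**  For each CNVR, SNPs within 5 kb of its boundaries are
clustered by linkage disequilibrium (single linkage over pairs with
r² > 0.8); every distinct phased allele string over a cluster is one
haplotype with per-sample dosage h ∈ {0, 1, 2}.  Fractional copy number c is
regressed on dosage,

    c = β₀ + β₁ h + ε,

and the CNVR is *tagged* if any haplotype's slope test survives a Bonferroni
correction for the number of informative haplotypes tested there
(p·m < 0.05).

**Selection enrichment.**  Per-SNP selection scores (−log₁₀ p of |iHS|,
threshold 3) are cross-tabulated against CNVR membership (2×2 Pearson χ²),
copy states against CNVR selection status (2×3 χ² with mean CNV frequency per
row), and tagging against selection across CNVRs (independence expectation
n_tagged·n_selected/n_total plus a 2×2 χ²).

**Population structure.**  Integer copy numbers are recoded as ordered allele
pairs (0 → 1 1, 1 → 1 2, 2 → 2 2, 3 → 2 3, … capped at 4 4), PCA and
IBS-distance MDS summarise structure, and Weir–Cockerham F_ST is estimated on
bi-allelic deletion loci (where deletion-allele dosage is exactly 2 − copies),
flagging loci more than 3 SD above the mean F_ST.

## Worked example

```bash
afrocnv run --seed 7 --out runs/demo
```

generates the default synthetic cohort (2 chromosomes × 10 Mb, 3 populations
× 20 samples, 300 true CNVRs) and runs every stage.  With `-v` the run for
seed 7 logs

```
afrocnv INFO outlier detection: 3 flagged (median=71.5, MAD=5.5, threshold=99.0)
afrocnv INFO consensus: 243 A-regions, 166 B-regions, 220 consensus
```

and the stage outputs contain, among others, observed shared length
1,628,183 bp against a simulated 900,878 ± 86,463 bp
(`null_overlap/null.tsv`, z = 8.4) and 121 of 220 consensus CNVRs tagged
(`taghap/tagged.tsv`).

Reading: the three planted outlier samples were removed; the fine caller's
regions share ~1.8× the length with the coarse caller's regions than random
placement predicts (the hallmark of genuine overlap); and about half the
consensus regions are tagged by at least one haplotype — taggable CNVRs ride
a single founder haplotype by construction, recurrent ones do not.  Stage
outputs land in `runs/demo/<stage>/` as headered
TSV/BED/VCF, with `manifest.json` recording version, seed, parameters and
input digests; rerunning with the same seed reproduces every output byte for
byte.

Individual stages are also exposed (`afrocnv simulate | consensus |
null-overlap | taghap ...`) and take the same files the pipeline writes.

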