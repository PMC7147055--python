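# Methods

## Coordinates and conventions

All internal coordinates are 0-based half-open (`[start, end)`), the BED
convention; VCF positions are converted exactly once on read, so a SNP at
VCF position *p* lies inside `[s, e)` iff *s* < *p* ≤ *e*.  Overlap always
means ≥ 1 bp shared; half-open adjacency is never overlap.  The diploid
reference copy number is 2; a sample with no call at a CNVR is reference,
never missing (required to define carrier frequencies).  Missing SNP
genotypes are flagged and excluded pairwise downstream — never imputed.

## Consensus construction

A CNVR is the maximal union of overlapping per-sample call intervals from
one caller.  The pipeline order is fixed: merge per caller → remove outlier
samples → re-merge → drop singleton regions (carried by < 2 samples) →
retain fine-caller regions with ≥ 1 bp overlap in the coarse caller's
regions.  Conventions where the procedure is otherwise under-determined:

* a sample with several overlapping calls inside one CNVR contributes the
  copy number of its longest call;
* region class is `deletion_only` if every non-reference copy is < 2,
  `insertion_only` if every one is > 2, else `mixed`;
* outliers are samples whose total call count exceeds median + k·MAD
  (default k = 5).  A count-based rule stands in for a visual
  multidimensional-scaling criterion; the outlier report includes group
  means and a Welch t-test comparing flagged vs retained counts, and the IBS
  coordinates are still computed for plotting.  Outlier detection refuses
  cohorts with fewer than 10 called samples (the MAD threshold is unstable).

**Shared-length semantics.**  `total_overlap_length(A, B)` is the summed
*full* length of A-intervals touching any B-interval — the retained-set
length, not the intersection length.  This makes the observed statistic and
its null directly comparable to the retained-set totals in the consensus
summary.

## Random-placement null

Each replicate re-places every observed A-interval length uniformly over all
valid start positions genome-wide: a chromosome is chosen with probability
proportional to its count of valid starts (`length − L + 1`), then the start
uniformly.  Placements are independent — replicate intervals may overlap one
another, since the statistic is a sum over intervals and nothing forbids
self-overlap.  The reported spread is the sample SD (n − 1) over replicate
totals (default 100 replicates).  For one placed interval of length L and a
single target of length M on a chromosome of length G, the closed-form hit
probability is (L + M − 1)/(G − L + 1), which the Monte-Carlo estimate must
reproduce — this is the engine's calibration check.  The toy layouts contain
no gaps or centromeres, so no placement exclusions are modelled.

## SNP QC

Loci with > 10 % missing genotypes are removed first, then samples with
> 10 % missingness over the surviving loci, then loci failing a 1-df
chi-square goodness-of-fit to Hardy–Weinberg proportions at p < 0.01.  The
chi-square (rather than an exact test) is the default because cohort sizes
here make the asymptotics unproblematic; an exact test would be the natural
swap for very small cohorts.

## Tag haplotypes

Candidate SNPs for a CNVR are those within the CNVR plus 5 kb flanks
(interior included by default; an interior-excluded mode exists because SNP
calls inside deletions are unreliable).  Pairwise LD r² is the squared
Pearson correlation of per-chromosome allele indicators — phase is known, so
no EM estimation is needed; pairs more than 50 kb apart are not evaluated.
SNPs are clustered by single linkage over edges with r² > 0.8, realising
"correlated with at least one other SNP" literally; singleton clusters are
dropped.  Every distinct per-chromosome allele string over a cluster defines
one haplotype; strings seen on fewer than 2 chromosomes are discarded as a
noise floor.  Haplotypes whose carriers all share one integer copy number
are uninformative and excluded from all calculations, including the
Bonferroni denominator.  Each remaining haplotype's dosage is regressed
against fractional copy number (the caller's continuous estimate, which
carries more information than the rounded integer) by OLS, with the slope
tested by a two-sided t-test on n − 2 df.  A CNVR is *tagged* iff some
haplotype achieves p·m < 0.05, m the number of informative haplotypes tested
at that CNVR.  Per-population re-runs subset the genotype columns and retest.

**Known limitation — family-wise calibration at small n.**  Two effects make
the realized false-tagging rate run above the nominal 5 % in small cohorts:
the slope t-test is anti-conservative in its extreme tail when the copy
vector is near-constant with a few ±1 outliers and the haplotype is sparse
(about 2× at n = 36 in a focused simulation), and the informativeness screen
reuses the data — a sparse haplotype is only tested when its carriers
straddle copy classes, conditioning retained tests toward association.  At
36 samples the recurrent-CNVR false-tagging rate measures ≈ 6 % instead of
5 %; at the default 60 samples it is statistically indistinguishable from
5 % (5.3 % over ~4,700 trials).  Calibration experiments therefore use the
default sample size and exchangeable populations: population stratification
induces a *real* dosage–copy confounding (both frequencies diverge across
populations) that is not a false positive of the test.

## Selection enrichment

Selection evidence is consumed as per-SNP scores, −log₁₀ p of |iHS|, with
"selected" meaning score > 3.  A CNVR's selected status includes its 5 kb
flanks, consistent with the tag-SNP windows.  Flanked regions are not merged;
SNP membership is tested against their union so each SNP counts once.  All
tests are Pearson chi-squares without continuity correction (Fisher's exact
is available by flag for the tagged×selected 2×2, whose original procedure
is not recoverable).  The 2×3 copy-state table counts every (CNVR, sample)
pair exactly once — deletion (< 2), wild type (= 2), insertion (> 2) — using
the complete-count convention (no pair exclusions); the mean CNV frequency
per row is (deletions + insertions)/row total.

## Population structure

Copy numbers are recoded as ordered allele pairs, alleles distributed
between chromosomes as equally as possible: 0 → (1,1), 1 → (1,2), 2 → (2,2),
3 → (2,3), 4 → (3,3), 5 → (3,4), and (4,4) for six or more copies.  PCA runs
on the column-centred sample × locus copy matrix (numerically simpler than
distance-based embedding and qualitatively equivalent); an IBS-distance
classical MDS over the allele-pair encoding is provided for parity.
Weir–Cockerham variance components are estimated per locus on bi-allelic
deletion loci only (states ⊆ {0, 1, 2}), where the deletion-allele dosage of
a sample is exactly 2 − copies and no phasing ambiguity exists.  The global
estimate is the ratio of summed components (not a mean of ratios); negative
per-locus values are retained, matching common tooling; monomorphic loci are
excluded from the sums.  High-F_ST loci exceed mean + 3·SD of the defined
per-locus values.

## Synthetic cohort

The generator emulates the statistical structure the stages assume — it is
not a mutation/recombination simulator and produces no reads.

* **Genome and cohort**: 2 chromosomes × 10 Mb; 3 populations × 20 samples,
  each population in its own linguistic group.  Sizes are desk-scale stand-ins
  chosen so every stage exercises its logic in seconds.
* **True CNVRs**: 300 non-overlapping intervals, log-normal lengths with
  median 5 kb (σ = 0.7), matching the fine caller's scale; half deletions,
  half insertions.
* **Frequencies**: ancestral carrier frequency Beta(0.8, 6) (mean ≈ 0.12,
  most CNVs rare), pushed through a two-level Balding–Nichols model —
  ancestral → group (F = 0.05) → population (F = 0.02) — so group-level and
  within-group divergence are separate dials.
* **Haplotypes**: a founder mosaic.  The genome is cut into 25 kb LD blocks;
  each block carries 5 founder haplotypes with Dirichlet frequencies (again
  perturbed per group and population); every chromosome draws one founder
  per block independently.  Each SNP (1 per 500 bp) carries a derived allele
  private to one founder, so SNPs with the same owner are in perfect LD and
  blocks decompose into discoverable clusters whose strings identify
  founders.  This is a star-shaped block structure: no recombination within
  blocks, no LD across blocks.
* **Taggable CNVRs** (60 %): an anchor block is chosen to overlap the tag
  window maximally; one founder is designated and its frequency pinned to
  h = 1 − √(1 − f) per population so the sample-level carrier frequency is f;
  copy number is exactly 2 ± founder dosage.  Recurrent CNVRs draw carrier
  dosage binomially, independent of any haplotype.
* **Callers**: caller A reports each carried CNVR per sample with Gaussian
  boundary jitter (sd 200 bp) and fractional copy = copies + N(0, 0.15) —
  the noise sd is set so rounding recovers the true integer > 99 % of the
  time; caller B merges true CNVRs within 20 kb and pads the span by 10 kb,
  emulating a read-depth caller that misses breakpoints and concatenates
  neighbours.  False-positive calls arrive at 0.02 per CNVR per sample;
  three outlier samples get a 40× multiplier, sized so their call totals sit
  ~5× above the retained mean — the regime the outlier filter expects.
* **Selection scores**: scaled so P(score > 3) equals the background rate
  (10⁻³) exactly, multiplied by the enrichment ratio (3×) inside selected
  CNVRs (5 %) plus 5 kb flanks.
* **Known-region database**: 97 % of true CNVRs, padded by 0–2 kb, plus 50
  decoy regions placed away from true CNVRs so the novelty rate stays at the
  configured 3 %.

What passing tests on this cohort do *not* show about real data: LD decay is
block-wise rather than continuous, fractional-copy noise is homoscedastic
Gaussian, false positives are uniform in the genome (no mappability or GC
structure), and every taggable CNV is perfectly concordant with one founder.
Real cohorts will sit between the generator's "taggable" and "recurrent"
extremes.

## Pipeline, determinism and problem sizes

`afrocnv run` executes simulate → consensus → null-overlap → annotate →
taghap → selection → popstruct; stages whose outputs exist are reused, no
stage mutates another's outputs, and a manifest records version, timestamp,
seed, resolved parameters and input digests.  All randomness flows from the
single seed; two runs with one seed are byte-identical in every stage output
(and in the manifest, timestamp aside).  The test and acceptance experiments
use reduced problem sizes chosen as the smallest that leave each measured
property in its asymptotic regime: 1 × 1.5–4 Mb genomes and 36–60 samples for
the tag experiments (50 seeds each), 10⁴ replicates for Monte-Carlo
calibration, and the full default cohort for the end-to-end run.

## Frequency denominator

Carrier frequency is carrier count over a configurable denominator,
defaulting to the retained (post-outlier) sample count; summaries round to
whole percent.  Cohort-level conventions differ on whether the denominator
is the enrolled or the retained cohort, so the choice is logged with every
output.
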