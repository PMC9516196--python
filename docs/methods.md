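# Methods

## The mapping model

The pipeline implements bulked-segregant mapping of a recessive mutation in
a selfing species. A mutagenized line, homozygous for one causal SNP and a
set of background SNPs, is crossed to its progenitor; the F1 is
heterozygous at every line variant. Pooling F2 individuals selected for the
recessive phenotype fixes the causal allele in the pool, so the SNP index
(alt reads / total reads) is 1 at the causal locus, decays as 1 − r with
recombination fraction r along the chromosome, and sits at ½ at unlinked
loci. The assumptions are: full penetrance of the recessive phenotype
(selection keeps exactly the causal homozygotes), no segregation
distortion, and biallelic SNPs.

Variants shared between pools cannot be causal for a line-specific
phenotype: wild-type-versus-reference SNPs are fixed in every pool (index
≈ 1 everywhere) and would mimic causal peaks if not removed, which is why
cross-pool exclusion is part of the model rather than a cosmetic filter.
"Presence" of a SNP in another pool is defined as ≥ 2 supporting alt reads
(`presence_min_alt_reads`); a hard genotype call would be fragile at ~20×
pooled coverage, a single read is compatible with sequencing error.

## Forward simulation

`simulate_f2_pool` draws gametes as a Markov walk along the ordered variant
positions of each chromosome: the inter-site recombination fraction is
Haldane, r = (1 − e^(−2d))/2 with d in Morgans from the uniform cM/Mb rate,
and crossovers are interference-free, so the two-site recombination
fractions compose exactly (r13 = r12 + r23 − 2 r12 r23). Selection
simulates batches of F2 individuals and keeps causal homozygotes; if 100×
the requested pool size is simulated without filling the pool, a
`SimulationError` signals an implausible specification. Sequencing is
Poisson site depth with mean `depth` and binomial alt reads with success
probability f(1−e) + (1−f)e, where f is the true pooled frequency and e a
symmetric per-base error rate. The true f is retained on each record
(`true_alt_freq`, INFO/TF in VCF output) so tests can compare observation
to truth; the pipeline never reads it.

The mutagen spectrum defaults to 0.85 probability for G:C→A:T transitions
with the remaining 0.15 spread evenly over the other five strand-symmetric
substitution classes — sodium azide and EMS screens are dominated by that
transition class, and both worked codon changes in the examples are
G:C→A:T. The spectrum is configurable per line.

Quality metadata on simulated records is constant (MQ 60, BQ 35): the
mapping-quality and base-quality filters act upstream of the allele-count
records this pipeline starts from, so simulated records are born clean and
the filter operations are exercised by dedicated unit tests with varied
records.

### Scale of the toy genome

The default genome is 12 chromosomes × 10 Mb at 4 cM/Mb. The genetic
density is rice-like; the physical scale is reduced so that hundreds of F2
individuals over ~2000 variant sites simulate in well under a second. Ten
megabases per chromosome (40 cM) is the smallest scale at which the index
decays visibly below the 0.9 peak threshold within a chromosome arm, giving
peak calling genuine work to do. Replicate counts in the test suite and the
acceptance script (100 mapping replicates, 20 null and 50 planted
enrichment replicates) were chosen as the package's own study sizes: large
enough that the Monte-Carlo error of each checked rate is several times
smaller than the margin it is checked against.

## Mapping-stage parameters

- `FilterConfig`: MQ ≥ 30, BQ ≥ 20 (inclusive); total depth ≥ 5. The depth
  floor is this package's choice — indices from a handful of reads are too
  unstable to plot or average; records below it are flagged and excluded
  from the track, not errors.
- Window/step default 1 Mb / 100 kb on the toy scale, windows half-open
  internally and reported 1-based inclusive; windows with fewer than
  `min_sites_per_window` (default 1) sites are emitted with a missing mean.
- Peak threshold 0.9 operationalizes "index close to 1"; qualifying
  windows merge when separated by at most one window size, and a region
  must contain ≥ 3 supporting sites. Regions are ranked by mean site index,
  ties broken by genomic order; `top_site` is the highest-index site
  (lowest position on ties).

## Codon-effect annotation

The affected codon is located strand-aware (minus-strand variants are
complemented and codons read 5′→3′ on the coding strand) and translated
with the standard nuclear code from Biopython's table. Categories partition
all CDS point substitutions into synonymous/missense/nonsense; stop-loss is
reported as missense with a `stop_loss` flag. Variants in an intron within
2 bp of a CDS segment boundary are `splice-adjacent`; all other non-CDS
positions are `noncoding`. Domain coordinates are 1-based inclusive in
amino-acid space. Multi-nucleotide variants, indels and isoform resolution
are out of scope.

## Segregation test

χ² = Σ (max(|O − E| − c, 0))² / E with c = 0.5 (Yates) by default for
two-class tests and c = 0 otherwise; the clamp prevents negative
contributions when |O − E| < c. The continuity correction is the default
because it is the standard convention for one-degree-of-freedom tests on
hand-scored phenotype counts. Expected counts below 5 produce a warning,
not an error.

## DEG overlap and clustering

The DEG rule is P ≤ 0.05 AND |log2FC| ≥ 1, both inclusive; the fold-change
bound is two-sided because both up- and downregulated DEGs are analysed.
Direction is the sign of log2FC (a value of exactly 0 cannot pass the
bound, so every DEG has a direction). Percentages are rounded half-up to
one decimal, matching the convention of printed summary tables. Clustering
is complete-linkage on Euclidean distances (scipy), on both genes and
contrasts; missing values are an error unless zero-fill is requested.

The DEG simulator is constructive: membership "cells" (pattern of
contrast→direction, with a count) pin every intersection and concordance
count exactly, and only nuisance quantities are random — DEG P-values
uniform on (0, 0.05], |log2FC| = 1 + Exponential(0.8), non-DEG P-values
uniform on [0, 1] with |log2FC| < 1. Because no gene sits on a threshold
boundary by chance, passing overlap tests demonstrates the set algebra and
the threshold conventions, not robustness to borderline measurements —
real DEG tables have genes at the boundary and correlated P-values that
the simulator deliberately does not model. The bundled three-contrast
preset fixes its free parameters (the split of direction-discordant genes,
the double-mutant status of genes the printed figures do not pin down) to
the simplest consistent assignment.

## Enrichment

Each term's 2×2 table is DEG/non-DEG × in-term/out-of-term over the
expressed background (default detection floor: ≥ 2 reads). Both one-sided
hypergeometric tails are computed and the smaller reported with its
direction; a term with empty background intersection gets P = 1 and an
undefined direction. The permutation correction draws gene sets of DEG
size uniformly without replacement from the background, preserving the
annotation structure, and corrects per term:
corrected P = (1 + #{permuted P ≤ observed P}) / (1 + n_perm). The add-one
numerator and denominator keep corrected P in [1/(n_perm+1), 1] and make
the estimate slightly conservative. The alternative global reading of
"more or equal extreme cases" (counting significant terms per permutation)
is not implemented. Because the permuted statistic depends on the drawn set
only through each term's overlap count, the implementation precomputes each
term's P as a function of the count and reduces the permutation loop to a
membership-matrix product; a test verifies this equals naive recomputation.

The annotation simulator draws unplanted terms uniformly without
replacement — an exact null for calibration. A planted term of size s and
fold f takes Binomial(s, f·|target|/N) genes from the target (DEG-like)
subset, making its expected overlap f times the null expectation.

## Numerical conventions

- Coordinates are 1-based inclusive (VCF convention) everywhere a position
  is reported; window arithmetic is half-open internally.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  the simulation specs; identical seeds give identical outputs, and derived
  child seeds stay below 2³¹.
- Percentages use decimal half-up rounding, not banker's rounding.
- Equal-scoring peak regions order by (chromosome, start); equal corrected
  P-values order by term id.

## Known limitations

- No read-level simulation (FASTQ), alignment, or variant calling; the
  pipeline starts from allele-count records.
- No confidence band on the SNP index; peak calling is threshold-based.
- The F2 simulator models a single cross design with full penetrance; no
  phenotyping error, no segregation distortion, no interference.
- Enrichment uses flat annotations; no ontology-graph propagation.
- The clustering stage returns trees and leaf orders; figure rendering is
  a minimal heat map, not a full annotated dendrogram.
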