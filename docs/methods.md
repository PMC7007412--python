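# Methods

## Allele models and junction signatures

The locus is modelled as three alleles. The wild-type (p) carries a repeat R
(default 212 bp) immediately followed by a replaced segment X (default 10 bp,
`CTGGTATTCT`). The Celtic allele (P_C) is `prefix + R + R + suffix` where the
wild type is `prefix + R + X + suffix`, so len(P_C) − len(p) =
len(R) − len(X) = 202 bp for the defaults. The plasmid-integrated allele
(P_C\*) adds the donor backbone (default 3.9 kb) and a second HDR-template
copy (default 1.6 kb) at a configurable offset; the true block order and
orientation at the integration site are not publicly known, so the
arrangement is a parameter with default `[backbone(forward), hdr_copy]`
placed immediately 3' of the second repeat copy. All coordinates are 0-based
half-open internally; FASTA/BED/VCF I/O converts at the boundary.

Junction signatures are derived, not asserted: for each boundary of the
divergent region an error-free read centred on the junction is aligned to the
unedited reference with an affine-gap semi-global aligner, and the emergent
op pattern is recorded. For non-homologous synthetic sequence the repeat's 3'
junction yields a clean deletion of len(X); with the real sequences,
micro-homology shifts this to a longer deletion — which is why the deletion
length is never hard-coded. When the best linear alignment costs more than
25% of the read length (the repeat–repeat junction), the signature is
recorded as a split (match + clip) pattern, mirroring how a mapper reports a
supplementary alignment; the companion signature against the amended
reference is always a pure match.

## Read classification

Reads sharing at least one exact canonical 25-mer with the insertion sequence
are baited. "Shared ≥25 bp" is implemented as k-mer membership because it is
deterministic and equivalent for error-free stretches; lowering k via
configuration covers the error-tolerant case. Classification is by alignment
ops, independent of the engine: class A requires a pure match to the
reference (mismatch tolerance configurable, default 0); class B requires the
single alignment to equal a derived deletion signature; class C requires a
pure match on the amended reference, in which case the split placement on the
reference (primary + supplementary piece, split at the junction inferred from
the amended alignment) is attached. When both B and C could apply, B wins
(the single-alignment explanation is the more parsimonious and is what a
linear mapper reports). Reads explained by neither are UNEXPLAINED and carry
their alignments for review — with heavy sequencing error this is an expected
outcome, not a failure.

Alignment engines: locus-scale alignment uses biopython's PairwiseAligner
(match +1, mismatch −4, gap open −6, gap extend −1, free target overhangs);
genome-wide placement and long-read alignment use edlib (unit costs, banded),
with affine scores recomputed from the op list. Ectopic detection places each
baited read at its best genome-wide position on either strand, drops
placements intersecting the expected locus window, clusters the rest with a
one-read-length gap and reports clusters with ≥3 supporting reads.

## Plasmid screen and long-read assignment

Backbone screening aligns k-mer-prefiltered reads locally to the backbone
(the plasmid with the HDR insert masked out by alignment, so template
homology with the genome cannot inflate coverage) and computes per-base
depth; an animal is backbone-positive when the covered fraction reaches the
breadth threshold (default 0.25 — far below a real carrier's ~1.0 and far
above a clean animal's ~0, so the call is insensitive to the exact value).
Aligned segments must cover ≥30 bp at ≥90% identity to count.

Long-read assignment aligns each baited read (k = 15, ≥3 hits — chosen for
~10%-error reads, where an error-free 15-mer occurs every ~5 bp of true
overlap) to both allele models and assigns the read to the higher-scoring
model when (i) the score margin is at least 20 score units (about five
mismatches — large against noise, small against the hundreds of units a true
junction difference produces) and (ii) the read's footprint is diagnostic:
overlapping the insertion-unique interval on P_C\*, or spanning the
integration breakpoint with ≥50 anchored bases on each side on P_C. Whether
"support" in the original analysis required junction spanning is not stated;
this junction-spanning contract is this package's definition. An edit-distance
band of 45% of the read length speeds up alignment; reads whose true model is
rejected by the band are assigned by the surviving model (the margin is then
effectively infinite).

## Variant QC

Hard filters use the conventional semantics that a missing INFO annotation
leaves its rule unevaluated. The depth rule (DP > 3105 fails) is interpreted
as cohort-summed depth and is configurable per record. Site filters apply in
order — biallelic, genotype rate < 95%, MAF < 5% — with strict `<`
exclusions (a site at exactly the threshold is retained) and MAF computed on
non-missing allele counts. The engine is idempotent.

## Trio statistics

A Mendelian error is an offspring genotype that cannot receive one allele
from each parent; exactly 12 of the 27 genotype triples are errors. Sites
with any missing genotype in the trio are skipped (neither errors nor
tested) — the conservative convention. "Percentage per individual" is the
per-variant percentage divided by the three trio members; this is the only
reading consistent with all twelve published rows. Rates can be computed
against a fixed cohort-wide denominator (14,084,653 biallelic variants for
the packaged fixture) to reproduce published values without genotypes.

The group comparison is a one-way fixed-effects ANOVA of the twelve per-trio
per-variant percentages across the three study groups (6/3/3), giving 2 and
9 degrees of freedom; per-family averaging is rejected because it cannot
yield those df. Tukey HSD is the post-hoc convention (the original post-hoc
method is unstated). F and p come from scipy; the tests recompute them from
the sum-of-squares formula independently.

The hotspot scan tiles each contig into 10-kb half-open bins from zero,
excludes bins with ≤10 errors summed over all offspring, and flags the
remainder; among them, bins whose per-group error total exceeds 1 error per
kb (>10 errors per bin per group) in *all* groups are "consistently high".
Zero counts are replaced by 0.5 only on any log2 plotting path, never in
statistics.

`expected_error_rate` gives the exact per-variant error probability under
the generator's model: HWE parents at frequency p, Mendelian transmission,
and a symmetric single-step genotype-error channel (neighbouring genotypes
confused at rate eps, homozygote-to-opposite-homozygote at eps²), integrated
over the frequency distribution by 24-node Gauss–Legendre quadrature. This
error model is the documented simulation contract; real genotyping errors
are biased toward heterozygote miscalls in ways this symmetric model only
loosely approximates.

## VIF pruning, IBS and dendrograms

Pruning slides windows of 50 retained SNPs in steps of 5, computing each
site's VIF = 1/(1 − R²) as the diagonal of the inverted window correlation
matrix and removing the worst site until all VIFs ≤ 2. Exactly collinear
windows (duplicated sites, or more sites than samples) have no finite VIFs;
there the most redundant site (largest summed squared correlation) is
removed until the window regains full rank. The sliding pass repeats until
no window removes anything, so the retained set is a fixed point and
re-pruning removes nothing. Note the finite-sample caveat: VIF estimates
inflate as the window width approaches the sample count, so with few samples
a VIF-2 threshold prunes aggressively; this is a property of the statistic,
not of the implementation.

IBS counts heterozygote pairs as sharing state via 2 − |g_i − g_j|, summed
over sites non-missing in both samples; distance is 1 − IBS. Pairs with no
co-called sites get NA and a warning; trees refuse NA inputs. The
tree-building method behind the original dendrogram is unstated, so
average-linkage hierarchical clustering is the default with neighbor joining
(scikit-bio) behind a flag; samples are pre-sorted lexicographically so ties
break deterministically, and Newick output carries 6-decimal branch lengths.

## Synthetic data

The generator's defaults are the study conditions: 2×150-bp pairs at 20×
diploid depth with insert ~N(400, 60²) and 0.1% substitution error; long
reads at 14× with log-normal lengths (mean 10 kb, σ = 0.4) and 10% error
split 60/20/20 into substitutions/insertions/deletions; 12 sire/dam/offspring
trios in four families and three groups (6/3/3, 28 animals); allele
frequencies Uniform(0.05, 0.95); genotyping error 0.5% and missingness 0.2%
(the cohort's 99.8% genotyping rate). The 212-bp repeat, plasmid backbone and
genomic background are random sequences — the real ones are not public — with
hooks to substitute real sequences. Every stochastic stream is derived from
(seed, stream-name) via SHA-256, so runs are reproducible and adding an
animal does not perturb other streams. An optional per-family F_ST
(Balding–Nichols) models population structure for relatedness studies;
it defaults to 0 so the analytic error-rate expectation applies exactly.

What the generator does not emulate: chimeric long reads, PCR duplicates,
quality-score miscalibration, indel sequencing errors in short reads,
reference bias and LD beyond family structure. Passing tests therefore show
the *methods* behave as specified under controlled conditions, not that real
data would be as clean.

Problem sizes used by the test suite were chosen as desk-scale stand-ins for
the genome-scale originals: a 1-Mb genome for insertion-stability runs, 50-kb
genomes for the 20-seed plasmid-screen specificity check, a 200-kb genome for
long-read assignment, and 10⁵ sites for Mendel-rate recovery. Genome-scale
outcomes that depend on the real data (total variant counts, the 4,438
error-prone bins, the 171 consistently-high regions, the published 8-vs-12
long-read support counts) are out of numeric scope; only their procedures are
implemented and property-tested.

## Known limitations

* The classification contract is strict (pure match = zero mismatches by
  default); noisy reads fall to UNEXPLAINED rather than being force-fitted.
* Ectopic detection reports best-placement clusters; reads wholly inside an
  ectopic repeat copy place at the expected locus and do not contribute
  support, so detection rests on junction-overlapping reads.
* The backbone screen is presence/absence; integration copy number and
  orientation are out of scope.
* VCF support covers the annotations the filter engine consumes; it is not a
  general-purpose VCF toolkit.
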