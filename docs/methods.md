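# Methods

## Scope and data model

`clipcims` consumes aligned CLIP tags (SAM with CIGAR and MD, or the
package's tag BED) and produces binding peaks, base-resolution crosslink
sites, enriched motifs, gene annotations and splicing/qPCR
quantifications. Coordinates are 0-based half-open internally; GFF3 and
SAM conventions are converted only at I/O. A tag is one primary
alignment: interval, strand, mapping multiplicity and a list of mutation
records (substitution, deletion, insertion). Substitutions are recovered
from the MD tag, deletions and insertions from the CIGAR; a multi-base
deletion is a single record. Insertions are parsed but never feed CIMS:
the crosslink signature of interest is substitutions and deletions, each
analyzed as its own channel.

Adapter trimming, alignment and quality filtering are upstream of this
package; alignments are the entry point.

## Tag filtering

Reads mapping to multiple loci are discarded (multiplicity > 1, carried
in an NH-style field). PCR duplicates are collapsed on the full
coordinate key `(chrom, start, end, strand)` — start alone is too
aggressive when trimmed read lengths vary. The retained representative
is the tag with the most mutation records (ties: smallest read id), so
crosslink evidence is never thrown away by deduplication. The two
filters commute, so their order is immaterial; this is property-tested.

## Clustered peak calling

Same-strand overlapping tags are grouped by single linkage (touching
intervals do not merge, by the half-open convention) and each cluster is
trimmed to the span between the first and last position where depth
reaches `min_height` (default 2 — a lone tag is not a peak). The
significance score is the upper-tail Poisson surprise of the peak height
against the host gene's tag density:

    lambda = (tags overlapping the gene + 1) / gene length * peak width
    score  = -log10 P(X >= height | lambda)

The pseudocount of one tag per gene keeps empty backgrounds finite;
peaks outside any strand-matched gene fall back to a whole-chromosome
density. The score is monotone in height for a fixed background, which
is all the downstream top-fraction selection needs. Selection keeps the
`ceil(0.15 N)` highest-scoring peaks and includes every peak tied with
the boundary score, making the rule deterministic and order-independent.

## CIMS detection and permutation FDR

For each (position, strand, type), m counts tags mutated there and k the
tags covering the position. The null model preserves each tag's interval
and mutation count but re-places the mutations uniformly at random
within the tag, without within-tag collisions — the within-read
shuffling null standard for CIMS. With `n_permutations` draws (default
100, minimum 20 enforced):

    FDR(m0) = mean_perm #\{null sites with m >= m0\} / #\{observed sites with m >= m0\}

capped at 1, stratified by mutation type, and pooled over k: at toy
scale a (k, m) stratification would be far too sparse. The raw ratios
are then made monotone so a larger m never has a larger FDR (running
minimum over m' <= m, ascending). Sites with FDR < 0.01 and m > 5
(strict; a flag relaxes to >=) become CIMS peaks extended ±10 bases, with
ids `s<n>` / `d<n>` for the substitution / deletion channel, numbered by
ascending FDR then descending m.

Two independent oracles pin this down in the tests: an exhaustive
enumeration of all 20³ placements for three stacked single-mutation
tags (expected exceedance 20·(1/20)³ = 0.0025), and a calibration run on
the matched null simulation, where the fraction of sites reaching
FDR < 0.01 stays ≤ 2% and no peak is called.

## Motif enrichment

Foreground sequences are peak intervals extended 20 bases each side,
reverse-complemented for minus-strand peaks and emitted in the RNA
alphabet, so every sequence reads 5'→3' on the bound transcript.
Backgrounds are 100-base flanks separated from the peak by a 100-base
gap, same strand as the host peak (scanning only the transcribed strand
is the decision here; the flanks inherit local composition while
avoiding the bound footprint). Flanks overlapping any peak are dropped,
as are end-clipped flanks shorter than half the flank length.

Enrichment is computed per k-mer (default k = 8, configurable 4–12) on
scanned-position frequencies f (foreground) and b (background, floored
at 0.5/N_bg and kept below 1 − floor so the variance term is positive):

    z = (f - b) / sqrt(b (1 - b) / N_fg)

with a two-sided normal p. The top-ranked k-mers are greedily merged by
exact-overlap alignment (overlap ≥ k − 2) into a consensus; k-mers that
cannot be placed are reported unmerged, and the aligned supports yield a
position-frequency matrix whose columns sum to 1 (MEME minimal text on
output). This defined statistic replaces black-box motif discovery so
the whole computation is testable; it is deliberately not an EM/ZOOPS
motif finder and does not calibrate E-values.

## Annotation and downstream quantification

Peaks are assigned to every overlapping gene on the same strand
(antisense overlap never assigns; more than one gene flags the peak
ambiguous) and classified by maximal overlap among disjoint feature
intervals: UTRs are carved out of exons, introns are per-transcript gaps
minus any exonic sequence, and ties break exon > 5'UTR > 3'UTR >
intron. Composition fractions are reported over gene-assigned peaks and
sum to 1.

Gene-set overlap uses the upper-tail hypergeometric
P(X ≥ |A∩B|) over a declared universe, checked exactly against
combinatorial enumeration for every universe up to 25.

Intron-retention counting for alternative terminal exons requires full
containment of a read in the isoform-specific intron; junction-spanning
or partially overlapping reads count for neither intron, which keeps the
retention signal unambiguous at the cost of a few discarded reads.
Genotypes are compared by a two-tailed Student's t-test on per-replicate
ratios a/(a+b), reporting the mean ratio difference as the effect.

qPCR analysis is the 2^−ΔΔCt convention: ΔCt = Ct_target − Ct_reference,
ΔΔCt relative to the mean ΔCt of the baseline group, group comparison by
a two-tailed t-test on log2 folds. Paired mode ratios the two sides of
each animal (e.g. crushed / uncrushed nerve) before any summary and
tests the log2 ratios against zero. All folds are invariant under a
constant shift of every Ct in the table, which is asserted in tests.
When many targets are tested at once the raw p-values are reported per
gene; Benjamini–Hochberg correction is left to the caller since the
motivating assays test single genes.

## Synthetic data: what it emulates and what it does not

The generator is the package's study-condition definition, not a
convenience fixture. Defaults: 2 chromosomes × 200 kb, 20 non-overlapping
genes (four exons each; the first gene carries the two-terminal-exon
structure: shared exons, then intron_a + exon_a vs intron_b + exon_b),
one UGUGUGUG site planted per gene inside an intron, strand-adjusted so
the transcribed sequence equals the motif. Per site, Poisson(50) tags
containing the crosslink base (the motif center — a point target for
CIMS); each carries a substitution there with probability 0.3 or a
single-base deletion with probability 0.05. Background tags arrive at
0.1/kb uniformly; every tag additionally acquires one uniformly placed
random substitution with probability 0.1, which gives the null
calibration its uniform-mutation condition (the null configuration is
simply crosslink rates set to zero) and gives precision a non-trivial
noise floor. PCR duplicates are exact coordinate copies
(Poisson(0.1) per tag); multi-mapping is a multiplicity flag on 5% of
tags rather than emitted secondary alignments, since downstream only
needs the "unique" predicate. Tag lengths are Normal(36, 4) clipped to
[20, 200]. The crosslink substitution/deletion rates are free
parameters of the simulation, not estimates of any particular library.

RNA-seq reads over the two-isoform gene choose isoform A with the
configured fraction, fall inside the isoform-specific intron with the
retention rate (0.3) or inside an exon otherwise, and are single-block;
junction reads exist in real data but are irrelevant to the containment
counter and are exercised separately in unit tests. qPCR tables are
Ct = baseline − log2(expression) + N(0, σ) with an independent reference
gene.

Passing tests therefore demonstrate correct statistics under idealized
conditions — no sequencing errors beyond the modeled mutations, no
quality scores, no mappability structure, no overdispersion between
replicates, uniform background rather than expression-weighted
background. Real libraries violate all of these to some degree; the
recovery numbers here are upper bounds on, not predictions of, realized
performance.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.Generator` seeded from
explicit config fields; the pipeline splits one master seed into
per-stage seeds via `SeedSequence`, so disabling one stage never
perturbs another's stream, and a fixed seed reproduces every output
file byte for byte (asserted in tests). Poisson tails come from
`scipy.stats.poisson.sf` with the p floored at 1e-300 before the log;
CIMS peak scores floor the FDR at 1e-12. Degenerate inputs are defined
rather than accidental: empty tag sets produce empty peak lists, a zero
read depth produces an empty replicate, zero intron totals report a
missing ratio, and identical groups in any t-test report p = 1.

## Known limitations

- The permutation null conditions on tag intervals and mutation counts
  but not on sequence context; real RT artifacts have base preferences.
- FDR stratification pools over coverage k; with genome-scale site
  counts a (k, m) stratification would be sharper.
- The Poisson peak score ignores fragment-length autocorrelation between
  overlapping tags, so its absolute scale is optimistic; only its
  ranking is consumed.
- Merging of the two peak-calling arms reports union and intersection
  gene lists; any further curation of a final target list is manual by
  nature and out of scope.
- The consensus builder assumes the signal is a single contiguous motif;
  composite or bipartite motifs surface as unmerged k-mers instead.
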