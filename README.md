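# clipcims

CLIP-seq binding-site analysis for RNA-binding proteins, built around
crosslink-induced mutation sites (CIMS), with the downstream
alternative-splicing quantifications that typically follow a CLIP study.

CLIP-seq (crosslinking immunoprecipitation with sequencing) maps where a
protein touches RNA in vivo. Two signals identify binding sites in the
aligned reads ("tags"): pileups of overlapping tags, and positions where
reverse transcriptase introduced a substitution or deletion while reading
through the crosslinked base. `clipcims` implements both arms on a shared
filtered tag set, plus the k-mer motif enrichment, peak annotation and
splicing/qPCR quantifications needed to interpret the called sites. A
synthetic-data generator with full ground truth drives calibration and
recovery testing. The CELF-family proteins (worm UNC-75, mouse CELF2),
whose UG-repeat binding motif and Syntaxin splicing targets motivate the
defaults here, are the canonical use case.

## Methods in brief

- **Tag filtering** — PCR duplicates (identical `(chrom, start, end,
  strand)`) collapsed to one representative; multi-mapping reads
  (multiplicity > 1) removed.
- **Clustered peaks** — maximal single-linkage unions of overlapping
  same-strand tags, trimmed to the span with depth ≥ `min_height`; each
  peak scored as −log10 P(X ≥ height) under a Poisson background with
  gene-local expected density (pseudocount 1 tag/gene); the top 15% by
  score are selected, ties at the boundary included.
- **CIMS peaks** — per position, strand and mutation type, m = tags
  mutated there out of k covering tags. The null re-places every tag's
  mutations uniformly within the tag; FDR(m₀) = E[null sites with
  m ≥ m₀] / #observed sites with m ≥ m₀, monotone in m. Sites with
  FDR < 0.01 and m > 5 become peaks (± 10 bases).
- **Motif enrichment** — peak sequences ± 20 bases vs 100-base flanks
  100 bases away; per 8-mer z = (f − b)/√(b(1 − b)/N), greedy
  overlap-merge of top k-mers into a consensus with a PFM.
- **Annotation & splicing** — maximal-overlap feature class (intron /
  exon / UTRs), hypergeometric gene-set overlap, intron-retention read
  counts for alternative terminal exons (full containment only), and
  2^−ΔΔCt qPCR fold changes with paired (two sides per animal) support.

## Worked example

```python
from clipcims import (SimConfig, generate_genome, simulate_clip_tags,
                      remove_duplicates, filter_unique,
                      tabulate_mutation_sites, estimate_fdr, call_cims_peaks)

genome = generate_genome(SimConfig(seed=1))        # 2 chromosomes, 20 genes,
tags = filter_unique(remove_duplicates(            # one UGUGUGUG site per gene
    simulate_clip_tags(genome).tags))
sites = estimate_fdr(tabulate_mutation_sites(tags), tags,
                     n_permutations=100, seed=7)
peaks = call_cims_peaks(sites, fdr_max=0.01, m_min=5)
```

Running `python examples/cims_detection.py` (the same computation) prints:

```
114 candidate mutation sites (max m = 21 mutated tags at one position)
19 CIMS peaks pass FDR < 0.01 and m > 5
  s1: chr1:172665-172686 m=21 k=59
recall vs planted truth: 19/20
```

114 genomic positions carry at least one mutation; after the permutation
FDR, 19 survive the FDR < 0.01, m > 5 rule. `s1` is a substitution-type
site where 21 of 59 covering tags are mutated at one base — a crosslink
signature far beyond what uniform mutation placement produces. 19 of the
20 planted sites are recovered (the miss drew an unusually low tag count).
The other examples cover clustered peak calling, motif discovery
(UGUGUGUG ranks first, z ≈ 41), isoform-ratio recovery and ΔΔCt analysis;
`examples/full_pipeline.py` runs everything through one seeded
`run_pipeline` call. The same stages are exposed on the command line as
`clipcims simulate|tags|peaks|cims|motif|annotate|introns|qpcr|run`.

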