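"""Rank k-mers enriched in peak sequences against flanking backgrounds.

Peak sequences are extended 20 bases each side; backgrounds are 100-base
flanks placed 100 bases away from each peak. Enrichment is a z score on
per-position k-mer frequencies, and the top k-mers are greedily merged
into a consensus.
"""

from clipcims import (
    SimConfig, generate_genome, simulate_clip_tags,
    remove_duplicates, filter_unique, cluster_tags, score_peaks,
    extract_peak_sequences, extract_background, kmer_enrichment, build_consensus,
)

genome = generate_genome(SimConfig(seed=1))
tags = filter_unique(remove_duplicates(simulate_clip_tags(genome).tags))
peaks = score_peaks(cluster_tags(tags, 2), tags, genome.genes, genome.chrom_sizes)

fg = extract_peak_sequences(peaks, genome.sequences, extension=20)
bg = extract_background(peaks, genome.sequences, flank_len=100, gap=100)
print(f"{len(fg)} peak sequences vs {len(bg)} flanking background windows")

table = kmer_enrichment(fg, bg, k=8)
print("top 5 enriched 8-mers (z = enrichment over flanks):")
for row in table.head(5).itertuples():
    print(f"  {row.kmer}  fg={row.fg_count}  bg={row.bg_count}  z={row.z:.1f}")

result = build_consensus(table)
print(f"consensus motif: {result.consensus}")
# the planted UGUGUGUG should rank first; overlapping shifted k-mers
# (GUGUGUGU etc.) merge into a longer UG-repeat consensus
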