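"""Simulate a CLIP experiment and call binding peaks by tag clustering.

Generates a toy genome with UGUGUGUG sites planted in introns, piles CLIP
tags on them, applies the standard filtering (PCR-duplicate removal,
unique-mappers only), clusters overlapping tags into peaks and scores each
peak against its host gene's background tag density.
"""

from clipcims import (
    SimConfig, generate_genome, simulate_clip_tags,
    remove_duplicates, filter_unique,
    cluster_tags, score_peaks, select_top_fraction,
)

genome = generate_genome(SimConfig(seed=1))
sim = simulate_clip_tags(genome)
print(f"simulated {sim.counts['total']} tags: {sim.counts['site_tags']} on "
      f"{len(genome.sites)} planted sites, {sim.counts['background_tags']} background, "
      f"{sim.counts['duplicates']} PCR duplicates")

tags = filter_unique(remove_duplicates(sim.tags))
print(f"{len(tags)} tags survive dedup + unique-mapping filter")

peaks = score_peaks(cluster_tags(tags, min_height=2), tags,
                    genome.genes, genome.chrom_sizes)
top = select_top_fraction(peaks, 0.15)
print(f"{len(peaks)} peaks called; top 15% by significance = {len(top)} peaks")
for p in sorted(top, key=lambda p: -p.score)[:3]:
    print(f"  {p.id}: {p.chrom}:{p.start}-{p.end} ({p.strand}) "
          f"height={p.height} score={p.score:.1f}")
# the score is -log10 of the Poisson tail probability of seeing that tag
# height given the gene-local background, so 60+ means a towering pileup
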