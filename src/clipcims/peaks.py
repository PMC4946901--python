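"""Peak calling by tag clustering (the "without CIMS" arm).

Overlapping same-strand tags are grouped by single linkage into clusters;
each cluster is trimmed to the span where tag depth reaches ``min_height``
and scored against a gene-local Poisson background. The top-scoring
fraction of peaks (default 15%) forms the selected peak set.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

from .model import AlignedTag, GeneModel, Peak, overlap_len

_MIN_P = 1e-300  # floor before -log10 so scores stay finite


def cluster_tags(tags: Iterable[AlignedTag], min_height: int = 2) -> list[Peak]:
    """Group overlapping same-strand tags into peaks.

    Peaks are maximal single-linkage unions of overlapping tag intervals,
    trimmed to the span between the first and last position where depth
    >= ``min_height``. Clusters that never reach ``min_height`` are
    dropped. Per strand, peaks are disjoint and each retained tag overlaps
    exactly one peak.
    """
    if min_height < 1:
        raise ValueError("min_height must be >= 1")
    by_group: dict[tuple[str, str], list[AlignedTag]] = {}
    for t in tags:
        by_group.setdefault((t.chrom, t.strand), []).append(t)

    peaks: list[Peak] = []
    for (chrom, strand), group in by_group.items():
        group.sort(key=lambda t: (t.start, t.end))
        cluster: list[AlignedTag] = []
        cluster_end = -1
        for t in group + [None]:  # sentinel flushes the last cluster
            if t is not None and (not cluster or t.start < cluster_end):
                cluster.append(t)
                cluster_end = max(cluster_end, t.end)
                continue
            if cluster:
                peak = _call_cluster(chrom, strand, cluster, min_height)
                if peak is not None:
                    peaks.append(peak)
            if t is not None:
                cluster = [t]
                cluster_end = t.end
    peaks.sort(key=lambda p: (p.chrom, p.start, p.strand))
    for i, p in enumerate(peaks, 1):
        p.id = f"p{i}"
    return peaks


def _call_cluster(
    chrom: str, strand: str, cluster: Sequence[AlignedTag], min_height: int
) -> Optional[Peak]:
    """Depth-trim one cluster; None if depth never reaches min_height."""
    events: dict[int, int] = {}
    for t in cluster:
        events[t.start] = events.get(t.start, 0) + 1
        events[t.end] = events.get(t.end, 0) - 1
    depth = 0
    max_depth = 0
    first = last = None
    breaks = sorted(events)
    for i, pos in enumerate(breaks):
        depth += events[pos]
        nxt = breaks[i + 1] if i + 1 < len(breaks) else pos
        if depth >= min_height and pos < nxt:
            if first is None:
                first = pos
            last = nxt
        max_depth = max(max_depth, depth)
    if first is None:
        return None
    n_tags = sum(1 for t in cluster if overlap_len((t.start, t.end), (first, last)) > 0)
    return Peak(
        chrom=chrom, start=first, end=last, strand=strand,
        height=max_depth, n_tags=n_tags,
    )


def score_peaks(
    peaks: Sequence[Peak],
    tags: Sequence[AlignedTag],
    genes: Sequence[GeneModel],
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> list[Peak]:
    """Score peaks as -log10 of the upper-tail Poisson probability.

    The expected tag count in a peak window is the host gene's tag density
    (tags overlapping the gene plus a pseudocount of 1, over the gene
    length) times the window width. Peaks without a strand-matched host
    gene fall back to a whole-chromosome background. The score is
    monotone in height for a fixed background.
    """
    gene_tag_count: dict[str, int] = {g.gene_id: 0 for g in genes}
    by_chrom_strand: dict[tuple[str, str], int] = {}
    for t in tags:
        by_chrom_strand[(t.chrom, t.strand)] = by_chrom_strand.get((t.chrom, t.strand), 0) + 1
        for g in genes:
            if g.chrom == t.chrom and g.strand == t.strand and overlap_len(
                (t.start, t.end), (g.start, g.end)
            ) > 0:
                gene_tag_count[g.gene_id] += 1

    chrom_extent: dict[str, int] = dict(chrom_sizes or {})
    for t in tags:
        chrom_extent[t.chrom] = max(chrom_extent.get(t.chrom, 1), t.end)

    for peak in peaks:
        host = None
        host_ov = 0
        for g in genes:
            if g.chrom != peak.chrom or g.strand != peak.strand or g.length == 0:
                continue
            ov = overlap_len((peak.start, peak.end), (g.start, g.end))
            if ov > host_ov:
                host, host_ov = g, ov
        if host is not None:
            density = (gene_tag_count[host.gene_id] + 1) / host.length
        else:
            n = by_chrom_strand.get((peak.chrom, peak.strand), 0)
            density = (n + 1) / chrom_extent.get(peak.chrom, 1)
        expected = density * (peak.end - peak.start)
        p = stats.poisson.sf(peak.height - 1, expected)
        peak.score = -math.log10(max(float(p), _MIN_P))
    return list(peaks)


def select_top_fraction(peaks: Sequence[Peak], fraction: float = 0.15) -> list[Peak]:
    """The ceil(fraction*N) highest-scoring peaks, boundary ties included."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    if not peaks:
        return []
    ranked = sorted(peaks, key=lambda p: -p.score)
    n = math.ceil(fraction * len(ranked))
    boundary = ranked[n - 1].score
    return [p for p in ranked if p.score >= boundary]
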