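"""Peak annotation, gene-set overlap, and intron-retention quantification."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .model import (
    AlignedTag,
    GeneModel,
    Peak,
    overlap_len,
    subtract_intervals,
    total_overlap,
)

# classification priority on exact overlap ties
_CLASS_ORDER = ("exon", "5'UTR", "3'UTR", "intron")


@dataclass
class PeakAnnotation:
    peak_id: str
    gene_ids: tuple[str, ...]
    feature: str  # intron / exon / 5'UTR / 3'UTR / intergenic
    ambiguous: bool = False


@dataclass
class IsoformCounts:
    """Reads fully contained in the isoform-specific introns of one replicate."""

    genotype: str
    replicate: str
    count_intron_a: int
    count_intron_b: int

    @property
    def ratio_a(self) -> Optional[float]:
        total = self.count_intron_a + self.count_intron_b
        return self.count_intron_a / total if total else None


def _feature_intervals(gene: GeneModel) -> dict[str, list[tuple[int, int]]]:
    """Disjoint per-class intervals: UTRs carved out of exons, introns minus exons."""
    exons = gene.exon_union()
    utrs = [iv for iv in (gene.utr5, gene.utr3) if iv is not None]
    return {
        "exon": subtract_intervals(exons, utrs),
        "5'UTR": [gene.utr5] if gene.utr5 else [],
        "3'UTR": [gene.utr3] if gene.utr3 else [],
        "intron": gene.intron_union(),
    }


def annotate_peaks(
    peaks: Sequence[Peak], genes: Sequence[GeneModel]
) -> tuple[list[PeakAnnotation], dict[str, float]]:
    """Classify each peak by its maximal-overlap feature class.

    A peak is assigned to every strand-matched overlapping gene (flagged
    ambiguous when more than one) and classified by the feature class with
    the largest total overlap across its genes; ties break in the order
    exon > 5'UTR > 3'UTR > intron. Peaks with no gene are intergenic.
    The returned composition is the class fraction over gene-assigned
    peaks and sums to 1.
    """
    usable = []
    for g in genes:
        if not g.exon_union():
            warnings.warn(f"gene {g.gene_id} has no exons; skipped", stacklevel=2)
            continue
        usable.append(g)
    features = {g.gene_id: _feature_intervals(g) for g in usable}

    annotations = []
    class_counts: dict[str, int] = {}
    for peak in peaks:
        iv = (peak.start, peak.end)
        hosts = [
            g
            for g in usable
            if g.chrom == peak.chrom
            and g.strand == peak.strand
            and overlap_len(iv, (g.start, g.end)) > 0
        ]
        if not hosts:
            annotations.append(PeakAnnotation(peak.id, (), "intergenic"))
            continue
        best_class, best_ov = "intron", -1
        for cls in _CLASS_ORDER:
            ov = sum(total_overlap(iv, features[g.gene_id][cls]) for g in hosts)
            if ov > best_ov:
                best_class, best_ov = cls, ov
        annotations.append(
            PeakAnnotation(
                peak.id, tuple(g.gene_id for g in hosts), best_class,
                ambiguous=len(hosts) > 1,
            )
        )
        class_counts[best_class] = class_counts.get(best_class, 0) + 1

    n_assigned = sum(class_counts.values())
    composition = {
        cls: class_counts.get(cls, 0) / n_assigned if n_assigned else 0.0
        for cls in _CLASS_ORDER
    }
    return annotations, composition


def gene_set_overlap(
    targets: Iterable[str], reference: Iterable[str], universe: Iterable[str]
) -> tuple[list[str], float]:
    """Intersection of two gene sets with an upper-tail hypergeometric p.

    p = P(X >= |overlap|) for X ~ Hypergeom(|universe|, |reference|,
    |targets|). Both sets must be subsets of the universe.
    """
    targets, reference, universe = set(targets), set(reference), set(universe)
    offenders = sorted((targets | reference) - universe)
    if offenders:
        raise ValueError(f"set elements outside universe: {offenders}")
    overlap = sorted(targets & reference)
    p = float(stats.hypergeom.sf(len(overlap) - 1, len(universe), len(reference), len(targets)))
    return overlap, min(1.0, p)


def count_intron_reads(
    reads: Sequence[AlignedTag],
    intron_a: tuple[int, int],
    intron_b: tuple[int, int],
    genotype: str = "",
    replicate: str = "",
) -> IsoformCounts:
    """Count reads fully contained in each isoform-specific intron.

    Junction-spanning or partially overlapping reads count for neither
    intron, so the retention signal is unambiguous.
    """
    if overlap_len(intron_a, intron_b) > 0:
        raise ValueError("intron_a and intron_b must not overlap")
    a = sum(1 for r in reads if intron_a[0] <= r.start and r.end <= intron_a[1])
    b = sum(1 for r in reads if intron_b[0] <= r.start and r.end <= intron_b[1])
    return IsoformCounts(genotype, replicate, a, b)


@dataclass
class RatioComparison:
    baseline_genotype: str
    test_genotype: str
    baseline_mean: float
    test_mean: float
    effect: float  # test mean ratio_a - baseline mean ratio_a
    t_statistic: float
    p_value: float


def compare_intron_ratios(
    counts: Sequence[IsoformCounts], baseline_genotype: str = "wt"
) -> RatioComparison:
    """Two-sample two-tailed Student's t on per-replicate intron-a ratios."""
    groups: dict[str, list[float]] = {}
    for c in counts:
        if c.ratio_a is None:
            continue
        groups.setdefault(c.genotype, []).append(c.ratio_a)
    if baseline_genotype not in groups:
        raise ValueError(f"no replicates for baseline genotype {baseline_genotype!r}")
    others = [g for g in groups if g != baseline_genotype]
    if len(others) != 1:
        raise ValueError("expected exactly two genotypes")
    test = others[0]
    base_r, test_r = groups[baseline_genotype], groups[test]
    if len(base_r) < 2 or len(test_r) < 2:
        raise ValueError("need >= 2 replicates per genotype")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-identical groups
        t, p = stats.ttest_ind(test_r, base_r)
    if np.isnan(p):  # zero variance in both groups, identical means
        t, p = 0.0, 1.0
    return RatioComparison(
        baseline_genotype=baseline_genotype, test_genotype=test,
        baseline_mean=float(np.mean(base_r)), test_mean=float(np.mean(test_r)),
        effect=float(np.mean(test_r) - np.mean(base_r)),
        t_statistic=float(t), p_value=float(p),
    )
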