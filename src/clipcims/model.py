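"""Core domain types for the CLIP-seq analysis.

Coordinates are 0-based half-open everywhere inside the library; conversion
to the 1-based closed convention of GFF3/SAM happens only at I/O boundaries
(:mod:`clipcims.io`). Strand is ``"+"`` or ``"-"``. Genomic sequences are
stored in the DNA alphabet; conversion to RNA (T->U) happens at sequence
extraction time in :mod:`clipcims.motif`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

STRANDS = ("+", "-")
MUTATION_TYPES = ("substitution", "deletion", "insertion")
#: mutation channels that feed CIMS analysis (insertions are parsed but ignored)
CIMS_TYPES = ("substitution", "deletion")

FEATURE_CLASSES = ("intron", "exon", "5'UTR", "3'UTR", "intergenic")


@dataclass(frozen=True, order=True)
class Mutation:
    """A single mismatch event between a read and the reference.

    ``position`` is the genomic coordinate (0-based) of the first affected
    reference base. Multi-base deletions are one record whose ``ref_base``
    holds all deleted bases; ``obs_base`` is empty for deletions and holds
    the inserted bases for insertions.
    """

    position: int
    type: str
    ref_base: str = ""
    obs_base: str = ""

    def __post_init__(self) -> None:
        if self.type not in MUTATION_TYPES:
            raise ValueError(f"unknown mutation type {self.type!r}")
        if self.position < 0:
            raise ValueError("mutation position must be >= 0")

    @property
    def ref_span(self) -> int:
        """Number of reference bases consumed (0 for insertions)."""
        if self.type == "substitution":
            return 1
        if self.type == "deletion":
            return max(1, len(self.ref_base))
        return 0


@dataclass(frozen=True)
class AlignedTag:
    """One mapped CLIP or RNA-seq read ("tag") with its mutation records."""

    chrom: str
    start: int
    end: int
    strand: str
    mutations: tuple[Mutation, ...] = ()
    multiplicity: int = 1
    read_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"tag {self.read_id!r}: start must be < end")
        if self.strand not in STRANDS:
            raise ValueError(f"tag {self.read_id!r}: strand must be + or -")
        if self.multiplicity < 1:
            raise ValueError(f"tag {self.read_id!r}: multiplicity must be >= 1")
        for mut in self.mutations:
            if not (self.start <= mut.position < self.end):
                raise ValueError(
                    f"tag {self.read_id!r}: mutation at {mut.position} outside "
                    f"[{self.start}, {self.end})"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def coord_key(self) -> tuple[str, int, int, str]:
        """The PCR-duplicate key: full coordinates plus strand."""
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class Peak:
    """A called binding region.

    ``provenance`` is ``"clustered"`` for tag-pileup peaks and ``"cims"``
    for peaks anchored on a crosslink-induced mutation site; merged peaks
    carry a ``"+"``-joined combination.
    """

    chrom: str
    start: int
    end: int
    strand: str
    height: int
    n_tags: int
    score: float = 0.0
    provenance: str = "clustered"
    id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("peak start must be < end")
        if self.height < 1:
            raise ValueError("peak height must be >= 1")
        if self.score < 0:
            raise ValueError("peak score must be >= 0")


@dataclass
class MutationSite:
    """A genomic position carrying reproducible mutation evidence.

    ``k`` is the number of tags spanning the position, ``m`` the number of
    tags carrying a mutation of ``type`` there. ``fdr`` is filled in by the
    permutation test; NaN until estimated.
    """

    chrom: str
    position: int
    strand: str
    type: str
    k: int
    m: int
    fdr: float = float("nan")

    def __post_init__(self) -> None:
        if self.type not in CIMS_TYPES:
            raise ValueError(f"CIMS site type must be one of {CIMS_TYPES}")
        if not (0 <= self.m <= self.k):
            raise ValueError("site requires 0 <= m <= k")
        if self.fdr == self.fdr and not (0.0 <= self.fdr <= 1.0):  # not NaN
            raise ValueError("fdr must lie in [0, 1]")


@dataclass(frozen=True)
class Transcript:
    """A transcript as an ordered tuple of exon intervals (0-based half-open)."""

    id: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.exons:
            if s >= e or s < prev_end:
                raise ValueError(f"transcript {self.id}: exons must be sorted, disjoint")
            prev_end = e

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i][1] < self.exons[i + 1][0]
        )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class GeneModel:
    """A gene with one or more transcripts and optional UTR annotations.

    Genes with alternative terminal exons (the Syntaxin-like two-isoform
    structure) additionally expose ``intron_a``/``intron_b`` — the
    isoform-specific introns used for retention read counting.
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]
    utr5: Optional[tuple[int, int]] = None
    utr3: Optional[tuple[int, int]] = None
    intron_a: Optional[tuple[int, int]] = None
    intron_b: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id}: needs >= 1 transcript")

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def has_alt_terminal_exons(self) -> bool:
        return self.intron_a is not None and self.intron_b is not None

    def exon_union(self) -> list[tuple[int, int]]:
        return merge_intervals(iv for t in self.transcripts for iv in t.exons)

    def intron_union(self) -> list[tuple[int, int]]:
        """Union of per-transcript introns, minus any exonic sequence."""
        raw = merge_intervals(iv for t in self.transcripts for iv in t.introns)
        return subtract_intervals(raw, self.exon_union())


# ---------------------------------------------------------------------------
# interval helpers


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, returned sorted and disjoint."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def total_overlap(iv: tuple[int, int], others: Sequence[tuple[int, int]]) -> int:
    return sum(overlap_len(iv, o) for o in others)


def subtract_intervals(
    base: Sequence[tuple[int, int]], minus: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference of half-open interval lists (both may be unsorted)."""
    result: list[tuple[int, int]] = []
    cuts = merge_intervals(minus)
    for s, e in merge_intervals(base):
        cur = s
        for cs, ce in cuts:
            if ce <= cur or cs >= e:
                continue
            if cs > cur:
                result.append((cur, cs))
            cur = max(cur, ce)
            if cur >= e:
                break
        if cur < e:
            result.append((cur, e))
    return result
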