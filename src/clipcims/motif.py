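"""K-mer motif enrichment of peak sequences against flanking backgrounds.

Foreground sequences are peak intervals extended 20 bases on both sides;
background sequences are 100-base flanks placed 100 bases away from each
peak, mirroring the standard peak-vs-flank contrast. Enrichment is a
per-k-mer z score on scanned-position frequencies, and the top k-mers are
greedily merged by overlap into a consensus with a position-frequency
matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import Peak, overlap_len

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
RNA_ROWS = "ACGU"


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass
class MotifResult:
    """Consensus motif with its supporting k-mer table and PFM."""

    consensus: str
    table: pd.DataFrame
    pfm: np.ndarray  # 4 x len(consensus), rows A/C/G/U, columns sum to 1
    unmerged: list[str] = field(default_factory=list)
    empty: bool = False


def extract_peak_sequences(
    peaks: Sequence[Peak], genome: Mapping[str, str], extension: int = 20
) -> list[str]:
    """Peak sequences with ``extension`` bases added on both sides.

    Windows are clipped to chromosome bounds; minus-strand peaks are
    reverse-complemented so every sequence reads 5'->3' on the bound RNA.
    Output is in the RNA alphabet.
    """
    out = []
    for p in peaks:
        if p.chrom not in genome:
            raise KeyError(f"peak {p.id or p}: unknown chromosome {p.chrom!r}")
        seq = genome[p.chrom]
        s = max(0, p.start - extension)
        e = min(len(seq), p.end + extension)
        window = seq[s:e].upper()
        if p.strand == "-":
            window = _revcomp(window)
        out.append(_to_rna(window))
    return out


def extract_background(
    peaks: Sequence[Peak],
    genome: Mapping[str, str],
    flank_len: int = 100,
    gap: int = 100,
) -> list[str]:
    """Flanking background windows: ``flank_len`` bases, ``gap`` away.

    Per peak, a left window [start-gap-flank_len, start-gap) and a right
    window [end+gap, end+gap+flank_len). Windows overlapping any peak on
    the same chromosome are dropped; windows clipped by chromosome ends
    are dropped when shorter than flank_len/2. Strand handling matches the
    host peak.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    out = []
    for p in peaks:
        seq = genome.get(p.chrom)
        if seq is None:
            raise KeyError(f"peak {p.id or p}: unknown chromosome {p.chrom!r}")
        for ws, we in (
            (p.start - gap - flank_len, p.start - gap),
            (p.end + gap, p.end + gap + flank_len),
        ):
            cs, ce = max(0, ws), min(len(seq), we)
            if ce - cs < flank_len / 2:
                continue
            if any(overlap_len((cs, ce), iv) > 0 for iv in by_chrom[p.chrom]):
                continue
            window = seq[cs:ce].upper()
            if p.strand == "-":
                window = _revcomp(window)
            out.append(_to_rna(window))
    return out


def _count_kmers(seqs: Sequence[str], k: int) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}
    n_positions = 0
    short_seen = False
    for seq in seqs:
        if len(seq) < k:
            if not short_seen:
                warnings.warn(f"sequence shorter than k={k} skipped", stacklevel=3)
                short_seen = True
            continue
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            counts[kmer] = counts.get(kmer, 0) + 1
            n_positions += 1
    return counts, n_positions


def kmer_enrichment(
    fg_seqs: Sequence[str], bg_seqs: Sequence[str], k: int = 8
) -> pd.DataFrame:
    """Rank k-mers by z score of foreground vs background frequency.

    Frequencies are per scanned position. The background frequency is
    floored at 0.5 / (background positions) to avoid zero division. The z
    score is (f - b) / sqrt(b (1 - b) / N_fg) with a two-sided normal p.
    """
    if not (2 <= k <= 16):
        raise ValueError("k must lie in [2, 16]")
    if not fg_seqs or not bg_seqs:
        raise ValueError("foreground and background sequence sets must be non-empty")
    fg_counts, n_fg = _count_kmers([_to_rna(s) for s in fg_seqs], k)
    bg_counts, n_bg = _count_kmers([_to_rna(s) for s in bg_seqs], k)
    if n_fg == 0 or n_bg == 0:
        raise ValueError("no scannable positions (all sequences shorter than k?)")
    floor = 0.5 / n_bg
    rows = []
    for kmer in sorted(set(fg_counts) | set(bg_counts)):
        fc = fg_counts.get(kmer, 0)
        bc = bg_counts.get(kmer, 0)
        f = fc / n_fg
        b = min(max(bc / n_bg, floor), 1.0 - floor)  # keep the variance term > 0
        z = (f - b) / np.sqrt(b * (1 - b) / n_fg)
        p = 2 * stats.norm.sf(abs(z))
        rows.append((kmer, fc, bc, f, b, z, p))
    df = pd.DataFrame(
        rows, columns=["kmer", "fg_count", "bg_count", "fg_freq", "bg_freq", "z", "p"]
    )
    return df.sort_values(["z", "kmer"], ascending=[False, True], ignore_index=True)


def _best_merge(consensus: str, kmer: str, min_overlap: int) -> Optional[int]:
    """Best offset of kmer against consensus with exact-match overlap.

    Returns the offset (possibly negative) maximizing overlap length, or
    None if no placement reaches ``min_overlap`` matching characters.
    """
    best_off, best_ov = None, min_overlap - 1
    for off in range(-(len(kmer) - min_overlap), len(consensus) - min_overlap + 1):
        lo = max(0, off)
        hi = min(len(consensus), off + len(kmer))
        if hi - lo <= best_ov:
            continue
        if consensus[lo:hi] == kmer[lo - off : hi - off]:
            best_off, best_ov = off, hi - lo
    return best_off


def build_consensus(table: pd.DataFrame, top_n: int = 10) -> MotifResult:
    """Greedy overlap merge of the top-ranked k-mers into a consensus.

    K-mers are taken in rank order; each is merged into the growing
    consensus at its best exact-overlap placement (overlap >= k - 2) or
    reported unmerged. The PFM columns are frequencies over the aligned
    supporting k-mers and each sums to 1.
    """
    positive = table[table["z"] > 0].head(top_n)
    if positive.empty:
        return MotifResult(
            consensus="", table=table, pfm=np.zeros((4, 0)), empty=True
        )
    kmers = list(positive["kmer"])
    k = len(kmers[0])
    consensus = kmers[0]
    aligned: list[tuple[str, int]] = [(kmers[0], 0)]
    unmerged: list[str] = []
    for kmer in kmers[1:]:
        off = _best_merge(consensus, kmer, min_overlap=k - 2)
        if off is None:
            unmerged.append(kmer)
            continue
        if off < 0:
            consensus = kmer[:-off] + consensus
            aligned = [(s, o - off) for s, o in aligned]
            off = 0
        if off + len(kmer) > len(consensus):
            consensus = consensus + kmer[len(consensus) - off :]
        aligned.append((kmer, off))

    pfm_counts = np.zeros((4, len(consensus)))
    row = {b: i for i, b in enumerate(RNA_ROWS)}
    for kmer, off in aligned:
        for j, base in enumerate(kmer):
            if base in row:
                pfm_counts[row[base], off + j] += 1
    col_sums = pfm_counts.sum(axis=0)
    col_sums[col_sums == 0] = 1
    pfm = pfm_counts / col_sums
    return MotifResult(consensus=consensus, table=table, pfm=pfm, unmerged=unmerged)
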