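"""Tag processing: alignment parsing and the CLIP filtering contract.

A "tag" is a single mapped read. The filtering contract mirrors standard
CLIP practice: reads mapping to multiple coordinates are discarded, and
coordinate-identical reads (PCR amplification artifacts) are collapsed to
one representative. Both filters commute, so their order is immaterial.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .model import AlignedTag, Mutation


def parse_alignments(sam_path: str | Path) -> list[AlignedTag]:
    """Parse primary alignments from a SAM file into tags.

    Substitutions are recovered from the MD tag (via the aligned-pairs
    reference reconstruction), deletions and insertions from the CIGAR.
    Unmapped, secondary and supplementary records are skipped. Records
    lacking an MD tag yield a warning and an empty substitution list.
    """
    tags: list[AlignedTag] = []
    md_warned = False
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            muts: list[Mutation] = []
            start = rec.reference_start
            end = rec.reference_end
            # deletions / insertions from CIGAR
            qpos, rpos = 0, start
            qseq = rec.query_sequence or ""
            for op, length in rec.cigartuples or ():
                if op in (0, 7, 8):  # M, =, X
                    qpos += length
                    rpos += length
                elif op == 1:  # I
                    muts.append(
                        Mutation(
                            position=min(rpos, end - 1), type="insertion",
                            ref_base="", obs_base=qseq[qpos : qpos + length],
                        )
                    )
                    qpos += length
                elif op == 2:  # D
                    muts.append(
                        Mutation(position=rpos, type="deletion", ref_base="N" * length)
                    )
                    rpos += length
                elif op in (4,):  # S
                    qpos += length
                elif op == 3:  # N
                    rpos += length
            # substitutions from MD
            if rec.has_tag("MD"):
                for q, r, ref in rec.get_aligned_pairs(with_seq=True):
                    if q is None or r is None or ref is None:
                        continue
                    if ref.islower():
                        muts.append(
                            Mutation(
                                position=r, type="substitution",
                                ref_base=ref.upper(), obs_base=qseq[q].upper(),
                            )
                        )
                # refine deletion reference bases from MD, best effort
                md_dels = _md_deletion_bases(rec.get_tag("MD"))
                if md_dels:
                    di = 0
                    refined = []
                    for m in muts:
                        if m.type == "deletion" and di < len(md_dels):
                            refined.append(
                                Mutation(m.position, "deletion", md_dels[di], "")
                            )
                            di += 1
                        else:
                            refined.append(m)
                    muts = refined
            elif not md_warned:
                warnings.warn(
                    f"{sam_path}: records without MD tag; substitutions not extracted",
                    stacklevel=2,
                )
                md_warned = True
            multiplicity = int(rec.get_tag("NH")) if rec.has_tag("NH") else 1
            tags.append(
                AlignedTag(
                    chrom=rec.reference_name, start=start, end=end,
                    strand="-" if rec.is_reverse else "+",
                    mutations=tuple(sorted(muts)),
                    multiplicity=multiplicity, read_id=rec.query_name,
                )
            )
    return tags


def _md_deletion_bases(md: str) -> list[str]:
    """Deleted reference bases from an MD string, in order of appearance."""
    out, i = [], 0
    while i < len(md):
        if md[i] == "^":
            j = i + 1
            while j < len(md) and md[j].isalpha():
                j += 1
            out.append(md[i + 1 : j])
            i = j
        else:
            i += 1
    return out


def remove_duplicates(tags: Iterable[AlignedTag]) -> list[AlignedTag]:
    """Collapse PCR duplicates: at most one tag per (chrom, start, end, strand).

    The retained representative is the tag with the most mutation records;
    ties break to the lexicographically smallest read id. Output preserves
    first-seen key order, so the operation is idempotent and deterministic.
    """
    best: dict[tuple, AlignedTag] = {}
    for tag in tags:
        key = tag.coord_key
        cur = best.get(key)
        if cur is None or (-len(tag.mutations), tag.read_id) < (
            -len(cur.mutations), cur.read_id
        ):
            best[key] = tag
    return list(best.values())


def filter_unique(tags: Iterable[AlignedTag]) -> list[AlignedTag]:
    """Keep only uniquely mapping tags (mapping_multiplicity == 1)."""
    return [t for t in tags if t.multiplicity == 1]
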