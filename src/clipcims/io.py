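"""Readers and writers for the on-disk formats.

All internal coordinates are 0-based half-open; the 1-based closed
conventions of FASTA indices, GFF3 and SAM are handled here and nowhere
else. SAM goes through pysam, GFF3 reading through gffutils, FASTA through
Bio.SeqIO. Tag and peak BED files are BED6 with extra columns documented on
the writer.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import AlignedTag, GeneModel, Mutation, MutationSite, Peak, Transcript

# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3 gene models


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/exon(/UTR) features, 1-based closed per GFF3."""
    lines = ["##gff-version 3"]
    for gene in genes:
        g1, g2 = gene.start + 1, gene.end
        lines.append(
            "\t".join(
                [gene.chrom, "clipcims", "gene", str(g1), str(g2), ".", gene.strand, ".",
                 f"ID={gene.gene_id}"]
            )
        )
        for tx in gene.transcripts:
            lines.append(
                "\t".join(
                    [gene.chrom, "clipcims", "mRNA", str(tx.start + 1), str(tx.end), ".",
                     gene.strand, ".", f"ID={tx.id};Parent={gene.gene_id}"]
                )
            )
            for i, (s, e) in enumerate(tx.exons, 1):
                lines.append(
                    "\t".join(
                        [gene.chrom, "clipcims", "exon", str(s + 1), str(e), ".",
                         gene.strand, ".", f"ID={tx.id}.exon{i};Parent={tx.id}"]
                    )
                )
        for utr, feat in ((gene.utr5, "five_prime_UTR"), (gene.utr3, "three_prime_UTR")):
            if utr is not None:
                lines.append(
                    "\t".join(
                        [gene.chrom, "clipcims", feat, str(utr[0] + 1), str(utr[1]), ".",
                         gene.strand, ".", f"ID={gene.gene_id}.{feat};Parent={gene.gene_id}"]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models via gffutils (in-memory database)."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for tx in db.children(g, featuretype="mRNA", order_by="start"):
            exons = tuple(
                (ex.start - 1, ex.end)
                for ex in db.children(tx, featuretype="exon", order_by="start")
            )
            if exons:
                transcripts.append(Transcript(id=tx.id, exons=exons))
        if not transcripts:
            continue
        utr5 = utr3 = None
        for u in db.children(g, featuretype="five_prime_UTR"):
            utr5 = (u.start - 1, u.end)
        for u in db.children(g, featuretype="three_prime_UTR"):
            utr3 = (u.start - 1, u.end)
        genes.append(
            GeneModel(
                gene_id=g.id, chrom=g.seqid, strand=g.strand,
                transcripts=tuple(transcripts), utr5=utr5, utr3=utr3,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# SAM

_BASES = "ACGT"


def _md_and_query(
    tag: AlignedTag, ref_seq: Optional[str]
) -> tuple[str, str, list[tuple[int, int]]]:
    """Build MD tag, query sequence and CIGAR ops for a tag.

    ``ref_seq`` is the full chromosome sequence (or None, in which case
    unmutated positions are written as 'A'). Returns (md, query, cigar)
    where cigar is a list of (op, length) with op in pysam codes.
    """
    dels = {m.position: m for m in tag.mutations if m.type == "deletion"}
    subs = {m.position: m for m in tag.mutations if m.type == "substitution"}
    if any(m.type == "insertion" for m in tag.mutations):
        raise ValueError("SAM writer does not support insertion mutations")

    def ref_base(pos: int) -> str:
        return ref_seq[pos].upper() if ref_seq is not None else "A"

    md_parts: list[str] = []
    query: list[str] = []
    cigar: list[tuple[int, int]] = []  # (op, len); 0=M, 2=D
    match_run = 0
    md_count = 0
    pos = tag.start
    while pos < tag.end:
        if pos in dels:
            d = dels[pos]
            span = d.ref_span
            if match_run:
                cigar.append((0, match_run))
                match_run = 0
            cigar.append((2, span))
            md_parts.append(str(md_count))
            md_count = 0
            deleted = d.ref_base or "".join(ref_base(p) for p in range(pos, pos + span))
            md_parts.append("^" + deleted.upper())
            pos += span
            continue
        if pos in subs:
            s = subs[pos]
            rb = (s.ref_base or ref_base(pos)).upper()
            ob = (s.obs_base or ("C" if rb != "C" else "G")).upper()
            md_parts.append(str(md_count))
            md_parts.append(rb)
            md_count = 0
            query.append(ob)
        else:
            query.append(ref_base(pos))
            md_count += 1
        match_run += 1
        pos += 1
    if match_run:
        cigar.append((0, match_run))
    md_parts.append(str(md_count))
    return "".join(md_parts), "".join(query), cigar


def write_tags_sam(
    tags: Sequence[AlignedTag],
    chrom_sizes: Mapping[str, int],
    path: str | Path,
    genome: Optional[Mapping[str, str]] = None,
) -> None:
    """Write tags as a text SAM with CIGAR/MD consistent with their mutations.

    The NH tag carries mapping multiplicity. Minus-strand tags get flag 16;
    the stored sequence is the reference-forward alignment, as in SAM.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": size} for name, size in chrom_sizes.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for tag in tags:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = tag.read_id or f"tag_{tag.chrom}_{tag.start}"
            seg.reference_name = tag.chrom
            seg.reference_start = tag.start
            seg.mapping_quality = 255
            seg.flag = 16 if tag.strand == "-" else 0
            ref_seq = genome.get(tag.chrom) if genome is not None else None
            md, query, cigar = _md_and_query(tag, ref_seq)
            seg.cigartuples = cigar
            seg.query_sequence = query
            seg.set_tag("MD", md)
            seg.set_tag("NH", tag.multiplicity)
            out.write(seg)


# ---------------------------------------------------------------------------
# tag BED (BED6 + multiplicity + mutation summary)


def _mutation_summary(mutations: Sequence[Mutation]) -> str:
    if not mutations:
        return "."
    parts = []
    for m in sorted(mutations):
        code = {"substitution": "sub", "deletion": "del", "insertion": "ins"}[m.type]
        parts.append(f"{code}@{m.position}:{m.ref_base}>{m.obs_base}")
    return ";".join(parts)


def _parse_mutation_summary(text: str) -> tuple[Mutation, ...]:
    if text in (".", ""):
        return ()
    muts = []
    for part in text.split(";"):
        code_pos, bases = part.split(":", 1)
        code, pos = code_pos.split("@")
        ref, obs = bases.split(">", 1)
        mtype = {"sub": "substitution", "del": "deletion", "ins": "insertion"}[code]
        muts.append(Mutation(position=int(pos), type=mtype, ref_base=ref, obs_base=obs))
    return tuple(muts)


def write_tags_bed(tags: Sequence[AlignedTag], path: str | Path) -> None:
    """BED6 plus column 7 = mapping multiplicity, column 8 = mutation summary."""
    with open(path, "w") as fh:
        for t in tags:
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.read_id}\t0\t{t.strand}\t"
                f"{t.multiplicity}\t{_mutation_summary(t.mutations)}\n"
            )


def read_tags_bed(path: str | Path) -> list[AlignedTag]:
    tags = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        tags.append(
            AlignedTag(
                chrom=f[0], start=int(f[1]), end=int(f[2]), read_id=f[3],
                strand=f[5], multiplicity=int(f[6]) if len(f) > 6 else 1,
                mutations=_parse_mutation_summary(f[7]) if len(f) > 7 else (),
            )
        )
    return tags


# ---------------------------------------------------------------------------
# peak BED (BED6 + height, n_tags, provenance)


def write_peaks_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    """BED6 (score column = significance score) + height, n_tags, provenance."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\t{p.score:.6g}\t{p.strand}\t"
                f"{p.height}\t{p.n_tags}\t{p.provenance}\n"
            )


def read_peaks_bed(path: str | Path) -> list[Peak]:
    peaks = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        peaks.append(
            Peak(
                chrom=f[0], start=int(f[1]), end=int(f[2]), id=f[3],
                score=float(f[4]), strand=f[5],
                height=int(f[6]) if len(f) > 6 else 1,
                n_tags=int(f[7]) if len(f) > 7 else 1,
                provenance=f[8] if len(f) > 8 else "clustered",
            )
        )
    return peaks


# ---------------------------------------------------------------------------
# mutation-site TSV

SITE_COLUMNS = ["chrom", "position", "strand", "type", "k", "m", "fdr"]


def write_sites_tsv(sites: Sequence[MutationSite], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.chrom, s.position, s.strand, s.type, s.k, s.m, s.fdr) for s in sites],
        columns=SITE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_sites_tsv(path: str | Path) -> list[MutationSite]:
    df = pd.read_csv(path, sep="\t")
    return [
        MutationSite(
            chrom=r.chrom, position=int(r.position), strand=r.strand, type=r.type,
            k=int(r.k), m=int(r.m), fdr=float(r.fdr),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# PFM in MEME minimal text format


def write_meme_pfm(consensus: str, pfm, path: str | Path, name: str = "motif1") -> None:
    """Write a single position-frequency matrix in MEME minimal format (RNA)."""
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGU", "",
        f"MOTIF {name} {consensus}",
        f"letter-probability matrix: alength= 4 w= {pfm.shape[1]}",
    ]
    for col in range(pfm.shape[1]):
        lines.append(" ".join(f"{pfm[row, col]:.6f}" for row in range(4)))
    Path(path).write_text("\n".join(lines) + "\n")
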