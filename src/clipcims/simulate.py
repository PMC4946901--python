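"""Synthetic genomes, CLIP tags, RNA-seq reads and qPCR tables.

The generator produces toy data with the statistical structure the
analysis assumes: CLIP tags piled on planted UGUGUGUG sites whose
crosslink base (the motif center) carries substitutions or single-base
deletions at configurable rates, uniform background tags, exact-coordinate
PCR duplicates, multi-mapper flags, a two-isoform gene with alternative
terminal exons and genotype-dependent intron retention, and paired Ct
tables with an internal reference gene. Every stochastic draw goes
through a numpy Generator seeded from the config, so a fixed seed gives
byte-identical outputs.

Truth records (planted sites, per-site occupancies, expected intron
counts) are returned alongside the data for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import AlignedTag, GeneModel, Mutation, Transcript

_DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimConfig:
    """Study conditions for the CLIP simulation.

    Rates named ``*_rate`` that are probabilities must lie in [0, 1];
    ``site_occupancy`` (expected tags per planted site), ``background_rate``
    (tags per kb) and ``pcr_dup_rate`` (expected duplicates per unique tag)
    are Poisson means and only need to be >= 0.
    """

    n_chromosomes: int = 2
    chrom_length: int = 200_000
    n_genes: int = 20
    motif: str = "UGUGUGUG"
    sites_per_gene: int = 1
    site_occupancy: float = 50.0
    background_rate: float = 0.1           # tags per kb
    crosslink_sub_rate: float = 0.3        # P(substitution at crosslink base)
    crosslink_del_rate: float = 0.05       # P(deletion instead)
    random_mut_rate: float = 0.1           # P(uniformly placed extra substitution)
    pcr_dup_rate: float = 0.1              # expected duplicates per unique tag
    multimap_fraction: float = 0.05
    tag_length_mean: float = 36.0
    tag_length_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crosslink_sub_rate", "crosslink_del_rate", "random_mut_rate",
                     "multimap_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.crosslink_sub_rate + self.crosslink_del_rate > 1.0:
            raise ValueError("crosslink substitution + deletion rate must be <= 1")
        for name in ("site_occupancy", "background_rate", "pcr_dup_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if set(self.motif.upper()) - set("ACGUT"):
            raise ValueError("motif must be over the ACGU/ACGT alphabet")
        if self.n_chromosomes < 1 or self.chrom_length < 1000 or self.n_genes < 0:
            raise ValueError("need >= 1 chromosome, chrom_length >= 1000, n_genes >= 0")

    @property
    def dna_motif(self) -> str:
        return self.motif.upper().replace("U", "T")

    def null(self) -> "SimConfig":
        """The matched null: same pileups, no crosslink-induced mutations."""
        return replace(self, crosslink_sub_rate=0.0, crosslink_del_rate=0.0)


@dataclass
class PlantedSite:
    """Truth record for one planted motif occurrence."""

    chrom: str
    position: int            # genomic start of the motif occurrence (0-based)
    strand: str
    motif: str
    gene_id: str
    crosslink_pos: int       # genomic coordinate of the designated crosslink base
    occupancy: int = 0       # tags drawn for this site (filled by simulate_clip_tags)


@dataclass
class SimulatedGenome:
    sequences: dict[str, str]
    genes: list[GeneModel]
    sites: list[PlantedSite]
    config: SimConfig

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}


@dataclass
class ClipSimResult:
    tags: list[AlignedTag]
    truth: pd.DataFrame      # one row per planted site
    counts: dict[str, int]   # site/background/duplicate/multimapped accounting


@dataclass
class IsoformSimSpec:
    """Conditions for the two-isoform RNA-seq simulation."""

    gene_id: str
    fraction_isoform_a: float = 0.5
    read_depth: int = 2000
    read_length: int = 50
    retention_rate: float = 0.3
    genotype: str = "wt"
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_isoform_a <= 1.0):
            raise ValueError("fraction_isoform_a must lie in [0, 1]")
        if not (0.0 <= self.retention_rate <= 1.0):
            raise ValueError("retention_rate must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.read_depth < 0 or self.read_length < 1:
            raise ValueError("read_depth must be >= 0 and read_length >= 1")


# ---------------------------------------------------------------------------
# genome + gene models

# exon/intron layout templates (lengths in bases)
_STD_EXONS = (300, 200, 250, 400)
_STD_INTRONS = (800, 1000, 900)
_ALT_SHARED_EXONS = (300, 200)
_ALT_SHARED_INTRON = 800
_ALT_INTRON_A = 1000
_ALT_EXON_A = 400
_ALT_INTRON_B = 1000
_ALT_EXON_B = 400
_UTR5_LEN = 80
_UTR3_LEN = 120
_SITE_MARGIN = 15  # planted motif kept this far from intron boundaries


def _standard_gene(gene_id: str, chrom: str, strand: str, start: int) -> GeneModel:
    exons = []
    pos = start
    for i, elen in enumerate(_STD_EXONS):
        exons.append((pos, pos + elen))
        pos += elen
        if i < len(_STD_INTRONS):
            pos += _STD_INTRONS[i]
    tx = Transcript(id=f"{gene_id}.t1", exons=tuple(exons))
    first, last = exons[0], exons[-1]
    if strand == "+":
        utr5 = (first[0], first[0] + _UTR5_LEN)
        utr3 = (last[1] - _UTR3_LEN, last[1])
    else:
        utr5 = (last[1] - _UTR5_LEN, last[1])
        utr3 = (first[0], first[0] + _UTR3_LEN)
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                     transcripts=(tx,), utr5=utr5, utr3=utr3)


def _alt_terminal_gene(gene_id: str, chrom: str, strand: str, start: int) -> GeneModel:
    """Two terminal-exon isoforms: shared exons, then exon_a vs exon_b.

    Isoform A splices the isoform-specific intron_a and ends in exon_a;
    isoform B skips exon_a entirely and ends in exon_b, whose specific
    intron_b is the gap between exon_a and exon_b.
    """
    shared = []
    pos = start
    for i, elen in enumerate(_ALT_SHARED_EXONS):
        shared.append((pos, pos + elen))
        pos += elen
        if i < len(_ALT_SHARED_EXONS) - 1:
            pos += _ALT_SHARED_INTRON
    intron_a = (pos, pos + _ALT_INTRON_A)
    pos += _ALT_INTRON_A
    exon_a = (pos, pos + _ALT_EXON_A)
    pos += _ALT_EXON_A
    intron_b = (pos, pos + _ALT_INTRON_B)
    pos += _ALT_INTRON_B
    exon_b = (pos, pos + _ALT_EXON_B)
    tx_a = Transcript(id=f"{gene_id}.A", exons=tuple(shared + [exon_a]))
    tx_b = Transcript(id=f"{gene_id}.B", exons=tuple(shared + [exon_b]))
    first = shared[0]
    utr5 = (first[0], first[0] + _UTR5_LEN) if strand == "+" else None
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                     transcripts=(tx_a, tx_b), utr5=utr5, utr3=None,
                     intron_a=intron_a, intron_b=intron_b)


def _gene_span(alt: bool) -> int:
    if alt:
        return (sum(_ALT_SHARED_EXONS) + _ALT_SHARED_INTRON + _ALT_INTRON_A
                + _ALT_EXON_A + _ALT_INTRON_B + _ALT_EXON_B)
    return sum(_STD_EXONS) + sum(_STD_INTRONS)


def generate_genome(config: SimConfig) -> SimulatedGenome:
    """Random genome with non-overlapping genes and planted motif sites.

    The first gene carries the alternative-terminal-exon structure. Each
    gene gets ``sites_per_gene`` motif occurrences planted inside introns,
    strand-adjusted so the transcribed sequence equals the motif; the
    crosslink base is the motif's center. Raises if the chromosomes are
    too short to host the requested genes.
    """
    rng = np.random.default_rng([config.seed, 0])
    base_codes = np.frombuffer(_DNA.encode(), dtype=np.uint8)
    sequences = {
        f"chr{c + 1}": base_codes[
            rng.integers(0, 4, size=config.chrom_length)
        ].tobytes().decode()
        for c in range(config.n_chromosomes)
    }
    chrom_names = list(sequences)

    genes: list[GeneModel] = []
    sites: list[PlantedSite] = []
    if config.n_genes:
        per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
        for i in range(config.n_genes % config.n_chromosomes):
            per_chrom[i] += 1
        gene_idx = 0
        for ci, chrom in enumerate(chrom_names):
            n_here = per_chrom[ci]
            if n_here == 0:
                continue
            slot = config.chrom_length // n_here
            max_span = _gene_span(alt=True) + 200
            if slot < max_span:
                raise ValueError(
                    f"chrom_length {config.chrom_length} too small for {n_here} genes "
                    f"per chromosome (need >= {max_span} bases per gene)"
                )
            for gi in range(n_here):
                gene_idx += 1
                gene_id = f"gene{gene_idx}"
                alt = gene_idx == 1
                span = _gene_span(alt)
                jitter = int(rng.integers(0, slot - span - 100))
                start = gi * slot + 100 + jitter
                strand = "+" if rng.random() < 0.5 else "-"
                gene = (_alt_terminal_gene if alt else _standard_gene)(
                    gene_id, chrom, strand, start
                )
                genes.append(gene)

        # plant motif sites inside introns
        seq_arrays = {name: bytearray(seq.encode()) for name, seq in sequences.items()}
        dna_motif = config.dna_motif
        klen = len(dna_motif)
        center = klen // 2
        for gene in genes:
            introns = gene.transcripts[0].introns
            for _ in range(config.sites_per_gene):
                intron = introns[int(rng.integers(0, len(introns)))]
                lo = intron[0] + _SITE_MARGIN
                hi = intron[1] - _SITE_MARGIN - klen
                pos = int(rng.integers(lo, hi))
                planted = dna_motif if gene.strand == "+" else _revcomp(dna_motif)
                seq_arrays[gene.chrom][pos : pos + klen] = planted.encode()
                crosslink = pos + center if gene.strand == "+" else pos + klen - 1 - center
                sites.append(
                    PlantedSite(
                        chrom=gene.chrom, position=pos, strand=gene.strand,
                        motif=config.motif.upper(), gene_id=gene.gene_id,
                        crosslink_pos=crosslink,
                    )
                )
        sequences = {name: arr.decode() for name, arr in seq_arrays.items()}

    return SimulatedGenome(sequences=sequences, genes=genes, sites=sites, config=config)


# ---------------------------------------------------------------------------
# CLIP tags


def _draw_tag_interval(
    rng: np.random.Generator, config: SimConfig, chrom_len: int, anchor: Optional[int]
) -> tuple[int, int]:
    """Tag interval; if ``anchor`` is given the interval must contain it."""
    length = int(round(rng.normal(config.tag_length_mean, config.tag_length_sd)))
    length = max(20, min(length, 200, chrom_len))
    if anchor is None:
        start = int(rng.integers(0, chrom_len - length + 1))
    else:
        offset = int(rng.integers(0, length))
        start = anchor - offset
        start = max(0, min(start, chrom_len - length, anchor))
        if not (start <= anchor < start + length):  # clamped off the anchor
            start = max(0, min(anchor, chrom_len - length))
    return start, start + length


def _maybe_random_sub(
    rng: np.random.Generator, config: SimConfig, seq: str,
    start: int, end: int, taken: set[int],
) -> Optional[Mutation]:
    if rng.random() >= config.random_mut_rate:
        return None
    pos = int(rng.integers(start, end))
    if pos in taken:
        return None
    ref = seq[pos]
    choices = [b for b in _DNA if b != ref]
    obs = choices[int(rng.integers(0, len(choices)))]
    return Mutation(position=pos, type="substitution", ref_base=ref, obs_base=obs)


def simulate_clip_tags(
    genome: SimulatedGenome,
    sites: Optional[Sequence[PlantedSite]] = None,
    config: Optional[SimConfig] = None,
) -> ClipSimResult:
    """Simulate CLIP tags over planted sites plus uniform background.

    Site-overlapping tags carry a substitution (or single-base deletion) at
    the site's crosslink base with the configured rates; every tag may also
    carry one uniformly placed random substitution (``random_mut_rate``).
    PCR duplicates are exact coordinate copies of their parent tag;
    multi-mapping is an NH-style multiplicity flag. Per-site occupancies
    are recorded in both the returned truth table and the sites.
    """
    config = config or genome.config
    sites = list(genome.sites if sites is None else sites)
    rng = np.random.default_rng([config.seed, 1])
    tags: list[AlignedTag] = []
    truth_rows = []

    for si, site in enumerate(sites):
        seq = genome.sequences[site.chrom]
        occ = int(rng.poisson(config.site_occupancy))
        site.occupancy = occ
        n_sub = n_del = 0
        for ti in range(occ):
            start, end = _draw_tag_interval(rng, config, len(seq), site.crosslink_pos)
            muts: list[Mutation] = []
            u = rng.random()
            if u < config.crosslink_sub_rate:
                ref = seq[site.crosslink_pos]
                choices = [b for b in _DNA if b != ref]
                obs = choices[int(rng.integers(0, len(choices)))]
                muts.append(Mutation(site.crosslink_pos, "substitution", ref, obs))
                n_sub += 1
            elif u < config.crosslink_sub_rate + config.crosslink_del_rate:
                muts.append(Mutation(site.crosslink_pos, "deletion", seq[site.crosslink_pos]))
                n_del += 1
            extra = _maybe_random_sub(
                rng, config, seq, start, end, {m.position for m in muts}
            )
            if extra is not None:
                muts.append(extra)
            tags.append(
                AlignedTag(
                    chrom=site.chrom, start=start, end=end, strand=site.strand,
                    mutations=tuple(sorted(muts)), read_id=f"site{si}_t{ti}",
                )
            )
        truth_rows.append(
            (site.chrom, site.position, site.strand, site.gene_id,
             site.crosslink_pos, occ, n_sub, n_del)
        )
    n_site_tags = len(tags)

    total_bases = sum(genome.chrom_sizes.values())
    chrom_names = list(genome.sequences)
    weights = np.array([genome.chrom_sizes[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    n_bg = int(rng.poisson(config.background_rate * total_bases / 1000))
    for bi in range(n_bg):
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=weights))]
        seq = genome.sequences[chrom]
        start, end = _draw_tag_interval(rng, config, len(seq), None)
        strand = "+" if rng.random() < 0.5 else "-"
        muts = []
        extra = _maybe_random_sub(rng, config, seq, start, end, set())
        if extra is not None:
            muts.append(extra)
        tags.append(
            AlignedTag(chrom=chrom, start=start, end=end, strand=strand,
                       mutations=tuple(muts), read_id=f"bg{bi}")
        )

    # multi-mapper flags
    flags = rng.random(len(tags)) < config.multimap_fraction
    n_multi = int(flags.sum())
    for i in np.flatnonzero(flags):
        tags[i] = replace(tags[i], multiplicity=int(rng.integers(2, 11)))

    # PCR duplicates: exact coordinate copies, mutations carried over
    duplicates = []
    for tag in tags:
        for j in range(int(rng.poisson(config.pcr_dup_rate))):
            duplicates.append(replace(tag, read_id=f"{tag.read_id}.d{j}"))
    tags.extend(duplicates)

    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "position", "strand", "gene_id", "crosslink_pos",
                 "occupancy", "n_sub_tags", "n_del_tags"],
    )
    counts = {
        "site_tags": n_site_tags,
        "background_tags": n_bg,
        "duplicates": len(duplicates),
        "multimapped": n_multi,
        "total": len(tags),
    }
    return ClipSimResult(tags=tags, truth=truth, counts=counts)


# ---------------------------------------------------------------------------
# RNA-seq over the two-isoform gene


def simulate_rnaseq_isoforms(
    spec: IsoformSimSpec, gene: GeneModel
) -> tuple[list[list[AlignedTag]], pd.DataFrame]:
    """Per-replicate reads from a gene with alternative terminal exons.

    Each read derives from isoform A with probability
    ``fraction_isoform_a``; with probability ``retention_rate`` it is an
    intron-retention read placed uniformly inside the isoform's specific
    intron (fully contained), otherwise it falls inside one of the
    isoform's exons. The truth table records expected and realized intron
    read counts per replicate.
    """
    if not gene.has_alt_terminal_exons:
        raise ValueError(f"gene {gene.gene_id} lacks the isoform A/B structure")
    tx_by_iso = {"A": gene.transcripts[0], "B": gene.transcripts[1]}
    intron_by_iso = {"A": gene.intron_a, "B": gene.intron_b}
    replicates: list[list[AlignedTag]] = []
    truth_rows = []
    for rep in range(spec.n_replicates):
        rng = np.random.default_rng([spec.seed, 100 + rep])
        reads: list[AlignedTag] = []
        realized = {"A": 0, "B": 0}
        for ri in range(spec.read_depth):
            iso = "A" if rng.random() < spec.fraction_isoform_a else "B"
            if rng.random() < spec.retention_rate:
                intron = intron_by_iso[iso]
                start = int(rng.integers(intron[0], intron[1] - spec.read_length + 1))
                realized[iso] += 1
            else:
                exons = [e for e in tx_by_iso[iso].exons
                         if e[1] - e[0] >= spec.read_length]
                w = np.array([e[1] - e[0] - spec.read_length + 1 for e in exons], float)
                exon = exons[int(rng.choice(len(exons), p=w / w.sum()))]
                start = int(rng.integers(exon[0], exon[1] - spec.read_length + 1))
            reads.append(
                AlignedTag(
                    chrom=gene.chrom, start=start, end=start + spec.read_length,
                    strand=gene.strand, read_id=f"{spec.genotype}_rep{rep}_r{ri}",
                )
            )
        replicates.append(reads)
        truth_rows.append(
            (spec.genotype, f"rep{rep}",
             spec.read_depth * spec.fraction_isoform_a * spec.retention_rate,
             spec.read_depth * (1 - spec.fraction_isoform_a) * spec.retention_rate,
             realized["A"], realized["B"])
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["genotype", "replicate", "expected_intron_a", "expected_intron_b",
                 "realized_intron_a", "realized_intron_b"],
    )
    return replicates, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables


def simulate_qpcr(
    groups: Mapping[str, int],
    reference_gene: str = "actb",
    effect_sizes: Optional[Mapping[str, float]] = None,
    noise_sd: float = 0.2,
    seed: int = 0,
    target_gene: str = "target",
    baseline_ct: float = 24.0,
    reference_ct: float = 18.0,
    paired: bool = False,
) -> pd.DataFrame:
    """Long-format Ct table: Ct = baseline - log2(expression) + noise.

    ``effect_sizes`` maps each group to its expression fold (1.0 = no
    change). In paired mode the two group keys are the two sides of each
    animal and must have equal n; pair ids link them. Every sample gets a
    Ct for both the target and the reference gene.
    """
    if not reference_gene:
        raise ValueError("a reference gene is required")
    if reference_gene == target_gene:
        raise ValueError("reference gene must differ from the target")
    effect_sizes = dict(effect_sizes or {})
    for g in groups:
        effect_sizes.setdefault(g, 1.0)
        if effect_sizes[g] <= 0:
            raise ValueError("effect sizes must be > 0")
    if paired:
        ns = set(groups.values())
        if len(groups) != 2 or len(ns) != 1:
            raise ValueError("paired mode needs exactly two sides with equal n")
    rng = np.random.default_rng([seed, 2])
    rows = []
    for group, n in groups.items():
        dct_shift = -np.log2(effect_sizes[group])
        for i in range(n):
            sample = f"{group}_{i + 1}"
            pair = f"animal{i + 1}" if paired else sample
            ct_t = baseline_ct + dct_shift + rng.normal(0.0, noise_sd)
            ct_r = reference_ct + rng.normal(0.0, noise_sd)
            rows.append((sample, group, pair, target_gene, float(ct_t)))
            rows.append((sample, group, pair, reference_gene, float(ct_r)))
    return pd.DataFrame(rows, columns=["sample", "group", "pair", "gene", "ct"])
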