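"""End-to-end orchestration: simulate -> tags -> peaks -> CIMS -> motif -> annotation.

The pipeline runs the two peak-calling arms (tag clustering with
significance scoring, and CIMS with permutation FDR) on the same filtered
tag set, merges them, runs motif enrichment on the merged peaks, annotates
everything against the gene models and, for simulated inputs, compares the
called CIMS peaks with the planted truth. A master seed splits
deterministically into per-stage seeds, so toggling one stage never
perturbs another's randomness and a fixed seed reproduces every output
file byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as cio
from .annotate import PeakAnnotation, annotate_peaks
from .cims import call_cims_peaks, estimate_fdr, tabulate_mutation_sites
from .model import AlignedTag, GeneModel, Peak, overlap_len
from .motif import MotifResult, build_consensus, extract_background, \
    extract_peak_sequences, kmer_enrichment
from .peaks import cluster_tags, score_peaks, select_top_fraction
from .simulate import ClipSimResult, SimConfig, SimulatedGenome, \
    generate_genome, simulate_clip_tags
from .tags import filter_unique, parse_alignments, remove_duplicates

logger = logging.getLogger("clipcims")

DEFAULT_STAGES = ("simulate", "tags", "peaks", "cims", "motif", "annotate")


@dataclass
class RunConfig:
    """One configured, seeded pipeline run.

    Published thresholds are the defaults where the study states them
    (fdr_max 0.01 with m > 5, top fraction 0.15, motif window +-20 with
    100/100 flank backgrounds); the rest are declared package defaults.
    """

    outdir: str = "clipcims_out"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    stages: tuple[str, ...] = DEFAULT_STAGES
    # file inputs, used when the simulate stage is disabled
    genome_fasta: Optional[str] = None
    gff3: Optional[str] = None
    sam: Optional[str] = None
    tags_bed: Optional[str] = None
    # thresholds
    fdr_max: float = 0.01
    m_min: int = 5
    strict_m: bool = True
    min_height: int = 2
    top_fraction: float = 0.15
    motif_k: int = 8
    peak_extension: int = 20
    flank_len: int = 100
    gap: int = 100
    cims_extension: int = 10
    n_permutations: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.fdr_max <= 1):
            raise ValueError("fdr_max must lie in (0, 1]")
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must lie in (0, 1]")
        if self.min_height < 1 or self.m_min < 0 or self.n_permutations < 20:
            raise ValueError("thresholds outside documented ranges")
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


@dataclass
class ResultsBundle:
    clustered_peaks: list[Peak]
    selected_peaks: list[Peak]
    cims_peaks: list[Peak]
    union_peaks: list[Peak]
    gene_lists: dict[str, list[str]]
    motif: Optional[MotifResult]
    annotations: list[PeakAnnotation]
    composition: dict[str, float]
    truth_report: dict
    manifest: dict


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seeds below 2**31 from one master seed."""
    return [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(n)]


def merge_peak_arms(
    clustered: Sequence[Peak],
    cims: Sequence[Peak],
    genes: Sequence[GeneModel],
    manifests: Optional[tuple[str, str]] = None,
) -> tuple[list[Peak], dict[str, list[str]]]:
    """Merge the two peak-calling arms and derive per-arm gene lists.

    Peaks overlapping across arms (same strand) are merged into their
    interval union with combined provenance. Gene lists come from peak
    annotation; the intersection and union lists are reported alongside.
    Refuses to merge arms computed from different tag manifests.
    """
    if manifests is not None and manifests[0] != manifests[1]:
        raise ValueError(
            f"peak arms come from different tag manifests: {manifests[0]!r} vs {manifests[1]!r}"
        )
    combined = sorted(
        list(clustered) + list(cims), key=lambda p: (p.chrom, p.strand, p.start, p.end)
    )
    union: list[Peak] = []
    for p in combined:
        last = union[-1] if union else None
        if (
            last is not None
            and last.chrom == p.chrom
            and last.strand == p.strand
            and p.start < last.end
        ):
            last.end = max(last.end, p.end)
            last.height = max(last.height, p.height)
            last.n_tags = max(last.n_tags, p.n_tags)
            last.score = max(last.score, p.score)
            prov = sorted(set(last.provenance.split("+")) | set(p.provenance.split("+")))
            last.provenance = "+".join(prov)
        else:
            union.append(dataclasses.replace(p))
    for i, p in enumerate(union, 1):
        p.id = f"u{i}"

    def arm_genes(peaks: Sequence[Peak]) -> list[str]:
        ann, _ = annotate_peaks(peaks, genes)
        return sorted({g for a in ann for g in a.gene_ids})

    g_clustered = arm_genes(clustered)
    g_cims = arm_genes(cims)
    gene_lists = {
        "clustered": g_clustered,
        "cims": g_cims,
        "intersection": sorted(set(g_clustered) & set(g_cims)),
        "union": sorted(set(g_clustered) | set(g_cims)),
    }
    return union, gene_lists


def _truth_report(
    genome: SimulatedGenome, cims_peaks: Sequence[Peak], motif: Optional[MotifResult]
) -> dict:
    """Recovery of planted sites by the CIMS arm, plus motif recovery."""
    sites = genome.sites
    recovered = 0
    for s in sites:
        if any(
            p.chrom == s.chrom and p.strand == s.strand
            and p.start <= s.crosslink_pos < p.end
            for p in cims_peaks
        ):
            recovered += 1
    correct_peaks = sum(
        1
        for p in cims_peaks
        if any(
            p.chrom == s.chrom and p.strand == s.strand
            and p.start <= s.crosslink_pos < p.end
            for s in sites
        )
    )
    report = {
        "n_planted_sites": len(sites),
        "n_cims_peaks": len(cims_peaks),
        "recall": recovered / len(sites) if sites else None,
        "precision": correct_peaks / len(cims_peaks) if cims_peaks else None,
    }
    if motif is not None and not motif.table.empty:
        top = motif.table.iloc[0]["kmer"]
        report["top_kmer"] = top
        report["motif_recovered"] = bool(top == genome.config.motif.upper())
    return report


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Execute the enabled stages in order, writing all artifacts + manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    counts: dict[str, int] = {}

    genome: Optional[SimulatedGenome] = None
    genes: list[GeneModel] = []
    sequences = None
    raw_tags: list[AlignedTag] = []

    if "simulate" in config.stages:
        sim_config = dataclasses.replace(config.sim, seed=seeds[0])
        genome = generate_genome(sim_config)
        genes = genome.genes
        sequences = genome.sequences
        sim = simulate_clip_tags(genome)
        raw_tags = sim.tags
        counts.update({f"sim_{k}": v for k, v in sim.counts.items()})
        cio.write_fasta(sequences, outdir / "genome.fa")
        cio.write_gff3(genes, outdir / "genes.gff3")
        cio.write_tags_sam(raw_tags, genome.chrom_sizes, outdir / "tags_raw.sam",
                           genome=sequences)
        sim.truth.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
        logger.info("simulate: %d tags (%d site, %d background, %d duplicates)",
                    len(raw_tags), sim.counts["site_tags"],
                    sim.counts["background_tags"], sim.counts["duplicates"])
    else:
        if config.genome_fasta:
            sequences = cio.read_fasta(config.genome_fasta)
        if config.gff3:
            genes = cio.read_gff3(config.gff3)
        if config.sam:
            raw_tags = parse_alignments(config.sam)
        elif config.tags_bed:
            raw_tags = cio.read_tags_bed(config.tags_bed)
        else:
            raise ValueError("no tag input: enable simulation or provide --sam/--tags")

    counts["tags_total"] = len(raw_tags)
    tags = filter_unique(remove_duplicates(raw_tags))
    counts["tags_filtered"] = len(tags)
    cio.write_tags_bed(tags, outdir / "tags.bed")
    logger.info("tags: %d -> %d after dedup + unique filter", len(raw_tags), len(tags))

    chrom_sizes = {c: len(s) for c, s in (sequences or {}).items()} or None

    clustered = cluster_tags(tags, min_height=config.min_height)
    clustered = score_peaks(clustered, tags, genes, chrom_sizes)
    selected = select_top_fraction(clustered, config.top_fraction)
    counts["peaks_clustered"] = len(clustered)
    counts["peaks_selected"] = len(selected)
    cio.write_peaks_bed(clustered, outdir / "peaks_clustered.bed")
    cio.write_peaks_bed(selected, outdir / "peaks_selected.bed")

    sites = tabulate_mutation_sites(tags)
    sites = estimate_fdr(sites, tags, n_permutations=config.n_permutations, seed=seeds[1])
    cims_peaks = call_cims_peaks(
        sites, fdr_max=config.fdr_max, m_min=config.m_min,
        strict_m=config.strict_m, extension=config.cims_extension,
    )
    counts["mutation_sites"] = len(sites)
    counts["peaks_cims"] = len(cims_peaks)
    cio.write_sites_tsv(sites, outdir / "sites.tsv")
    cio.write_peaks_bed(cims_peaks, outdir / "peaks_cims.bed")
    logger.info("peaks: %d clustered (%d selected), %d CIMS",
                len(clustered), len(selected), len(cims_peaks))

    union, gene_lists = merge_peak_arms(selected, cims_peaks, genes)
    cio.write_peaks_bed(union, outdir / "peaks_union.bed")
    (outdir / "gene_lists.json").write_text(
        json.dumps(gene_lists, indent=2, sort_keys=True) + "\n"
    )

    motif_result: Optional[MotifResult] = None
    if "motif" in config.stages and sequences and union:
        fg = extract_peak_sequences(union, sequences, extension=config.peak_extension)
        bg = extract_background(union, sequences, flank_len=config.flank_len,
                                gap=config.gap)
        if fg and bg:
            table = kmer_enrichment(fg, bg, k=config.motif_k)
            motif_result = build_consensus(table)
            table.head(50).to_csv(outdir / "kmers.tsv", sep="\t", index=False,
                                  float_format="%.6g")
            if not motif_result.empty:
                cio.write_meme_pfm(motif_result.consensus, motif_result.pfm,
                                   outdir / "motif.txt")

    annotations: list[PeakAnnotation] = []
    composition: dict[str, float] = {}
    if "annotate" in config.stages and genes:
        annotations, composition = annotate_peaks(union, genes)
        with open(outdir / "annotations.tsv", "w") as fh:
            fh.write("peak_id\tgene_ids\tfeature\tambiguous\n")
            for a in annotations:
                fh.write(f"{a.peak_id}\t{','.join(a.gene_ids) or '.'}\t"
                         f"{a.feature}\t{int(a.ambiguous)}\n")
        with open(outdir / "composition.tsv", "w") as fh:
            fh.write("feature\tfraction\n")
            for cls, frac in composition.items():
                fh.write(f"{cls}\t{frac:.6g}\n")

    truth_report = _truth_report(genome, cims_peaks, motif_result) if genome else {}
    if truth_report:
        (outdir / "truth_report.json").write_text(
            json.dumps(truth_report, indent=2, sort_keys=True) + "\n"
        )

    manifest = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": list(config.stages),
        "thresholds": {
            "fdr_max": config.fdr_max,
            "m_min": config.m_min,
            "strict_m": config.strict_m,
            "min_height": config.min_height,
            "top_fraction": config.top_fraction,
            "motif_k": config.motif_k,
            "peak_extension": config.peak_extension,
            "flank_len": config.flank_len,
            "gap": config.gap,
            "cims_extension": config.cims_extension,
            "n_permutations": config.n_permutations,
        },
        "sim": dataclasses.asdict(config.sim),
        "counts": counts,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )

    return ResultsBundle(
        clustered_peaks=clustered, selected_peaks=selected, cims_peaks=cims_peaks,
        union_peaks=union, gene_lists=gene_lists, motif=motif_result,
        annotations=annotations, composition=composition,
        truth_report=truth_report, manifest=manifest,
    )
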