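"""The generator must honour its own stated statistical contract."""

import numpy as np
import pandas as pd
import pytest

from clipcims import (
    IsoformSimSpec,
    SimConfig,
    count_intron_reads,
    delta_delta_ct,
    generate_genome,
    parse_alignments,
    remove_duplicates,
    simulate_clip_tags,
    simulate_qpcr,
    simulate_rnaseq_isoforms,
)
from clipcims.io import write_fasta, write_gff3, write_tags_sam

_COMP = str.maketrans("ACGT", "TGCA")


def test_fixed_seed_gives_byte_identical_genome_files(tmp_path):
    paths = []
    for run in ("a", "b"):
        g = generate_genome(SimConfig(seed=1))
        fa = tmp_path / f"{run}.fa"
        gff = tmp_path / f"{run}.gff3"
        write_fasta(g.sequences, fa)
        write_gff3(g.genes, gff)
        paths.append((fa.read_bytes(), gff.read_bytes()))
    assert paths[0] == paths[1]


def test_zero_genes_yields_empty_gene_set():
    g = generate_genome(SimConfig(seed=2, n_genes=0))
    assert g.genes == [] and g.sites == []
    assert len(g.sequences) == 2


def test_chromosome_too_small_raises():
    with pytest.raises(ValueError, match="too small"):
        generate_genome(SimConfig(seed=0, chrom_length=2000, n_genes=4))


def test_planted_sites_carry_the_motif_strand_adjusted(default_genome):
    dna_motif = default_genome.config.dna_motif
    assert len(default_genome.sites) == 20
    for site in default_genome.sites:
        seq = default_genome.sequences[site.chrom][site.position : site.position + 8]
        if site.strand == "-":
            seq = seq.translate(_COMP)[::-1]
        assert seq == dna_motif


def test_each_site_lies_in_exactly_one_gene(default_genome):
    for site in default_genome.sites:
        hosts = [
            g for g in default_genome.genes
            if g.chrom == site.chrom and g.start <= site.position < g.end
        ]
        assert len(hosts) == 1 and hosts[0].gene_id == site.gene_id


def test_rate_zero_config_emits_no_mutations():
    cfg = SimConfig(seed=3, crosslink_sub_rate=0.0, crosslink_del_rate=0.0,
                    random_mut_rate=0.0)
    sim = simulate_clip_tags(generate_genome(cfg))
    assert all(not t.mutations for t in sim.tags)


def test_zero_dup_rate_leaves_dedup_a_noop():
    cfg = SimConfig(seed=4, pcr_dup_rate=0.0)
    sim = simulate_clip_tags(generate_genome(cfg))
    assert sim.counts["duplicates"] == 0
    # coordinate collisions can still occur by chance among site tags, so
    # compare against the number of distinct coordinate keys, not len(tags)
    assert len(remove_duplicates(sim.tags)) == len({t.coord_key for t in sim.tags})


def test_tag_accounting_conserved(default_sim):
    c = default_sim.counts
    assert c["site_tags"] + c["background_tags"] + c["duplicates"] == c["total"]
    assert c["total"] == len(default_sim.tags)
    assert (default_sim.truth["occupancy"].sum()) == c["site_tags"]


def test_sam_round_trip_mutation_count_matches_truth(tmp_path):
    # no duplicates / random mutations so the SAM total is exactly the truth total
    cfg = SimConfig(seed=5, pcr_dup_rate=0.0, random_mut_rate=0.0)
    genome = generate_genome(cfg)
    sim = simulate_clip_tags(genome)
    sam = tmp_path / "tags.sam"
    write_tags_sam(sim.tags, genome.chrom_sizes, sam, genome=genome.sequences)
    parsed = parse_alignments(sam)
    n_sub = sum(1 for t in parsed for m in t.mutations if m.type == "substitution")
    n_del = sum(1 for t in parsed for m in t.mutations if m.type == "deletion")
    assert n_sub == sim.truth["n_sub_tags"].sum()
    assert n_del == sim.truth["n_del_tags"].sum()


def test_site_depth_and_background_match_configured_means():
    """Monte-Carlo check of the generator against its own stated expectations."""
    cfg0 = SimConfig()
    occs, bgs = [], []
    for seed in range(20):
        sim = simulate_clip_tags(generate_genome(SimConfig(seed=seed)))
        occs.extend(sim.truth["occupancy"])
        bgs.append(sim.counts["background_tags"])
    mean_occ = np.mean(occs)
    se_occ = np.sqrt(cfg0.site_occupancy / len(occs))
    assert abs(mean_occ - cfg0.site_occupancy) < 3 * se_occ
    expected_bg = cfg0.background_rate * cfg0.n_chromosomes * cfg0.chrom_length / 1000
    se_bg = np.sqrt(expected_bg / len(bgs))
    assert abs(np.mean(bgs) - expected_bg) < 3 * se_bg
    # planted-site pileups tower over the uniform background
    assert mean_occ > 10 * expected_bg / (cfg0.n_chromosomes * cfg0.chrom_length / 1000)


# ---------------------------------------------------------------------------
# RNA-seq isoform simulation


@pytest.fixture(scope="module")
def alt_gene(default_genome):
    return next(g for g in default_genome.genes if g.has_alt_terminal_exons)


def test_pure_isoform_a_retains_only_intron_a(alt_gene):
    spec = IsoformSimSpec(gene_id=alt_gene.gene_id, fraction_isoform_a=1.0,
                          read_depth=500, n_replicates=1, seed=6)
    reps, truth = simulate_rnaseq_isoforms(spec, alt_gene)
    counts = count_intron_reads(reps[0], alt_gene.intron_a, alt_gene.intron_b)
    assert counts.count_intron_b == 0
    assert counts.count_intron_a == truth["realized_intron_a"].iloc[0] > 0


def test_balanced_isoforms_recover_half_ratio(alt_gene):
    spec = IsoformSimSpec(gene_id=alt_gene.gene_id, fraction_isoform_a=0.5,
                          read_depth=2000, n_replicates=4, seed=7)
    reps, _ = simulate_rnaseq_isoforms(spec, alt_gene)
    for rep in reps:
        c = count_intron_reads(rep, alt_gene.intron_a, alt_gene.intron_b)
        assert abs(c.ratio_a - 0.5) < 0.05


def test_isoform_sim_deterministic(alt_gene):
    spec = IsoformSimSpec(gene_id=alt_gene.gene_id, seed=8)
    r1, _ = simulate_rnaseq_isoforms(spec, alt_gene)
    r2, _ = simulate_rnaseq_isoforms(spec, alt_gene)
    assert r1 == r2


def test_zero_depth_gives_empty_replicates(alt_gene):
    spec = IsoformSimSpec(gene_id=alt_gene.gene_id, read_depth=0, n_replicates=2, seed=9)
    reps, _ = simulate_rnaseq_isoforms(spec, alt_gene)
    assert all(r == [] for r in reps)


def test_isoform_spec_validation():
    from clipcims import GeneModel, Transcript

    with pytest.raises(ValueError):
        IsoformSimSpec(gene_id="g", fraction_isoform_a=1.5)
    # a standard single-transcript gene lacks the A/B structure
    g = GeneModel("g1", "chr1", "+", (Transcript("g1.t1", ((0, 100),)),))
    with pytest.raises(ValueError, match="isoform"):
        simulate_rnaseq_isoforms(IsoformSimSpec(gene_id="g1"), g)


# ---------------------------------------------------------------------------
# qPCR simulation


def test_qpcr_no_effect_no_noise_gives_fold_one():
    table = simulate_qpcr({"ctl": 4, "exp": 4}, effect_sizes={"exp": 1.0},
                          noise_sd=0.0, seed=10)
    result = delta_delta_ct(table, "actb", "ctl")
    assert np.allclose(result.folds["fold"], 1.0)


def test_qpcr_twofold_induction_shifts_ct_one_cycle():
    table = simulate_qpcr({"ctl": 3, "exp": 3}, effect_sizes={"exp": 2.0},
                          noise_sd=0.0, seed=11)
    ct = table.pivot_table(index="group", columns="gene", values="ct")
    assert ct.loc["ctl", "target"] - ct.loc["exp", "target"] == pytest.approx(1.0)
    result = delta_delta_ct(table, "actb", "ctl")
    exp_folds = result.folds.query("group == 'exp'")["fold"]
    assert np.allclose(exp_folds, 2.0)


def test_qpcr_recovers_twofold_effect_under_noise():
    folds = []
    for seed in range(50):
        table = simulate_qpcr({"ctl": 6, "exp": 6}, effect_sizes={"exp": 2.0},
                              noise_sd=0.2, seed=seed)
        result = delta_delta_ct(table, "actb", "ctl")
        folds.append(result.summary.query("group == 'exp'")["mean_fold"].iloc[0])
    assert 1.8 < np.mean(folds) < 2.2


def test_qpcr_requires_reference_gene():
    with pytest.raises(ValueError, match="reference"):
        simulate_qpcr({"a": 2}, reference_gene="", seed=0)
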