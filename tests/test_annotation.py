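"""Peak annotation, gene-set overlap and splicing/qPCR quantification."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from clipcims import (
    AlignedTag,
    GeneModel,
    IsoformCounts,
    IsoformSimSpec,
    Peak,
    Transcript,
    annotate_peaks,
    compare_intron_ratios,
    count_intron_reads,
    delta_delta_ct,
    gene_set_overlap,
    simulate_qpcr,
    simulate_rnaseq_isoforms,
)


def _gene(gid="g1", strand="+", chrom="chr1"):
    # exon [0,200) intron [200,800) exon [800,1000); UTRs at the ends
    tx = Transcript(f"{gid}.t1", ((0, 200), (800, 1000)))
    return GeneModel(gid, chrom, strand, (tx,), utr5=(0, 50), utr3=(950, 1000))


def _peak(start, end, strand="+", pid="p1", chrom="chr1"):
    return Peak(chrom, start, end, strand, height=1, n_tags=1, id=pid)


def test_intronic_peak_classified_intron():
    anns, _ = annotate_peaks([_peak(300, 350)], [_gene()])
    assert anns[0].feature == "intron" and anns[0].gene_ids == ("g1",)


def test_utr_and_exon_classification():
    anns, _ = annotate_peaks([_peak(0, 40, pid="u5"), _peak(100, 150, pid="ex"),
                              _peak(960, 990, pid="u3")], [_gene()])
    by_id = {a.peak_id: a.feature for a in anns}
    assert by_id == {"u5": "5'UTR", "ex": "exon", "u3": "3'UTR"}


def test_peak_outside_genes_is_intergenic():
    anns, _ = annotate_peaks([_peak(5000, 5050)], [_gene()])
    assert anns[0].feature == "intergenic" and anns[0].gene_ids == ()


def test_antisense_peak_not_assigned():
    anns, _ = annotate_peaks([_peak(300, 350, strand="-")], [_gene(strand="+")])
    assert anns[0].feature == "intergenic"


def test_ambiguous_peak_assigned_to_all_overlapping_genes():
    g1 = _gene("g1")
    tx2 = Transcript("g2.t1", ((100, 400),))
    g2 = GeneModel("g2", "chr1", "+", (tx2,))
    anns, _ = annotate_peaks([_peak(150, 250)], [g1, g2])
    assert anns[0].ambiguous and set(anns[0].gene_ids) == {"g1", "g2"}


def test_composition_fractions_mirror_reported_split():
    peaks = [_peak(210 + i, 230 + i, pid=f"i{i}") for i in range(79)]
    peaks += [_peak(60 + i, 70 + i, pid=f"e{i}") for i in range(21)]
    _, comp = annotate_peaks(peaks, [_gene()])
    assert comp["intron"] == pytest.approx(0.79)
    assert comp["exon"] == pytest.approx(0.21)
    assert sum(comp.values()) == pytest.approx(1.0)


def test_gene_without_exons_is_skipped_with_warning():
    bad = GeneModel("gx", "chr1", "+", (Transcript("gx.t1", ()),))
    with pytest.warns(UserWarning, match="no exons"):
        anns, _ = annotate_peaks([_peak(2, 8)], [bad])
    assert anns[0].feature == "intergenic"


# ---------------------------------------------------------------------------
# gene-set overlap


def hypergeom_oracle(M, n_ref, n_targ, k):
    """Upper-tail hypergeometric by exhaustive summation over overlap counts."""
    total = math.comb(M, n_targ)
    acc = 0
    for j in range(k, min(n_ref, n_targ) + 1):
        acc += math.comb(n_ref, j) * math.comb(M - n_ref, n_targ - j)
    return acc / total if total else 1.0


def test_overlap_p_matches_enumeration_oracle():
    universe = [f"g{i}" for i in range(20)]
    targets = universe[:5]
    reference = universe[3:7]
    overlap, p = gene_set_overlap(targets, reference, universe)
    assert overlap == ["g3", "g4"]
    assert p == pytest.approx(hypergeom_oracle(20, 4, 5, 2), rel=1e-12)


def test_oracle_itself_matches_brute_force_enumeration():
    """Validate the summation oracle against literal subset enumeration."""
    universe = list(range(10))
    reference = {0, 1, 2, 3}
    for n_targ in (2, 4, 6):
        for k in range(0, n_targ + 1):
            brute = sum(
                1 for combo in itertools.combinations(universe, n_targ)
                if len(reference & set(combo)) >= k
            ) / math.comb(10, n_targ)
            assert hypergeom_oracle(10, 4, n_targ, k) == pytest.approx(brute, rel=1e-12)


def test_disjoint_sets_give_p_one():
    universe = [f"g{i}" for i in range(10)]
    overlap, p = gene_set_overlap(universe[:3], universe[5:8], universe)
    assert overlap == [] and p == pytest.approx(1.0)


def test_identical_full_sets_forced_outcome():
    universe = [f"g{i}" for i in range(6)]
    overlap, p = gene_set_overlap(universe, universe, universe)
    assert overlap == sorted(universe) and p == pytest.approx(1.0)


def test_elements_outside_universe_listed():
    with pytest.raises(ValueError, match="gX"):
        gene_set_overlap(["gX"], ["g1"], ["g1", "g2"])


# ---------------------------------------------------------------------------
# intron read counting


def _read(start, end, rid):
    return AlignedTag("chr1", start, end, "+", read_id=rid)


def test_intron_counts_and_ratio():
    reads = [_read(110 + i, 130 + i, f"a{i}") for i in range(30)]
    reads += [_read(510 + i, 530 + i, f"b{i}") for i in range(10)]
    c = count_intron_reads(reads, (100, 400), (500, 900))
    assert (c.count_intron_a, c.count_intron_b) == (30, 10)
    assert c.ratio_a == pytest.approx(0.75)


def test_boundary_spanning_read_counts_for_neither():
    reads = [_read(90, 120, "x")]  # crosses into intron_a
    c = count_intron_reads(reads, (100, 400), (500, 900))
    assert (c.count_intron_a, c.count_intron_b) == (0, 0)
    assert c.ratio_a is None


def test_overlapping_introns_rejected():
    with pytest.raises(ValueError):
        count_intron_reads([], (100, 400), (300, 500))


def test_identical_ratios_give_null_comparison():
    counts = [IsoformCounts("wt", f"r{i}", 10, 10) for i in range(3)]
    counts += [IsoformCounts("mut", f"r{i}", 20, 20) for i in range(3)]
    res = compare_intron_ratios(counts, baseline_genotype="wt")
    assert res.effect == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)


def test_replication_required():
    counts = [IsoformCounts("wt", "r0", 10, 10), IsoformCounts("mut", "r0", 5, 10)]
    with pytest.raises(ValueError, match="replicates"):
        compare_intron_ratios(counts)


def test_retention_shift_gives_positive_effect(default_genome):
    gene = next(g for g in default_genome.genes if g.has_alt_terminal_exons)
    counts = []
    for genotype, frac in (("wt", 0.5), ("mutant", 0.8)):
        reps, _ = simulate_rnaseq_isoforms(
            IsoformSimSpec(gene_id=gene.gene_id, fraction_isoform_a=frac,
                           genotype=genotype, seed=3), gene)
        for i, rep in enumerate(reps):
            c = count_intron_reads(rep, gene.intron_a, gene.intron_b,
                                   genotype=genotype, replicate=f"r{i}")
            counts.append(c)
    res = compare_intron_ratios(counts, baseline_genotype="wt")
    assert res.effect > 0  # mutant shifted toward intron_a
    assert res.p_value < 0.05


# ---------------------------------------------------------------------------
# ddCt


def _ct_table(rows):
    return pd.DataFrame(rows, columns=["sample", "group", "pair", "gene", "ct"])


def test_equal_ct_gives_fold_one_everywhere():
    rows = []
    for grp in ("ctl", "exp"):
        for i in range(3):
            s = f"{grp}{i}"
            rows += [(s, grp, s, "tgt", 24.0), (s, grp, s, "ref", 18.0)]
    res = delta_delta_ct(_ct_table(rows), "ref", "ctl")
    assert np.allclose(res.folds["fold"], 1.0)


def test_one_cycle_lower_target_is_exactly_twofold():
    rows = []
    for grp, ct in (("ctl", 24.0), ("exp", 23.0)):
        for i in range(2):
            s = f"{grp}{i}"
            rows += [(s, grp, s, "tgt", ct), (s, grp, s, "ref", 18.0)]
    res = delta_delta_ct(_ct_table(rows), "ref", "ctl")
    exp = res.folds.query("group == 'exp'")["fold"]
    assert np.allclose(exp, 2.0)


def test_constant_ct_shift_leaves_folds_unchanged():
    table = simulate_qpcr({"ctl": 4, "exp": 4}, effect_sizes={"exp": 1.7},
                          noise_sd=0.3, seed=12)
    shifted = table.assign(ct=table["ct"] + 3.0)
    r1 = delta_delta_ct(table, "actb", "ctl")
    r2 = delta_delta_ct(shifted, "actb", "ctl")
    assert np.allclose(r1.folds["fold"], r2.folds["fold"])


def test_paired_identical_sides_give_ratio_one():
    rows = []
    for i in range(4):
        for side in ("crushed", "uncrushed"):
            s = f"{side}{i}"
            rows += [(s, side, f"animal{i}", "tgt", 25.0),
                     (s, side, f"animal{i}", "ref", 19.0)]
    res = delta_delta_ct(_ct_table(rows), "ref", "uncrushed", paired=True)
    assert np.allclose(res.folds["fold"], 1.0)
    assert res.summary["p"].iloc[0] == pytest.approx(1.0)


def test_paired_missing_side_names_the_animal():
    rows = [("c0", "crushed", "animal0", "tgt", 25.0),
            ("c0", "crushed", "animal0", "ref", 19.0),
            ("u0", "uncrushed", "animal0", "tgt", 25.0),
            ("u0", "uncrushed", "animal0", "ref", 19.0),
            ("c1", "crushed", "animal1", "tgt", 25.0),
            ("c1", "crushed", "animal1", "ref", 19.0)]
    with pytest.raises(ValueError, match="animal1"):
        delta_delta_ct(_ct_table(rows), "ref", "uncrushed", paired=True)


def test_missing_reference_names_the_sample():
    rows = [("s1", "ctl", "s1", "tgt", 25.0),
            ("s2", "ctl", "s2", "tgt", 25.0), ("s2", "ctl", "s2", "ref", 19.0)]
    with pytest.raises(ValueError, match="s1"):
        delta_delta_ct(_ct_table(rows), "ref", "ctl")
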