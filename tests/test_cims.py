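"""CIMS tabulation, permutation null, FDR estimation and peak calling."""

import itertools
from collections import Counter

import numpy as np
import pytest

from clipcims import (
    AlignedTag,
    Mutation,
    MutationSite,
    SimConfig,
    call_cims_peaks,
    estimate_fdr,
    filter_unique,
    generate_genome,
    permute_mutations,
    remove_duplicates,
    simulate_clip_tags,
    tabulate_mutation_sites,
)


def _tag(start, end, muts=(), strand="+", rid=None):
    return AlignedTag("chrI", start, end, strand, tuple(sorted(muts)),
                      read_id=rid or f"r{start}_{end}_{len(muts)}")


def _sub(pos):
    return Mutation(pos, "substitution", "T", "C")


def test_tabulate_counts_k_and_m():
    tags = [_tag(0, 20, [_sub(7)] if i < 3 else [], rid=f"r{i}") for i in range(10)]
    (site,) = tabulate_mutation_sites(tags)
    assert (site.position, site.k, site.m, site.type) == (7, 10, 3, "substitution")


def test_deletion_and_substitution_make_separate_sites():
    tags = [
        _tag(0, 20, [_sub(5)], rid="a"),
        _tag(0, 20, [Mutation(5, "deletion", "T")], rid="b"),
    ]
    sites = tabulate_mutation_sites(tags)
    assert sorted(s.type for s in sites) == ["deletion", "substitution"]
    assert all(s.position == 5 and s.k == 2 and s.m == 1 for s in sites)


def test_no_mutations_no_sites():
    assert tabulate_mutation_sites([_tag(0, 20), _tag(30, 60)]) == []


def test_coverage_is_strand_separated():
    tags = [_tag(0, 20, [_sub(5)], strand="+", rid="a"), _tag(0, 20, strand="-", rid="b")]
    (site,) = tabulate_mutation_sites(tags)
    assert site.k == 1  # the minus-strand tag does not cover the plus-strand site


# ---------------------------------------------------------------------------
# permutation null


def test_permute_leaves_mutation_free_tags_untouched():
    tags = [_tag(0, 20), _tag(30, 60)]
    assert permute_mutations(tags, 0) == tags


def test_permute_conserves_per_tag_counts_and_intervals():
    rng = np.random.default_rng(3)
    tags = []
    for i in range(50):
        start = int(rng.integers(0, 500))
        length = int(rng.integers(5, 40))
        nmut = int(rng.integers(0, min(3, length)))
        muts = [_sub(start + j) for j in range(nmut)]
        tags.append(_tag(start, start + length, muts, rid=f"r{i}"))
    permuted = permute_mutations(tags, 7)
    for before, after in zip(tags, permuted):
        assert (after.start, after.end, after.strand) == (
            before.start, before.end, before.strand
        )
        assert len(after.mutations) == len(before.mutations)
        assert len({m.position for m in after.mutations}) == len(after.mutations)


def test_permute_rejects_overfull_tag():
    overfull = AlignedTag(
        "chrI", 0, 2, "+",
        (_sub(0), _sub(1), Mutation(1, "insertion", "", "A")),
        read_id="x",
    )
    with pytest.raises(ValueError, match="more mutations"):
        permute_mutations([overfull], 0)


def test_permutation_placement_is_uniform():
    """Each offset of a length-20 tag drawn ~1/20 of the time."""
    tag = _tag(0, 20, [_sub(7)])
    rng = np.random.default_rng(11)
    freq = Counter()
    n = 20_000
    for _ in range(n):
        (p,) = permute_mutations([tag], rng)
        freq[p.mutations[0].position] += 1
    for off in range(20):
        assert 0.04 <= freq[off] / n <= 0.06


# ---------------------------------------------------------------------------
# FDR estimation


def _enumeration_oracle_exceedance(n_tags=3, length=20):
    """E[#positions with >= m mutations] by full enumeration of placements."""
    exceed = {m0: 0.0 for m0 in (1, 2, 3)}
    total = length ** n_tags
    for placement in itertools.product(range(length), repeat=n_tags):
        counts = Counter(placement)
        for m0 in exceed:
            exceed[m0] += sum(1 for v in counts.values() if v >= m0)
    return {m0: v / total for m0, v in exceed.items()}


def test_fdr_matches_exhaustive_enumeration_oracle():
    """Three 1-mutation tags stacked on one 20-base window, all mutated at
    the same position (m=3): the permutation estimate must agree with the
    exact 20^3-placement enumeration within 3 Monte-Carlo standard errors."""
    tags = [_tag(0, 20, [_sub(7)], rid=f"r{i}") for i in range(3)]
    (site,) = tabulate_mutation_sites(tags)
    assert site.m == 3 and site.k == 3
    n_perm = 10_000
    est = estimate_fdr([site], tags, n_permutations=n_perm, seed=5)[0].fdr
    oracle = _enumeration_oracle_exceedance()[3]  # = 20 * (1/20)^3 = 0.0025
    assert oracle == pytest.approx(0.0025)
    # per permutation the exceedance count is Bernoulli-like; bound its SE
    se = np.sqrt(oracle * (1 - oracle) / n_perm)
    assert abs(est - oracle) <= 3 * se


def test_fdr_zero_when_null_never_reaches_m():
    # two tags overlapping at a single base, both mutated there (m=2); under
    # permutation a collision needs both draws on that one base (p=1/400),
    # which this seeded 100-permutation run never produces
    tags = [_tag(0, 20, [_sub(19)], rid="a"), _tag(19, 39, [_sub(19)], rid="b")]
    sites = tabulate_mutation_sites(tags)
    site2 = next(s for s in sites if s.m == 2)
    est = estimate_fdr(sites, tags, n_permutations=100, seed=1)
    assert next(s for s in est if s.m == 2).fdr == 0.0


def test_fdr_bounds_and_monotonicity(filtered_tags):
    sites = tabulate_mutation_sites(filtered_tags)
    sites = estimate_fdr(sites, filtered_tags, n_permutations=40, seed=9)
    by_type = {}
    for s in sites:
        assert 0.0 <= s.fdr <= 1.0
        by_type.setdefault(s.type, {})[s.m] = s.fdr
    for fdrs in by_type.values():
        ms = sorted(fdrs)
        for a, b in zip(ms, ms[1:]):
            assert fdrs[b] <= fdrs[a]


def test_fdr_requires_enough_permutations():
    with pytest.raises(ValueError):
        estimate_fdr([], [], n_permutations=5, seed=0)


def test_null_simulation_is_calibrated():
    """Under the matched null (no crosslinking, uniform mutations) almost no
    site reaches FDR < 0.01 and no CIMS peak is called."""
    n_sites = n_signif = n_peaks = 0
    for seed in range(3):
        cfg = SimConfig(seed=seed).null()
        sim = simulate_clip_tags(generate_genome(cfg))
        tags = filter_unique(remove_duplicates(sim.tags))
        sites = estimate_fdr(tabulate_mutation_sites(tags), tags,
                             n_permutations=100, seed=seed + 100)
        n_sites += len(sites)
        n_signif += sum(1 for s in sites if s.fdr < 0.01)
        n_peaks += len(call_cims_peaks(sites))
    assert n_sites > 50
    assert n_signif / n_sites <= 0.02
    assert n_peaks == 0


# ---------------------------------------------------------------------------
# peak calling thresholds


def _site(m, fdr, pos=100, mtype="substitution"):
    return MutationSite("chrI", pos, "+", mtype, k=max(m, 20), m=m, fdr=fdr)


def test_threshold_semantics_match_published_rule():
    assert len(call_cims_peaks([_site(6, 0.005)])) == 1   # passes FDR < 0.01, m > 5
    assert call_cims_peaks([_site(6, 0.02)]) == []        # FDR too high
    assert call_cims_peaks([_site(5, 0.001)]) == []       # m must exceed 5 strictly
    assert len(call_cims_peaks([_site(5, 0.001)], strict_m=False)) == 1


def test_cims_peak_geometry_and_ids():
    peaks = call_cims_peaks(
        [_site(8, 0.001, pos=100), _site(10, 0.0001, pos=300),
         _site(7, 0.002, pos=500, mtype="deletion")],
        extension=10,
    )
    assert [p.id for p in peaks] == ["s1", "s2", "d1"]
    best = next(p for p in peaks if p.id == "s1")
    assert (best.start, best.end) == (290, 311)  # centered on pos 300, +-10
    assert all(p.provenance == "cims" for p in peaks)
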