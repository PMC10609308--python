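import random

import numpy as np
import pytest

from straintag import (
    AlignScoring,
    SequenceRecord,
    ani,
    build_kmer_index,
    find_unique_regions,
    revcomp,
    specificity_filter,
)
from straintag.simdata import mutate_genome, simulate_backbone
from straintag.uniqueness import CandidateRegion, canonical_kmer_values

from .oracles import random_dna


class TestKmerIndex:
    def test_size_upper_bound(self):
        rng = random.Random(0)
        g = SequenceRecord("g", random_dna(rng, 2000))
        index = build_kmer_index([g], 21)
        assert len(index) <= len(g.seq) - 21 + 1

    def test_canonicalisation_makes_strands_equivalent(self):
        rng = random.Random(1)
        g = SequenceRecord("g", random_dna(rng, 3000))
        g_rc = SequenceRecord("g_rc", revcomp(g.seq))
        alone = build_kmer_index([g], 21)
        both = build_kmer_index([g, g_rc], 21)
        assert np.array_equal(alone.members, both.members)

    def test_membership_against_bruteforce_set(self):
        rng = random.Random(2)
        seq = random_dna(rng, 10_000)
        k = 21
        index = build_kmer_index([SequenceRecord("g", seq)], k)
        truth = {
            min(seq[i : i + k], revcomp(seq[i : i + k]))
            for i in range(len(seq) - k + 1)
        }
        for i in range(0, len(seq) - k + 1, 97):
            assert index.contains(seq[i : i + k])
        misses = 0
        while misses < 1000:
            kmer = random_dna(rng, k)
            if min(kmer, revcomp(kmer)) in truth:
                continue
            assert not index.contains(kmer)
            misses += 1

    def test_n_windows_never_stored(self):
        seq = "ACGT" * 10 + "N" + "ACGT" * 10
        values, valid = canonical_kmer_values(seq, 21)
        assert not valid[len(seq) // 2 - 20 : len(seq) // 2 + 1].any()

    def test_k_validation(self):
        g = [SequenceRecord("g", "ACGT" * 100)]
        with pytest.raises(ValueError):
            build_kmer_index(g, 20)
        with pytest.raises(ValueError):
            build_kmer_index(g, 13)


@pytest.fixture(scope="module")
def backbone_with_island():
    rng = random.Random(3)
    backbone = random_dna(rng, 100_000)
    island = random_dna(rng, 1500)
    genome = backbone[:50_000] + island + backbone[50_000:]
    return backbone, island, genome


class TestFindUniqueRegions:

    def test_identical_genome_yields_nothing(self):
        rng = random.Random(4)
        g = SequenceRecord("g", random_dna(rng, 20_000))
        index = build_kmer_index([g], 21)
        assert find_unique_regions([g], index) == []

    def test_island_recovered(self, backbone_with_island):
        backbone, island, genome = backbone_with_island
        index = build_kmer_index([SequenceRecord("bg", backbone)], 21)
        regions = find_unique_regions([SequenceRecord("t", genome)], index)
        assert len(regions) == 1
        region = regions[0]
        lo, hi = 50_000, 50_000 + len(island)
        overlap = min(region.end, hi) - max(region.start, lo)
        assert overlap / len(island) >= 0.95
        assert overlap / len(region) >= 0.95
        assert region.seq == genome[region.start : region.end]

    def test_short_island_filtered_by_min_len(self):
        rng = random.Random(5)
        backbone = random_dna(rng, 50_000)
        island = random_dna(rng, 800)
        genome = backbone[:20_000] + island + backbone[20_000:]
        index = build_kmer_index([SequenceRecord("bg", backbone)], 21)
        assert find_unique_regions([SequenceRecord("t", genome)], index, min_len=1000) == []

    def test_monotone_in_background(self, backbone_with_island):
        backbone, island, genome = backbone_with_island
        rng = random.Random(6)
        extra = SequenceRecord("x", random_dna(rng, 30_000) + island[:700])
        small = build_kmer_index([SequenceRecord("bg", backbone)], 21)
        large = build_kmer_index([SequenceRecord("bg", backbone), extra], 21)
        before = find_unique_regions([SequenceRecord("t", genome)], small)
        after = find_unique_regions([SequenceRecord("t", genome)], large)
        assert len(after) <= len(before)
        total = lambda rs: sum(len(r) for r in rs)
        assert total(after) <= total(before)

    def test_reported_kmers_absent_from_background(self, backbone_with_island):
        backbone, _, genome = backbone_with_island
        index = build_kmer_index([SequenceRecord("bg", backbone)], 21)
        (region,) = find_unique_regions([SequenceRecord("t", genome)], index)
        # interior spot-check: every k-mer fully inside the unique run core
        core = region.seq[100:-100]
        for i in range(0, len(core) - 21 + 1, 13):
            assert not index.contains(core[i : i + 21])

    def test_empty_target(self):
        rng = random.Random(7)
        index = build_kmer_index([SequenceRecord("bg", random_dna(rng, 20_000))], 21)
        assert find_unique_regions([], index) == []

    def test_min_len_must_cover_k(self):
        rng = random.Random(8)
        g = SequenceRecord("g", random_dna(rng, 20_000))
        index = build_kmer_index([g], 21)
        with pytest.raises(ValueError):
            find_unique_regions([g], index, min_len=10)


class TestSpecificityFilter:
    def test_region_copied_from_nontarget_excluded(self):
        rng = random.Random(9)
        nontarget = SequenceRecord("nt", random_dna(rng, 5000))
        target = SequenceRecord("t", random_dna(rng, 5000))
        region = CandidateRegion("t", 0, 1000, nontarget.seq[1000:2000])
        kept = specificity_filter([region], [target], [nontarget])
        assert kept == []

    def test_region_from_target_passes_target_test(self):
        rng = random.Random(10)
        target = SequenceRecord("t", random_dna(rng, 5000))
        region = CandidateRegion("t", 2000, 3200, target.seq[2000:3200])
        kept = specificity_filter([region], [target], [SequenceRecord("nt", random_dna(rng, 5000))])
        assert kept == [region]
        assert region.target_score >= 2000
        assert region.max_nontarget_score < 40

    def test_30bp_exact_offtarget_match_excluded(self):
        rng = random.Random(11)
        region_seq = random_dna(rng, 1200)
        nontarget_seq = random_dna(rng, 4000)
        # implant 30 exact bases of the region into the non-target: score 60
        nontarget_seq = nontarget_seq[:2000] + region_seq[500:530] + nontarget_seq[2030:]
        region = CandidateRegion("t", 0, 1200, region_seq)
        target = SequenceRecord("t", region_seq + random_dna(rng, 2000))
        kept = specificity_filter([region], [target], [SequenceRecord("nt", nontarget_seq)])
        assert kept == []

    def test_empty_nontarget_warns_and_passes_vacuously(self):
        rng = random.Random(12)
        target = SequenceRecord("t", random_dna(rng, 3000))
        region = CandidateRegion("t", 0, 1100, target.seq[:1100])
        with pytest.warns(UserWarning, match="vacuous"):
            kept = specificity_filter([region], [target], [])
        assert kept == [region]


class TestANI:
    def test_self_identity(self):
        g = simulate_backbone(20_000, 0.45, 21)
        assert ani([g], [g], fragment_len=1020) == (100.0, 100.0)

    def test_known_mutation_rate_recovered(self):
        g = simulate_backbone(50_000, 0.45, 22)
        m = mutate_genome(g, 0.01, 23)
        value, coverage = ani([g], [m])
        assert value == pytest.approx(99.0, abs=0.2)
        assert coverage > 95.0

    def test_sibling_regime_above_98(self):
        g = simulate_backbone(50_000, 0.45, 24)
        m = mutate_genome(g, 0.001, 25)
        value, _ = ani([g], [m])
        assert value > 98.0

    def test_near_symmetry_on_siblings(self):
        g = simulate_backbone(30_000, 0.45, 26)
        m = mutate_genome(g, 0.005, 27)
        ab, _ = ani([g], [m])
        ba, _ = ani([m], [g])
        assert abs(ab - ba) < 1.0

    def test_too_short_genome_rejected(self):
        g = SequenceRecord("g", "ACGT" * 100)
        with pytest.raises(ValueError):
            ani([g], [g], fragment_len=1020)
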