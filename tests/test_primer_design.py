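import itertools
import random

import pytest

from straintag import (
    DesignConstraints,
    SequenceRecord,
    SpecificityRules,
    enumerate_candidates,
    find_binding_sites,
    insilico_pcr,
    is_unintended_binder,
    revcomp,
    specificity_verdict,
)
from straintag.primer_design import BindingSite, PrimerPair
from straintag.uniqueness import CandidateRegion

from .oracles import binding_sites_bruteforce, random_dna


def _region(seq: str, rid: str = "r") -> CandidateRegion:
    return CandidateRegion(rid, 0, len(seq), seq)


class TestEnumerateCandidates:
    def test_too_short_region_warns_empty(self):
        with pytest.warns(UserWarning):
            assert enumerate_candidates(_region("ACGT" * 20)) == []

    def test_all_returned_pairs_satisfy_constraints(self, small_bundle):
        constraints = DesignConstraints()
        from straintag import tm_nn, gc_percent, dimer_dg

        region_seq = small_bundle.target[0].seq
        lo, hi = small_bundle.truth.islands[0][1], small_bundle.truth.islands[0][2]
        region = _region(region_seq[lo:hi], "island0")
        pairs = enumerate_candidates(region, constraints, max_candidates=40)
        assert pairs
        for p in pairs:
            for primer in (p.fwd, p.rev):
                assert constraints.size_min <= len(primer) <= constraints.size_max
                assert constraints.gc_min <= gc_percent(primer) <= constraints.gc_max
                assert dimer_dg(primer, primer) >= constraints.dimer_dg_floor
            assert abs(tm_nn(p.fwd) - tm_nn(p.rev)) <= constraints.max_tm_diff
            assert constraints.product_min <= p.product_len <= constraints.product_max
            assert p.product_len == p.rev_end - p.fwd_start
            assert dimer_dg(p.fwd, p.rev) >= constraints.dimer_dg_floor
            # primers reproduce the template at their coordinates
            assert region.seq[p.fwd_start : p.fwd_start + len(p.fwd)] == p.fwd
            assert region.seq[p.rev_end - len(p.rev) : p.rev_end] == revcomp(p.rev)

    def test_deterministic_ranking(self, small_bundle):
        lo, hi = small_bundle.truth.islands[0][1], small_bundle.truth.islands[0][2]
        region = _region(small_bundle.target[0].seq[lo:hi], "island0")
        first = enumerate_candidates(region, max_candidates=10)
        second = enumerate_candidates(region, max_candidates=10)
        assert [(p.fwd, p.rev) for p in first] == [(p.fwd, p.rev) for p in second]

    def test_tightening_constraints_never_enlarges_output(self, small_bundle):
        lo, hi = small_bundle.truth.islands[0][1], small_bundle.truth.islands[0][2]
        region = _region(small_bundle.target[0].seq[lo:hi], "island0")
        base = {(p.fwd, p.rev) for p in enumerate_candidates(region)}
        for tightened in (
            DesignConstraints(gc_min=48.0),
            DesignConstraints(max_tm_diff=0.5),
            DesignConstraints(product_max=300),
            DesignConstraints(size_min=21, size_max=24),
        ):
            subset = {(p.fwd, p.rev) for p in enumerate_candidates(region, tightened)}
            assert subset <= base


class TestBindingSites:
    def test_exact_match_site(self):
        rng = random.Random(31)
        genome = random_dna(rng, 3000)
        primer = genome[1000:1022]
        sites = find_binding_sites(primer, [SequenceRecord("g", genome)])
        exact = [s for s in sites if s.total_mismatches == 0]
        assert any(s.start == 1000 and s.strand == "+" and s.last5_mismatches == 0 for s in exact)

    def test_nine_mismatch_sites_ignored(self):
        primer = "ACGTACGTACGTACGTACGT"
        corrupted = list(primer)
        for i in range(0, 18, 2):  # 9 substitutions
            corrupted[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[corrupted[i]]
        genome = "TTTT" + "".join(corrupted) + "TTTT"
        sites = find_binding_sites(primer, [SequenceRecord("g", genome)])
        assert all(s.start != 4 or s.total_mismatches < 9 for s in sites)

    def test_agrees_with_sliding_window_oracle(self):
        rng = random.Random(32)
        genome = random_dna(rng, 5000)
        for _ in range(3):
            primer = genome[rng.randrange(0, 4000) :][:22]
            got = {
                (s.start, s.strand, s.total_mismatches, s.last5_mismatches)
                for s in find_binding_sites(primer, [SequenceRecord("g", genome)])
            }
            expected = set(binding_sites_bruteforce(primer, genome))
            assert got == expected

    def test_strand_symmetry(self):
        rng = random.Random(33)
        genome = random_dna(rng, 4000)
        primer = genome[500:522]
        fwd_sites = find_binding_sites(primer, [SequenceRecord("g", genome)])
        rc_sites = find_binding_sites(primer, [SequenceRecord("g", revcomp(genome))])
        n = len(genome)
        mirrored = {
            (n - (s.start + len(primer)), {"+": "-", "-": "+"}[s.strand],
             s.total_mismatches, s.last5_mismatches)
            for s in rc_sites
        }
        original = {
            (s.start, s.strand, s.total_mismatches, s.last5_mismatches)
            for s in fwd_sites
        }
        assert mirrored == original


class TestUnintendedBinder:
    def test_truth_table(self):
        rules = SpecificityRules()
        for total, last5 in itertools.product(range(9), range(6)):
            if last5 > min(5, total):
                continue
            site = BindingSite("g", 0, "+", total, last5)
            expected = total < 6 and last5 < 5
            assert is_unintended_binder(site, rules) is expected

    def test_perfect_match_primes(self):
        assert is_unintended_binder(BindingSite("g", 0, "+", 0, 0))

    def test_seven_total_mismatches_cannot_prime(self):
        assert not is_unintended_binder(BindingSite("g", 0, "+", 7, 2))


def _pair_from_template(template: str, product: int, rid: str = "r") -> PrimerPair:
    fwd = template[:22]
    rev = revcomp(template[product - 22 : product])
    return PrimerPair(
        fwd=fwd, rev=rev, region_id=rid, fwd_start=0, rev_end=product,
        product_len=product, tm_fwd=0.0, tm_rev=0.0, gc_fwd=0.0, gc_rev=0.0,
    )


class TestInsilicoPcr:
    def test_absent_primers_no_product(self):
        rng = random.Random(41)
        pair = _pair_from_template(random_dna(rng, 400), 300)
        genome = SequenceRecord("g", random_dna(rng, 5000))
        assert insilico_pcr(pair, [genome]) == []

    def test_implanted_sites_give_expected_product(self):
        rng = random.Random(42)
        template = random_dna(rng, 400)
        pair = _pair_from_template(template, 300)
        genome_seq = random_dna(rng, 3000) + template[:300] + random_dna(rng, 3000)
        amps = insilico_pcr(pair, [SequenceRecord("g", genome_seq)])
        assert len(amps) == 1
        assert amps[0].length == 300
        assert amps[0].start == 3000

    def test_flipped_orientation_also_amplifies(self):
        rng = random.Random(43)
        template = random_dna(rng, 400)
        pair = _pair_from_template(template, 300)
        genome_seq = random_dna(rng, 2000) + revcomp(template[:300]) + random_dna(rng, 2000)
        amps = insilico_pcr(pair, [SequenceRecord("g", genome_seq)])
        assert [a.length for a in amps] == [300]

    def test_amplicon_respects_max_size(self):
        rng = random.Random(44)
        left = random_dna(rng, 22)
        right = random_dna(rng, 22)
        spacer = random_dna(rng, 5000)
        genome = SequenceRecord("g", left + spacer + revcomp(right))
        pair = PrimerPair(
            fwd=left, rev=right, region_id="r", fwd_start=0, rev_end=0,
            product_len=0, tm_fwd=0, tm_rev=0, gc_fwd=0, gc_rev=0,
        )
        assert insilico_pcr(pair, [genome], SpecificityRules(max_amplicon=4000)) == []
        assert len(insilico_pcr(pair, [genome], SpecificityRules(max_amplicon=6000))) == 1


class TestSpecificityVerdict:
    def test_pass_on_unique_template(self):
        rng = random.Random(51)
        template = random_dna(rng, 400)
        pair = _pair_from_template(template, 300)
        target = SequenceRecord("t", random_dna(rng, 2000) + template + random_dna(rng, 2000))
        nontarget = SequenceRecord("nt", random_dna(rng, 4000))
        verdict = specificity_verdict(pair, [target], [nontarget])
        assert verdict.passed
        assert len(verdict.target_amplicons) == 1

    def test_fail_when_region_copied_into_nontarget(self):
        rng = random.Random(52)
        template = random_dna(rng, 400)
        pair = _pair_from_template(template, 300)
        target = SequenceRecord("t", template + random_dna(rng, 2000))
        nontarget = SequenceRecord("nt", random_dna(rng, 1000) + template + random_dna(rng, 1000))
        verdict = specificity_verdict(pair, [target], [nontarget])
        assert not verdict.passed
        assert verdict.offtarget_amplicons
        assert verdict.offtarget_amplicons[0][0] == "nt"

    def test_fail_on_duplicated_target_locus(self):
        rng = random.Random(53)
        template = random_dna(rng, 400)
        pair = _pair_from_template(template, 300)
        target = SequenceRecord("t", template + random_dna(rng, 1000) + template)
        verdict = specificity_verdict(pair, [target], [])
        assert not verdict.passed
        # both copies amplify, and the two outer sites bracket a third product
        assert len(verdict.target_amplicons) >= 2
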