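import numpy as np
import pytest

from temir import (
    GenomicInterval,
    MATURE_MIR1302,
    ScanConfig,
    excise_precursors,
    find_seed_matches,
    make_consensus_element,
    scan_paralogs,
    seed_of,
    transcribed_not_exonic,
)
from temir.genome_io import RepeatAnnotation, revcomp, normalize_nt

MATURE_DNA = MATURE_MIR1302.replace("U", "T")


def element_genome(strand="+", pad=500, seed=1):
    """One chromosome containing a single intact seed-carrying element."""
    rng = np.random.default_rng(seed)
    el = make_consensus_element(193, 9, rng, mature=MATURE_MIR1302,
                                mature_offset=49)
    if strand == "-":
        el = revcomp(el)
    left = "".join(rng.choice(list("ACGT"), pad))
    right = "".join(rng.choice(list("ACGT"), pad))
    genome = {"chr1": left + el + right}
    ann = RepeatAnnotation(
        GenomicInterval("chr1", pad + 1, pad + 193, "+"), "MER53"
    )
    return genome, ann


class TestSeedOf:
    def test_printed_mature_gives_printed_seed(self):
        assert seed_of("UUGGGACAUACUUAUGCUAAA") == "UGGGACA"

    def test_positional_slice(self):
        assert seed_of("AACGTACGT") == "ACGTACG"

    def test_short_mature_rejected(self):
        with pytest.raises(ValueError):
            seed_of("ACGTACG")


class TestFindSeedMatches:
    def test_overlapping_occurrences_counted(self):
        genome = {"c": "AAAAAAAA"}
        el = RepeatAnnotation(GenomicInterval("c", 1, 8), "MER53")
        hits = find_seed_matches(genome, [el], "AAAAAAA", both_strands=False)
        assert [(h.offset, h.strand) for h in hits] == [(0, "+"), (1, "+")]

    def test_minus_strand_implant_found_once(self):
        genome, ann = element_genome(strand="-")
        seed = seed_of(MATURE_MIR1302)
        hits = find_seed_matches(genome, [ann], seed)
        minus = [h for h in hits if h.strand == "-"]
        assert len(minus) == 1
        # invariant: the 7-mer at the offset equals the seed on that strand
        plus_seq = genome["c" if "c" in genome else "chr1"]
        el_seq = ann.interval.slice_of(plus_seq)
        oriented = revcomp(el_seq)
        off = minus[0].offset
        assert normalize_nt(oriented[off:off + 7]) == normalize_nt(seed)

    def test_element_without_seed_is_empty(self):
        genome = {"c": "ACGT" * 50}
        el = RepeatAnnotation(GenomicInterval("c", 1, 200), "MER53")
        assert find_seed_matches(genome, [el], "TTTTTTT") == []

    def test_element_outside_genome_rejected(self):
        genome = {"c": "ACGTACGTAC"}
        el = RepeatAnnotation(GenomicInterval("c", 5, 50), "MER53")
        with pytest.raises(ValueError, match="outside"):
            find_seed_matches(genome, [el], "ACGTACG")


class TestExcisePrecursors:
    def test_two_windows_both_contain_seed(self):
        genome, ann = element_genome(strand="+")
        seed = seed_of(MATURE_MIR1302)
        (hit,) = [
            h for h in find_seed_matches(genome, [ann], seed)
            if h.strand == "+"
        ]
        cands = excise_precursors(genome, hit)
        assert [c.arm for c in cands] == ["left", "right"]
        for c in cands:
            assert c.interval.length == 110 and len(c.seq) == 110
            assert normalize_nt(seed) in normalize_nt(c.seq)

    def test_truncated_windows_dropped_at_chromosome_edges(self, caplog):
        # seed ~60 nt from the chromosome end: the left-arm window (which
        # extends 3' of the mature) runs off the end and is dropped, while
        # the right-arm window still fits
        genome = {"c": "C" * 340 + "TGGGACA" + "A" * 53}
        el = RepeatAnnotation(GenomicInterval("c", 301, 400), "MER53")
        (hit,) = find_seed_matches(genome, [el], "TGGGACA",
                                   both_strands=False)
        with caplog.at_level("WARNING", logger="temir"):
            cands = excise_precursors(genome, hit)
        assert [c.arm for c in cands] == ["right"]
        assert any("truncated" in r.message for r in caplog.records)
        # seed close to the chromosome start: both windows reach past
        # position 1 and are dropped
        genome2 = {"c": "AAAAA" + "TGGGACA" + "C" * 300}
        el2 = RepeatAnnotation(GenomicInterval("c", 1, 312), "MER53")
        (hit2,) = find_seed_matches(genome2, [el2], "TGGGACA",
                                    both_strands=False)
        assert excise_precursors(genome2, hit2) == []

    def test_minus_strand_windows_mirror_plus(self):
        g_plus, ann_plus = element_genome(strand="+", seed=7)
        g_minus, ann_minus = element_genome(strand="-", seed=7)
        seed = seed_of(MATURE_MIR1302)
        plus_hit = [h for h in find_seed_matches(g_plus, [ann_plus], seed)
                    if h.strand == "+"][0]
        minus_hit = [h for h in find_seed_matches(g_minus, [ann_minus], seed)
                     if h.strand == "-"][0]
        plus_left = excise_precursors(g_plus, plus_hit)[0]
        minus_left = excise_precursors(g_minus, minus_hit)[0]
        assert plus_left.arm == minus_left.arm == "left"
        # identical element content, so identical oriented window sequences
        assert normalize_nt(plus_left.seq) == normalize_nt(minus_left.seq)

    def test_left_arm_passes_hairpin_right_arm_fails(self):
        genome, ann = element_genome(strand="+")
        seed = seed_of(MATURE_MIR1302)
        hit = [h for h in find_seed_matches(genome, [ann], seed)
               if h.strand == "+"][0]
        cands = scan_paralogs(genome, [ann], MATURE_MIR1302, None, None,
                              ScanConfig(est_policy="pass"))
        by_arm = {(c.arm, c.interval.strand): c.hairpin.accepted
                  for c in cands}
        assert by_arm[("left", "+")] is True
        assert by_arm[("right", "+")] is False


class TestTranscriptionFilter:
    def make_candidate(self):
        genome, ann = element_genome()
        seed = seed_of(MATURE_MIR1302)
        hit = find_seed_matches(genome, [ann], seed, both_strands=False)[0]
        return genome, excise_precursors(genome, hit)[0]

    def test_inside_est_outside_exons(self):
        genome, cand = self.make_candidate()
        est = [GenomicInterval("chr1", 1, len(genome["chr1"]))]
        transcribed_not_exonic(cand, est, [])
        assert cand.transcribed and not cand.exonic

    def test_one_bp_exon_overlap_kills_call(self):
        genome, cand = self.make_candidate()
        est = [GenomicInterval("chr1", 1, len(genome["chr1"]))]
        exon = [GenomicInterval("chr1", cand.interval.end,
                                cand.interval.end + 100)]
        transcribed_not_exonic(cand, est, exon)
        assert cand.exonic and not cand.final_call

    def test_missing_est_track_policy(self):
        _, cand = self.make_candidate()
        transcribed_not_exonic(cand, None, None, est_policy="strict")
        assert not cand.transcribed
        transcribed_not_exonic(cand, None, None, est_policy="pass")
        assert cand.transcribed


class TestScanParalogs:
    def test_recovers_exactly_the_carriers(self, small_genome_sim):
        sim = small_genome_sim
        cands = scan_paralogs(sim.records, sim.repeats, MATURE_MIR1302,
                              sim.ests, sim.exons)
        final = [c for c in cands if c.final_call]
        carriers = [t for t in sim.truth if t.carrier]
        recovered = [
            t for t in carriers
            if any(c.interval.overlaps(t.interval) for c in final)
        ]
        assert len(recovered) == len(carriers) == 5
        decoy_calls = [
            c for c in final
            if not any(c.interval.overlaps(t.interval) for t in carriers)
        ]
        assert decoy_calls == []

    def test_every_final_candidate_contains_seed_on_reported_strand(
        self, small_genome_sim
    ):
        sim = small_genome_sim
        seed = normalize_nt(seed_of(MATURE_MIR1302))
        cands = scan_paralogs(sim.records, sim.repeats, MATURE_MIR1302,
                              sim.ests, sim.exons)
        genome = {r.id: r.seq for r in sim.records}
        for c in cands:
            if c.final_call:
                assert seed in normalize_nt(c.interval.slice_of(
                    genome[c.interval.chrom]))

    def test_exonic_implant_audited_but_not_called(self):
        genome, ann = element_genome()
        est = [GenomicInterval("chr1", 1, len(genome["chr1"]))]
        exons = [GenomicInterval("chr1", ann.interval.start,
                                 ann.interval.end)]
        cands = scan_paralogs(genome, [ann], MATURE_MIR1302, est, exons)
        assert cands  # audit trail keeps the candidates
        assert all(not c.final_call for c in cands)
        assert any(c.hairpin.accepted and c.exonic for c in cands)

    def test_rescan_is_bit_identical(self, small_genome_sim):
        sim = small_genome_sim
        def run():
            return [
                (c.interval.to_string(), c.arm, c.final_call,
                 tuple(c.hairpin.reasons))
                for c in scan_paralogs(sim.records, sim.repeats,
                                       MATURE_MIR1302, sim.ests, sim.exons)
            ]
        assert run() == run()

    def test_empty_element_list_is_clean(self):
        assert scan_paralogs({"c": "ACGT" * 100}, [], MATURE_MIR1302,
                             None, None) == []
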