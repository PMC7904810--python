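"""Unit behavior of each locus-caller stage on constructed fixtures."""

import os

import pytest

from neotel.io_formats import AlignmentRecord, Config, CopySegment
from neotel.repeat_loci import (
    CandidateRegion,
    DiscordantAnchor,
    RepeatLocus,
    TwoSidedEvent,
    associate_copy_number,
    call_hotspots,
    cluster_regions,
    filter_panel_of_normals,
    find_discordant_anchors,
    insertion_evidence,
    microhomology,
    pair_two_sided,
    refine_junction,
)

TEL = "TTAGGG" * 17  # 102 bp telomeric
NONTEL = ("ACGGTA" * 17)[:102]


def _pair(anchor_mapq=60, anchor_seq=NONTEL, mate_seq=TEL, mate_mapped=False,
          proper=False, rid="p1", pos=5000):
    anchor = AlignmentRecord(
        rid, "sim1", pos, anchor_mapq, "+", [("M", len(anchor_seq))], anchor_seq,
        mate_chrom=None if not mate_mapped else "sim1",
        mate_pos=None if not mate_mapped else pos + 300,
        mate_strand="-", is_proper_pair=proper,
    )
    if mate_mapped:
        mate = AlignmentRecord(
            rid, "sim1", pos + 300, 60, "-", [("M", len(mate_seq))], mate_seq,
            mate_chrom="sim1", mate_pos=pos, mate_strand="+",
            is_proper_pair=proper, is_read1=False,
        )
    else:
        mate = AlignmentRecord(
            rid, None, None, 0, "-", [], mate_seq,
            mate_chrom="sim1", mate_pos=pos, mate_strand="+",
            is_proper_pair=proper, is_read1=False,
        )
    return [anchor, mate]


class TestDiscordantAnchors:
    def test_high_mapq_anchor_with_unmapped_telomeric_mate(self):
        (a,) = find_discordant_anchors(_pair())
        assert a.anchor_pos == 5000 and a.anchor_mapq == 60

    def test_mapq_30_boundary_excluded(self):
        assert find_discordant_anchors(_pair(anchor_mapq=30)) == []
        assert find_discordant_anchors(_pair(anchor_mapq=31)) != []

    def test_both_ends_telomeric_excluded(self):
        assert find_discordant_anchors(_pair(anchor_seq=TEL)) == []

    def test_proper_pairs_and_orphans_excluded(self):
        assert find_discordant_anchors(_pair(proper=True)) == []
        assert find_discordant_anchors(_pair()[:1]) == []  # orphan


def _anchors(positions, chrom="sim1"):
    return [
        DiscordantAnchor(f"a{i}", chrom, p, 60, "+") for i, p in enumerate(positions)
    ]


class TestClusterRegions:
    def test_four_anchors_within_600bp_make_one_region(self):
        regions = cluster_regions(_anchors([100, 300, 500, 700]), [])
        assert len(regions) == 1
        assert regions[0].tumor_discordant == 4

    def test_three_anchors_insufficient(self):
        assert cluster_regions(_anchors([100, 300, 500]), []) == []

    def test_control_anchor_inside_padded_span_vetoes(self):
        tumor = _anchors([100, 300, 500, 700])
        control = _anchors([650])
        assert cluster_regions(tumor, control) == []
        far_control = _anchors([5000])
        assert len(cluster_regions(tumor, far_control)) == 1

    def test_tile_mode_counts_fixed_windows(self):
        cfg = Config(cluster_mode="tile")
        # 4 anchors split 2/2 across the 1 kb tile boundary: no tile reaches 4
        split = _anchors([900, 950, 1050, 1100])
        assert cluster_regions(split, [], cfg) == []
        # linkage mode joins them
        assert len(cluster_regions(split, [])) == 1


class TestPanelOfNormals:
    def _region(self):
        return CandidateRegion("sim1", 5000, 5400, tumor_discordant=6)

    def test_fifteen_sample_boundary(self):
        region_hit = [_anchors([5100])] * 15
        assert filter_panel_of_normals([self._region()], region_hit) == []
        kept = filter_panel_of_normals([self._region()], [_anchors([5100])] * 14 + [[]])
        assert len(kept) == 1

    def test_counts_samples_not_reads(self):
        one_sample = [_anchors(range(5000, 5300, 10))] + [[]] * 15  # 30 reads, 1 sample
        kept = filter_panel_of_normals([self._region()], one_sample)
        assert len(kept) == 1 and kept[0].pon_hit_samples == 1

    def test_small_panel_is_inert(self):
        kept = filter_panel_of_normals([self._region()], [_anchors([5100])] * 5)
        assert len(kept) == 1


def _split_read(pos, m, clip_seq, side="right", rid="s", chrom="sim1"):
    anchor_seq = NONTEL[:m]
    if side == "right":
        seq = anchor_seq + clip_seq
        cigar = [("M", m), ("S", len(clip_seq))]
    else:
        seq = clip_seq + anchor_seq
        cigar = [("S", len(clip_seq)), ("M", m)]
    return AlignmentRecord(rid, chrom, pos, 60, "+", cigar, seq)


class TestRefineJunction:
    REGION = CandidateRegion("sim1", 4700, 4950, tumor_discordant=5)

    def test_three_agreeing_split_reads_define_the_junction(self):
        reads = [
            _split_read(5000 - 30, 30, "TTAGGG" * 3, rid=f"s{i}") for i in range(3)
        ]
        locus = refine_junction(self.REGION, reads)
        assert locus is not None
        assert (locus.junction, locus.orientation, locus.n_split) == (5000, "tel_right", 3)
        assert locus.repeat_phase == 0

    def test_two_split_reads_insufficient(self):
        reads = [
            _split_read(5000 - 30, 30, "TTAGGG" * 3, rid=f"s{i}") for i in range(2)
        ]
        assert refine_junction(self.REGION, reads) is None

    def test_clips_without_telomeric_motif_rejected(self):
        reads = [
            _split_read(5000 - 30, 30, "ACGTAC" * 3, rid=f"s{i}") for i in range(3)
        ]
        assert refine_junction(self.REGION, reads) is None

    def test_disagreeing_boundaries_do_not_pool(self):
        reads = [
            _split_read(5000 - 30 + i, 30, "TTAGGG" * 3, rid=f"s{i}")
            for i in range(3)  # boundaries 5000, 5001, 5002
        ]
        assert refine_junction(self.REGION, reads) is None
        cfg = Config(junction_tolerance_bp=2)
        assert refine_junction(self.REGION, reads, cfg) is not None

    def test_left_clip_gives_tel_left(self):
        reads = [
            _split_read(5000, 30, "CCCTAA" * 3, side="left", rid=f"s{i}")
            for i in range(3)
        ]
        locus = refine_junction(self.REGION, reads)
        assert (locus.junction, locus.orientation) == (5000, "tel_left")
        assert locus.repeat_phase == 5  # junction-adjacent base is the final A


def _mh_oracle(ref, junction, orientation, phase):
    """Independent oracle: common-prefix length against a rotated repeat."""
    if orientation == "tel_right":
        rot = "TTAGGG"[phase:] + "TTAGGG"[:phase]
        extension_left = (rot * 20)[-100:]
        flank = ref[:junction][-100:]
        return len(os.path.commonprefix([flank[::-1], extension_left[::-1]]))
    rot = "CCCTAA"[phase + 1 :] + "CCCTAA"[: phase + 1]
    extension_right = (rot * 20)[:100]
    flank = ref[junction : junction + 100]
    return len(os.path.commonprefix([flank, extension_right]))


class TestMicrohomology:
    def test_engineered_flank_phase4_scores_four(self):
        # flank ...AATTAG, telomere resumes at phase 4 ("GG TTAGGG...")
        ref = {"c": "C" * 20 + "AATTAG" + "TTTTTT"}
        locus = RepeatLocus("c", 26, "tel_right", 3, 4, repeat_phase=4)
        assert microhomology(locus, ref) == 4
        assert _mh_oracle(ref["c"], 26, "tel_right", 4) == 4

    def test_mismatching_flank_scores_zero(self):
        ref = {"c": "A" * 20 + "CCCC" + "T" * 10}  # expected G before phase-0 start
        locus = RepeatLocus("c", 24, "tel_right", 3, 4, repeat_phase=0)
        assert microhomology(locus, ref) == 0

    def test_full_hexamer_flank_scores_six(self):
        ref = {"c": "A" * 20 + "TTAGGG" + "T" * 10}
        locus = RepeatLocus("c", 26, "tel_right", 3, 4, repeat_phase=0)
        assert microhomology(locus, ref) == 6

    @pytest.mark.parametrize("k", range(7))
    @pytest.mark.parametrize("orientation", ["tel_right", "tel_left"])
    def test_simulated_flanks_score_exactly_k(self, k, orientation):
        from neotel.synthetic_data import SimEvent, SimScenario, make_genome

        sc = SimScenario(
            seed=40 + k,
            genome_length_bp=10_000,
            events=[SimEvent("sim1", 5_000, orientation, microhomology_bp=k)],
        )
        genome = make_genome(sc)
        phase = 0 if orientation == "tel_right" else 5
        locus = RepeatLocus("sim1", 5_000, orientation, 3, 4, repeat_phase=phase)
        assert microhomology(locus, genome) == k
        assert _mh_oracle(genome["sim1"], 5_000, orientation, phase) == k

    def test_contig_edge_returns_none(self):
        locus = RepeatLocus("c", 3, "tel_right", 3, 4, repeat_phase=0)
        assert microhomology(locus, {"c": "A" * 50}) is None


def _locus(junction, orientation):
    return RepeatLocus("sim1", junction, orientation, 3, 4)


class TestTwoSidedPairing:
    def test_opposite_orientation_within_10kb_pairs(self):
        events, loci = pair_two_sided([_locus(1000, "tel_right"), _locus(6000, "tel_left")])
        assert len(events) == 1 and events[0].gap_bp == 5000
        assert all(l.sidedness == "two_sided_member" for l in loci)

    def test_gap_over_10kb_stays_one_sided(self):
        events, loci = pair_two_sided([_locus(1000, "tel_right"), _locus(16_000, "tel_left")])
        assert events == [] and all(l.sidedness == "one_sided" for l in loci)

    def test_same_orientation_never_pairs(self):
        events, _ = pair_two_sided([_locus(1000, "tel_right"), _locus(6000, "tel_right")])
        assert events == []

    def test_each_locus_in_at_most_one_event(self):
        loci = [_locus(1000, "tel_right"), _locus(3000, "tel_left"), _locus(5000, "tel_left")]
        events, _ = pair_two_sided(loci)
        assert len(events) == 1 and events[0].gap_bp == 2000  # nearest pairing


class TestInsertionEvidence:
    def _event(self):
        return TwoSidedEvent(_locus(5000, "tel_right"), _locus(8000, "tel_left"), 3000)

    def test_empty_read_set_is_false(self):
        assert insertion_evidence(self._event(), []) is False

    def test_spanning_pair_detected(self):
        rid = "span"
        left = AlignmentRecord(rid, "sim1", 4800, 60, "+", [("M", 100)], "A" * 100)
        right = AlignmentRecord(rid, "sim1", 8100, 60, "-", [("M", 100)], "A" * 100,
                                is_read1=False)
        event = self._event()
        assert insertion_evidence(event, [left, right]) is True
        assert event.true_insertion_evidence

    def test_low_mapq_pair_ignored(self):
        rid = "span"
        left = AlignmentRecord(rid, "sim1", 4800, 20, "+", [("M", 100)], "A" * 100)
        right = AlignmentRecord(rid, "sim1", 8100, 20, "-", [("M", 100)], "A" * 100,
                                is_read1=False)
        assert insertion_evidence(self._event(), [left, right]) is False


class TestCopyNumberAssociation:
    def test_distal_loss_at_boundary(self):
        segs = [CopySegment("sim1", 0, 10_000, 2, 1), CopySegment("sim1", 10_000, 20_000, 1, 0)]
        locus = _locus(10_000, "tel_right")
        assert associate_copy_number(locus, segs) == "loss"
        # symmetric: telomere on the low side of the same boundary
        assert associate_copy_number(_locus(10_000, "tel_left"), segs) == "gain"

    def test_flat_profile_is_neutral_no_sv(self):
        segs = [CopySegment("sim1", 0, 20_000, 2, 1)]
        assert associate_copy_number(_locus(10_000, "tel_right"), segs) == "neutral_no_SV"

    def test_flat_profile_with_nearby_sv(self):
        segs = [CopySegment("sim1", 0, 20_000, 2, 1)]
        cls = associate_copy_number(
            _locus(10_000, "tel_right"), segs, sv_breakpoints=[14_000]
        )
        assert cls == "neutral_with_SV"

    def test_boundary_beyond_tolerance_ignored(self):
        segs = [CopySegment("sim1", 0, 100_000, 2, 1), CopySegment("sim1", 100_000, 200_000, 1, 0)]
        assert associate_copy_number(_locus(10_000, "tel_right"), segs) == "neutral_no_SV"

    def test_uncovered_junction_unknown(self):
        segs = [CopySegment("other", 0, 20_000, 2, 1)]
        assert associate_copy_number(_locus(10_000, "tel_right"), segs) == "unknown"


class TestHotspots:
    def test_six_samples_over_one_megabase_form_one_hotspot(self):
        # mirrors a ~1.06 Mb recurrent cluster: junctions every 212 kb
        cohort = {
            f"s{i}": [_locus(230_370_000 + i * 212_000, "tel_right")] for i in range(6)
        }
        (hs,) = call_hotspots(cohort)
        assert hs["n_samples"] == 6
        assert hs["end"] - hs["start"] == 5 * 212_000 + 1

    def test_two_samples_below_recurrence_threshold(self):
        cohort = {"s1": [_locus(1_000_000, "tel_right")], "s2": [_locus(1_100_000, "tel_left")]}
        assert call_hotspots(cohort) == []

    def test_distant_junctions_stay_separate(self):
        cohort = {
            f"s{i}": [_locus(1_000_000, "tel_right"), _locus(3_000_000, "tel_right")]
            for i in range(3)
        }
        hotspots = call_hotspots(cohort)
        assert len(hotspots) == 2
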