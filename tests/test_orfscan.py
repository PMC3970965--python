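import numpy as np
import pytest

from dicistro import orfscan
from dicistro.codons import STOP_CODONS
from dicistro.seqio import GenomeRecord, Region


def _random_record(rng, length):
    return GenomeRecord("rnd", "".join("ACGT"[i] for i in rng.integers(4, size=length)))


class TestStopMap:
    def test_single_stop_codon(self):
        stops = orfscan.stop_map(GenomeRecord("r", "TAA"))
        assert stops == {0: [1], 1: [], 2: []}

    def test_phase_is_respected(self):
        stops = orfscan.stop_map(GenomeRecord("r", "ATAAA"))
        assert stops[1] == [2] and stops[0] == [] and stops[2] == []

    def test_matches_naive_scan_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            rec = _random_record(rng, int(rng.integers(100, 3000)))
            stops = orfscan.stop_map(rec)
            for frame in range(3):
                naive = [
                    pos
                    for pos in range(frame + 1, rec.length - 1)
                    if (pos - 1) % 3 == frame
                    and rec.seq[pos - 1 : pos + 2] in STOP_CODONS
                ]
                assert stops[frame] == naive


class TestFindOrfs:
    def test_stop_free_frame_is_one_open_orf(self):
        rec = GenomeRecord("r", "ATGAAACCCGGG")
        orfs = [f for f in orfscan.find_orfs(rec, min_len=1) if f.frame == 0]
        assert len(orfs) == 1
        assert orfs[0].region.as_tuple() == (1, 12)
        assert orfs[0].annotation == "open"

    def test_minimal_aug_to_stop_orf(self):
        rec = GenomeRecord("r", "ATGTAA")
        orfs = orfscan.find_orfs(rec, mode="aug_to_stop", min_len=1)
        (orf,) = [f for f in orfs if f.frame == 0]
        assert orf.region.as_tuple() == (1, 6)  # one codon plus terminal stop

    def test_orfs_are_internally_stop_free(self):
        rng = np.random.default_rng(1)
        rec = _random_record(rng, 2000)
        for orf in orfscan.find_orfs(rec, min_len=1):
            seq = rec.seq[orf.region.start - 1 : orf.region.end]
            codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
            internal = codons[:-1] if codons[-1] in STOP_CODONS else codons
            assert not any(c in STOP_CODONS for c in internal)

    def test_orfs_and_stops_partition_each_frame(self):
        rng = np.random.default_rng(2)
        rec = _random_record(rng, 1500)
        stops = orfscan.stop_map(rec)
        orfs = orfscan.find_orfs(rec, min_len=1)
        for frame in range(3):
            codon_starts = set(range(frame + 1, rec.length - 1, 3))
            covered = set()
            for f in (f for f in orfs if f.frame == frame):
                covered |= set(range(f.region.start, f.region.end, 3))
            covered |= set(stops[frame])
            assert covered == codon_starts

    def test_recovers_planted_orf1(self, toy):
        record, truth = toy
        orfs = orfscan.find_orfs(record, mode="aug_to_stop", min_len=50)
        matches = [
            f for f in orfs if f.region.as_tuple() == tuple(truth.orf1_cds)
        ]
        assert len(matches) == 1
        assert matches[0].frame == truth.orf1_frame


class TestFindSlippery:
    def test_worked_cassette_example(self):
        # the 13-nt ORF1/ORF2 overlap with ORF1 codons starting at position 2
        rec = GenomeRecord("cassette", "UGAUUUAAACUGA")
        hits = orfscan.find_slippery(rec, orf_frame=1)
        (hit,) = hits
        assert hit.region.as_tuple() == (4, 10)
        assert rec.seq[3:10] == "TTTAAAC"
        assert hit.phase_ok is True
        assert hit.annotation == "U_GAU_UUA_AAC_UGA"

    def test_homopolymer_without_aaa_ttt_yyy_is_rejected(self):
        assert orfscan.find_slippery(GenomeRecord("r", "GGGGGGG"), 0) == []

    def test_z_position_g_is_rejected(self):
        assert orfscan.find_slippery(GenomeRecord("r", "TTTAAAG"), 0) == []

    def test_invariant_under_u_rendering(self):
        dna = GenomeRecord("d", "CCTGATTTAAACTGACC")
        rna = GenomeRecord("r", dna.seq.replace("T", "U"))
        for f in range(3):
            assert orfscan.find_slippery(dna, f) == orfscan.find_slippery(rna, f)

    def test_matches_exhaustive_heptamer_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            rec = _random_record(rng, int(rng.integers(200, 2000)))
            hits = {h.region.start for h in orfscan.find_slippery(rec, 0)}
            oracle = set()
            for pos in range(1, rec.length - 5):
                h = rec.seq[pos - 1 : pos + 6]
                if (
                    h[0] == h[1] == h[2]
                    and h[3] == h[4] == h[5]
                    and h[3:6] in ("AAA", "TTT")
                    and h[6] != "G"
                ):
                    oracle.add(pos)
            assert hits == oracle

    def test_recovers_planted_site_in_orf1(self, toy):
        record, truth = toy
        in_orf1 = [
            h
            for h in orfscan.find_slippery(record, truth.orf1_frame)
            if h.phase_ok and truth.orf1_cds[0] <= h.region.start <= truth.orf1_cds[1]
        ]
        (hit,) = in_orf1
        assert hit.region.start == truth.slippery_pos
        assert hit.annotation == truth.cassette_rendering


class TestOrfOverlap:
    def test_disjoint_orfs_have_empty_overlap(self):
        rec = GenomeRecord("r", "A" * 30)
        a = orfscan.FrameFeature("orf", Region(1, 9), frame=0)
        b = orfscan.FrameFeature("orf", Region(20, 28), frame=1)
        ov = orfscan.orf_overlap(a, b, rec)
        assert ov.region is None

    def test_same_frame_errors(self):
        rec = GenomeRecord("r", "A" * 30)
        a = orfscan.FrameFeature("orf", Region(1, 9), frame=0)
        b = orfscan.FrameFeature("orf", Region(4, 12), frame=0)
        with pytest.raises(ValueError, match="same frame"):
            orfscan.orf_overlap(a, b, rec)

    def test_symmetric_up_to_phasing(self, toy):
        record, truth = toy
        orf1 = orfscan.FrameFeature(
            "orf", Region(*truth.orf1_cds), frame=truth.orf1_frame
        )
        orf2 = orfscan.FrameFeature(
            "orf", Region(*truth.orf2_extended), frame=truth.orf2_frame
        )
        ov_ab = orfscan.orf_overlap(orf1, orf2, record)
        ov_ba = orfscan.orf_overlap(orf2, orf1, record)
        assert ov_ab.region == ov_ba.region
        assert ov_ab.offset == -ov_ba.offset

    def test_extended_orf2_overlap_is_the_13nt_cassette(self, toy):
        record, truth = toy
        orf1 = orfscan.FrameFeature(
            "orf", Region(*truth.orf1_cds), frame=truth.orf1_frame
        )
        orf2 = orfscan.FrameFeature(
            "orf", Region(*truth.orf2_extended), frame=truth.orf2_frame
        )
        orf2_ext = orfscan.extend_orf_upstream(record, orf2)
        ov = orfscan.orf_overlap(orf1, orf2_ext, record)
        assert ov.region.as_tuple() == tuple(truth.cassette)
        assert ov.region.length == 13
        assert ov.offset == -1
        assert ov.annotation == "U_GAU_UUA_AAC_UGA"


class TestStartContext:
    @pytest.mark.parametrize(
        "seq,pos,minus3,plus4,call",
        [
            ("GGGATGG", 4, "G", "G", "strong"),  # G at -3 and G at +4
            ("AAAATGA", 4, "A", "A", "strong"),  # A at -3 alone suffices
            ("CCCATGA", 4, "C", "A", "weak"),  # C at -3, A at +4
        ],
    )
    def test_printed_context_cases(self, seq, pos, minus3, plus4, call):
        ctx = orfscan.start_context(GenomeRecord("r", seq), pos)
        assert (ctx.minus3, ctx.plus4, ctx.call) == (minus3, plus4, call)

    def test_edge_aug_is_flagged_not_errored(self):
        ctx = orfscan.start_context(GenomeRecord("r", "ATGAAA"), 1)
        assert ctx.minus3 is None and ctx.call is None

    def test_non_aug_position_errors(self):
        with pytest.raises(ValueError, match="no AUG"):
            orfscan.start_context(GenomeRecord("r", "GGGAAA"), 1)


class TestSgrnaAugSurvey:
    def test_survey_matches_planted_positions(self, toy):
        record, truth = toy
        survey = orfscan.sgrna_aug_survey(
            record, truth.sg_start, n=3, ref_frame=truth.orf1_frame
        )
        assert [c.position.start for c, _ in survey] == list(truth.first_augs_after_sg)

    def test_aug_on_the_start_itself_is_item_one(self):
        rec = GenomeRecord("r", "CCCATGAAAATGAAA")
        survey = orfscan.sgrna_aug_survey(rec, 4, n=2)
        assert survey[0][0].position.start == 4

    def test_returns_fewer_when_fewer_exist(self):
        rec = GenomeRecord("r", "CCCATGAAA")
        survey = orfscan.sgrna_aug_survey(rec, 1, n=3)
        assert len(survey) == 1

    def test_frame_labels_relative_to_reference_orf(self):
        rec = GenomeRecord("r", "ATGCATGCCATGCC")
        survey = orfscan.sgrna_aug_survey(rec, 1, n=3, ref_frame=0)
        assert [label for _, label in survey] == ["ORF", "+1", "ORF"]
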