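import pytest

from dicistro import orfscan, products
from dicistro.products import CleavageScheme, WATER_AVG
from dicistro.seqio import GenomeRecord, Region


class TestTranslate:
    def test_simple_translation(self):
        rec = GenomeRecord("r", "ATGAAA")
        assert products.translate(rec, Region(1, 6)) == "MK"

    def test_terminal_stop_dropped(self):
        rec = GenomeRecord("r", "ATGTAA")
        assert products.translate(rec, Region(1, 6)) == "M"

    def test_internal_stop_errors(self):
        rec = GenomeRecord("r", "ATGTAAAAA")
        with pytest.raises(ValueError, match="internal stop"):
            products.translate(rec, Region(1, 9))

    def test_length_not_divisible_by_three_errors(self):
        rec = GenomeRecord("r", "ATGAA")
        with pytest.raises(ValueError, match="divisible"):
            products.translate(rec, Region(1, 5))


class TestAverageMass:
    def test_glycine(self):
        assert products.average_mass("G") == pytest.approx(75.07, abs=0.01)

    def test_empty_peptide_is_water(self):
        assert products.average_mass("") == pytest.approx(18.02, abs=0.01)

    def test_nonstandard_residue_errors(self):
        with pytest.raises(ValueError, match="nonstandard"):
            products.average_mass("MKX")

    def test_additive_over_concatenation_minus_water(self):
        a, b = "MKLV", "GGSTY"
        assert products.average_mass(a + b) == pytest.approx(
            products.average_mass(a) + products.average_mass(b) - WATER_AVG
        )


class TestCleave:
    def test_no_sites_returns_precursor(self):
        rec = GenomeRecord("r", "ATGAAACGT")
        orf = orfscan.FrameFeature("orf", Region(1, 9, frame_anchor=1), frame=0)
        prod = products.orf_product(rec, orf)
        (frag,) = products.cleave(prod, CleavageScheme(()))
        assert frag.sequence == prod.sequence
        assert frag.mass_da == pytest.approx(prod.mass_da)

    def test_one_cut_adds_exactly_one_water(self):
        rec = GenomeRecord("r", "ATGAAACGT")  # MKR
        orf = orfscan.FrameFeature("orf", Region(1, 9, frame_anchor=1), frame=0)
        prod = products.orf_product(rec, orf)
        frags = products.cleave(prod, [1])
        assert [f.sequence for f in frags] == ["M", "KR"]
        total = sum(f.mass_da for f in frags)
        assert total == pytest.approx(prod.mass_da + WATER_AVG, abs=1e-6)

    def test_mass_additivity_exact_for_many_cuts(self, toy):
        record, truth = toy
        orf1 = orfscan.FrameFeature(
            "orf", Region(*truth.orf1_cds, frame_anchor=truth.orf1_cds[0]),
            frame=truth.orf1_frame,
        )
        prod = products.orf_product(record, orf1, start=truth.orf1_start)
        sites = [10, 50, 100, 150]
        frags = products.cleave(prod, sites)
        assert "".join(f.sequence for f in frags) == prod.sequence
        assert sum(f.mass_da for f in frags) == pytest.approx(
            prod.mass_da + len(sites) * WATER_AVG, abs=0.01
        )

    def test_fragment_segments_map_back_to_genome(self, toy):
        record, truth = toy
        orf1 = orfscan.FrameFeature(
            "orf", Region(*truth.orf1_cds), frame=truth.orf1_frame
        )
        slips = [
            s
            for s in orfscan.find_slippery(record, truth.orf1_frame)
            if s.phase_ok and s.region.start == truth.slippery_pos
        ]
        tf = products.transframe_product(record, orf1, slips[0], start=truth.orf1_start)
        frags = products.cleave(tf, [tf.length_aa // 2])
        for frag in frags:
            retranslated = "".join(
                products.translate(record, r, frame=fr) for r, fr in frag.segments
            )
            assert retranslated == frag.sequence

    def test_site_out_of_range_errors(self):
        rec = GenomeRecord("r", "ATGAAACGT")
        orf = orfscan.FrameFeature("orf", Region(1, 9, frame_anchor=1), frame=0)
        prod = products.orf_product(rec, orf)
        with pytest.raises(ValueError, match="site"):
            products.cleave(prod, [3])


class TestTransframeProduct:
    def test_equals_generator_peptide(self, toy):
        record, truth = toy
        orf1 = orfscan.FrameFeature(
            "orf", Region(*truth.orf1_cds), frame=truth.orf1_frame
        )
        (slip,) = [
            s
            for s in orfscan.find_slippery(record, truth.orf1_frame)
            if s.phase_ok and s.region.start == truth.slippery_pos
        ]
        tf = products.transframe_product(record, orf1, slip, start=truth.orf1_start)
        assert tf.sequence == truth.transframe_peptide

    def test_sequence_is_concatenation_of_segment_translations(self, toy):
        record, truth = toy
        orf1 = orfscan.FrameFeature(
            "orf", Region(*truth.orf1_cds), frame=truth.orf1_frame
        )
        (slip,) = [
            s
            for s in orfscan.find_slippery(record, truth.orf1_frame)
            if s.phase_ok and s.region.start == truth.slippery_pos
        ]
        tf = products.transframe_product(record, orf1, slip, start=truth.orf1_start)
        assert tf.sequence == "".join(
            products.translate(record, r, frame=fr) for r, fr in tf.segments
        )

    def test_removing_slippery_reproduces_nonframeshift_product(self, toy):
        record, truth = toy
        orf1 = orfscan.FrameFeature(
            "orf", Region(*truth.orf1_cds), frame=truth.orf1_frame
        )
        nf = products.orf_product(record, orf1, start=truth.orf1_start)
        assert nf.sequence == truth.nonframeshift_peptide

    def test_minimal_extension_when_stop_is_immediate(self):
        # 0-frame codons ATG GAT TTA AAC ... with heptamer TTTAAAC at 6;
        # the -1 frame reads AAA CGG TAA, stopping after two codons
        rec = GenomeRecord("r", "ATGGATTTAAACGGTAAA")
        orf = orfscan.FrameFeature("orf", Region(1, 18, frame_anchor=1), frame=0)
        (slip,) = [h for h in orfscan.find_slippery(rec, 0) if h.phase_ok]
        assert slip.region.start == 6
        tf = products.transframe_product(rec, orf, slip)
        seg2 = tf.segments[1][0]
        assert (seg2.length // 3) <= 2
        assert tf.sequence == "MDLKR"

    def test_out_of_phase_slippery_rejected(self):
        rec = GenomeRecord("r", "ATGGATTTAAACGGTAAA")
        orf = orfscan.FrameFeature("orf", Region(1, 18, frame_anchor=1), frame=0)
        bad = orfscan.FrameFeature(
            "slippery", Region(6, 12), frame=0, phase_ok=False
        )
        with pytest.raises(ValueError, match="phase"):
            products.transframe_product(rec, orf, bad)


class TestProductCatalog:
    def test_no_slippery_site_gives_only_nonframeshift(self):
        rec = GenomeRecord("r", "CCCATGAAACGTGGCTAACCC")
        orfs = orfscan.find_orfs(rec, min_len=2)
        catalog = products.product_catalog(rec, orfs)
        assert [p.name for p in catalog] == ["nonframeshift"]

    def test_catalog_masses_conserved_under_cleavage(self, toy):
        record, truth = toy
        orfs = orfscan.find_orfs(record, min_len=50)
        catalog = products.product_catalog(
            record, orfs, sg_start=None, cleavage=None
        )
        names = [p.name for p in catalog]
        assert names == ["nonframeshift", "transframe"]
        tf = catalog[1]
        cut = tf.length_aa // 2
        catalog2 = products.product_catalog(
            record, orfs, sg_start=None, cleavage=[cut]
        )
        frags = catalog2[2:]
        assert sum(f.mass_da for f in frags) == pytest.approx(
            tf.mass_da + WATER_AVG, abs=0.01
        )
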