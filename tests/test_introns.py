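"""Intron-length extraction, the variance screen, profile grouping."""

import pytest
from hypothesis import given, settings, strategies as st

from plastidpoly import introns as intr
from plastidpoly import quadripartite as quad
from plastidpoly import synth
from plastidpoly.records import FeatureClass, GeneFeature, PlastomeRecord, revcomp


def _cis_gene(spans, strand="+"):
    return GeneFeature("g", FeatureClass.PROTEIN_CODING, strand, spans)


class TestIntronLengths:
    def test_simple_gap_arithmetic(self):
        rec = PlastomeRecord("t", "A" * 100)
        feat = _cis_gene([(0, 10), (25, 40)])
        assert intr.intron_lengths(rec, feat) == [15]

    def test_minus_strand_gap(self):
        rec = PlastomeRecord("t", "A" * 100)
        feat = _cis_gene([(60, 80), (10, 30)], strand="-")
        assert intr.intron_lengths(rec, feat) == [30]

    def test_single_exon_rejected(self):
        rec = PlastomeRecord("t", "A" * 100)
        with pytest.raises(ValueError, match="no introns"):
            intr.intron_lengths(rec, _cis_gene([(0, 10)]))

    def test_overlapping_exons_rejected_with_name(self):
        rec = PlastomeRecord("t", "A" * 100)
        feat = _cis_gene([(0, 30), (20, 50)])
        with pytest.raises(ValueError, match="g"):
            intr.intron_lengths(rec, feat)

    def test_trans_junction_skipped_cis_reported(self, base_record):
        (rps12,) = base_record.genes("rps12")
        assert rps12.is_trans_spliced
        assert intr.intron_lengths(base_record, rps12) == [540]

    def test_planted_lengths_recovered(self, base_record):
        expected = {
            "rpl22": [111],
            "rps16": [880],
            "petB": [788],
            "clpP": [830, 624],
            "ndhA": [1132],
            "ndhB": [669],
            "trnL-UAA": [516],
        }
        for gene, lengths in expected.items():
            feat = base_record.genes(gene)[0]
            assert intr.intron_lengths(base_record, feat) == lengths

    def test_footprint_identity_exons_plus_introns(self, base_record):
        n = len(base_record.sequence)
        for f in base_record.features:
            if f.is_trans_spliced or len(f.exon_spans) < 2:
                continue
            exon_bp = sum(e - s for s, e in f.exon_spans)
            intron_bp = sum(intr.intron_lengths(base_record, f))
            lo = min(s for s, _ in f.exon_spans)
            hi = max(e for _, e in f.exon_spans)
            assert exon_bp + intron_bp == hi - lo


class TestBuildMatrix:
    def test_two_identical_accessions_all_variance_zero(self, base_and_manifest):
        base, manifest = base_and_manifest
        twin = synth.derive_accession(base, manifest, [], "TWIN", seed=1)
        assert twin.sequence == base.sequence
        parts = [quad.partition(r, 1000) for r in (base, twin)]
        matrix = intr.build_matrix([base, twin], parts)
        assert all(r.variance_bp == 0 for r in matrix.records)

    def test_panel_variances_match_planted_indels(
        self, panel_records, panel_partitions
    ):
        matrix = intr.build_matrix(panel_records, panel_partitions)
        assert matrix.row("rpl22").variance_bp == 20
        assert matrix.row("petB").variance_bp == 10
        assert matrix.row("clpP", 2).variance_bp == 10
        assert matrix.row("ndhA").variance_bp == 24
        assert matrix.row("rps16").variance_bp == 25
        # untouched rows stay flat
        for gene, idx in [("ndhB", 1), ("rps12", 1), ("trnL-UAA", 1), ("clpP", 1)]:
            assert matrix.row(gene, idx).variance_bp == 0

    def test_region_labels(self, panel_records, panel_partitions):
        matrix = intr.build_matrix(panel_records, panel_partitions)
        assert matrix.row("ndhB").region == "IR"
        assert matrix.row("ndhA").region == "SSC"
        assert matrix.row("rpl22").region == "LSC"

    def test_gene_missing_in_one_accession_excluded(self, base_and_manifest):
        base, manifest = base_and_manifest
        twin = synth.derive_accession(base, manifest, [], "TWIN2", seed=2)
        twin.features = [f for f in twin.features if f.gene_name != "rpl22"]
        parts = [quad.partition(r, 1000) for r in (base, twin)]
        matrix = intr.build_matrix([base, twin], parts)
        assert all(r.gene_name != "rpl22" for r in matrix.records)
        assert "rpl22 intron 1" in matrix.excluded

    def test_ir_copy_disagreement_flagged(self, base_and_manifest):
        base, _ = base_and_manifest
        broken = PlastomeRecord(
            "broken",
            base.sequence,
            features=[f.copy() for f in base.features],
        )
        # shrink one ndhB copy's intron by moving its second exon
        copies = broken.genes("ndhB")
        f = copies[0]
        spans = sorted(f.exon_spans)
        s2, e2 = spans[1]
        f.exon_spans = [spans[0], (s2 - 5, e2)]
        part = quad.partition(broken, 1000)
        with pytest.raises(intr.IRCopyMismatchError):
            intr.build_matrix([broken, broken], [part, part])


class TestIrCoEditing:
    def test_co_edited_ir_intron_keeps_ir_exact_and_recovers_delta(
        self, base_and_manifest
    ):
        base, manifest = base_and_manifest
        edited = synth.derive_accession(
            base, manifest, [synth.IntronEdit("ndhB", -15)], "IRDEL", seed=5
        )
        part_e = quad.partition(edited, 1000)
        ira = part_e.ira.extract(edited.sequence)
        irb = part_e.irb.extract(edited.sequence)
        assert irb == revcomp(ira)  # repeat still exact after co-editing
        parts = [quad.partition(base, 1000), part_e]
        matrix = intr.build_matrix([base, edited], parts)
        assert matrix.row("ndhB").variance_bp == 15


class TestScreenAndGrouping:
    def test_planted_30bp_deletion_ranks_first(self, base_and_manifest):
        base, manifest = base_and_manifest
        edited = synth.derive_accession(
            base, manifest, [synth.IntronEdit("rps16", -30)], "DEL30", seed=6
        )
        parts = [quad.partition(r, 1000) for r in (base, edited)]
        matrix = intr.build_matrix([base, edited], parts)
        poly = intr.polymorphic_genes(matrix, 10)
        assert [(r.gene_name, r.variance_bp) for r in poly] == [("rps16", 30)]

    def test_threshold_zero_returns_all_varying_rows(
        self, panel_records, panel_partitions
    ):
        matrix = intr.build_matrix(panel_records, panel_partitions)
        poly = intr.polymorphic_genes(matrix, 0)
        assert len(poly) == len(matrix.records)

    def test_panel_groups_by_profile(self, panel_records, panel_partitions):
        matrix = intr.build_matrix(panel_records, panel_partitions)
        groups = intr.group_accessions_by_intron_profile(matrix)
        assert sorted(map(sorted, groups)) == [
            ["A1", "A2", "A3"], ["B1", "B2", "B3"]
        ]

    def test_single_accession_is_singleton_group(self, base_record):
        part = quad.partition(base_record, 1000)
        matrix = intr.build_matrix([base_record], [part])
        groups = intr.group_accessions_by_intron_profile(matrix)
        assert groups == [[base_record.accession_id]]

    @settings(max_examples=20, derandomize=True)
    @given(st.permutations(range(6)))
    def test_variance_invariant_under_accession_order(
        self, panel_records, panel_partitions, perm
    ):
        records = [panel_records[i] for i in perm]
        parts = [panel_partitions[i] for i in perm]
        matrix = intr.build_matrix(records, parts)
        assert matrix.row("rpl22").variance_bp == 20
        assert matrix.row("ndhA").variance_bp == 24

    def test_variance_invariant_under_rotation(self, panel_records):
        rotated = [r.rotated(1234 + 7 * i) for i, r in enumerate(panel_records)]
        parts = [quad.partition(r, 1000) for r in rotated]
        matrix = intr.build_matrix(rotated, parts)
        assert matrix.row("rpl22").variance_bp == 20
        assert matrix.row("rps16").variance_bp == 25
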