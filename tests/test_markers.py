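"""Primer binding, in-silico amplification, band grouping, primer design."""

import numpy as np
import pytest

from plastidpoly import introns as intr
from plastidpoly import markers as mk
from plastidpoly import quadripartite as quad
from plastidpoly import synth
from plastidpoly.records import FeatureClass, PlastomeRecord, revcomp


@pytest.fixture(scope="module")
def fixture_5kb():
    rng = np.random.default_rng(10)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    return PlastomeRecord("FIX", seq)


class TestFindBindingSites:
    def test_unique_planted_20mer_found_on_plus(self, fixture_5kb):
        primer = fixture_5kb.sequence[1000:1020]
        sites = mk.find_binding_sites(fixture_5kb.sequence, primer)
        plus = [s for s in sites if s.strand == "+"]
        assert any(s.start == 1000 for s in plus)

    def test_revcomp_primer_found_on_minus(self, fixture_5kb):
        primer = revcomp(fixture_5kb.sequence[2000:2020])
        sites = mk.find_binding_sites(fixture_5kb.sequence, primer)
        assert any(s.start == 2000 and s.strand == "-" for s in sites)

    def test_circular_site_across_origin(self, fixture_5kb):
        seq = fixture_5kb.sequence
        primer = seq[-10:] + seq[:10]
        sites = mk.find_binding_sites(seq, primer, circular=True)
        assert any(s.start == len(seq) - 10 and s.strand == "+" for s in sites)
        assert mk.find_binding_sites(seq, primer, circular=False) == []

    @pytest.mark.parametrize("max_mismatch", [0, 1, 2])
    def test_equals_bruteforce_scan(self, fixture_5kb, max_mismatch):
        seq = fixture_5kb.sequence
        rng = np.random.default_rng(11)
        for _ in range(4):
            start = int(rng.integers(0, 4900))
            primer = list(seq[start : start + 20])
            n_mm = int(rng.integers(0, max_mismatch + 1))
            for _ in range(n_mm):
                k = int(rng.integers(0, 15))  # keep the 3' end intact
                primer[k] = "ACGT"[(("ACGT".index(primer[k])) + 1) % 4]
            primer = "".join(primer)
            fast = mk.find_binding_sites(seq, primer, max_mismatch)
            brute = mk.find_binding_sites_bruteforce(seq, primer, max_mismatch)
            assert fast == brute

    def test_three_prime_mismatch_never_anneals(self, fixture_5kb):
        seq = fixture_5kb.sequence
        primer = list(seq[500:520])
        primer[-1] = "ACGT"[("ACGT".index(primer[-1]) + 1) % 4]
        primer = "".join(primer)
        sites = mk.find_binding_sites(seq, primer, max_mismatch=2)
        assert all(s.start != 500 for s in sites)
        # an internal mismatch with the same budget still anneals
        primer2 = list(seq[500:520])
        primer2[5] = "ACGT"[("ACGT".index(primer2[5]) + 1) % 4]
        sites2 = mk.find_binding_sites(seq, "".join(primer2), max_mismatch=1)
        assert any(s.start == 500 and s.strand == "+" for s in sites2)

    def test_short_primer_rejected(self, fixture_5kb):
        with pytest.raises(ValueError):
            mk.find_binding_sites(fixture_5kb.sequence, "ACGTACGT")


class TestPredictAmplicon:
    def test_product_size_is_5prime_to_5prime(self, fixture_5kb):
        seq = fixture_5kb.sequence
        fwd = seq[100:120]
        rev = revcomp(seq[480:500])
        pair = mk.PrimerPair("toy", fwd, rev)
        pred = mk.predict_amplicon(fixture_5kb, pair)
        assert pred.product_size_bp == 400  # 100..500 inclusive of footprints
        assert not pred.ambiguous

    def test_product_across_origin(self, fixture_5kb):
        rotated = fixture_5kb.rotated(300)  # amplicon now spans the origin
        seq = fixture_5kb.sequence
        pair = mk.PrimerPair("toy", seq[100:120], revcomp(seq[480:500]))
        pred = mk.predict_amplicon(rotated, pair)
        assert pred.product_size_bp == 400

    def test_no_sites_gives_none(self, fixture_5kb):
        pair = mk.PrimerPair("toy", "A" * 20, "C" * 20)
        pred = mk.predict_amplicon(fixture_5kb, pair)
        assert pred.product_size_bp is None

    def test_planted_deletion_shortens_product_exactly(self, base_and_manifest):
        base, manifest = base_and_manifest
        edited = synth.derive_accession(
            base, manifest, [synth.IntronEdit("rps16", -30)], "PCRDEL", seed=8
        )
        pair = mk.design_primer_pair(
            base, "rps16", mk.DesignConstraints(product_target=400)
        )
        size_base = mk.predict_amplicon(base, pair).product_size_bp
        size_edit = mk.predict_amplicon(edited, pair).product_size_bp
        assert size_base - size_edit == 30


class TestBandGroups:
    def test_binning_at_gel_resolution(self):
        preds = [
            mk.AmpliconPrediction("x", "m", 400),
            mk.AmpliconPrediction("y", "m", 410),
            mk.AmpliconPrediction("z", "m", 430),
        ]
        table = mk.band_groups(preds, size_resolution_bp=15)
        assert sorted(map(sorted, table.groups["m"])) == [["x", "y"], ["z"]]

    def test_identical_sizes_one_class(self):
        preds = [mk.AmpliconPrediction(a, "m", 400) for a in "abc"]
        table = mk.band_groups(preds, 10)
        assert table.joint_groups == [["a", "b", "c"]]

    def test_null_band_is_its_own_class(self):
        preds = [
            mk.AmpliconPrediction("a", "m", 400),
            mk.AmpliconPrediction("b", "m", None),
        ]
        table = mk.band_groups(preds, 10)
        assert sorted(map(sorted, table.groups["m"])) == [["a"], ["b"]]

    def test_panel_markers_split_designed_groups(
        self, panel_records, panel_partitions
    ):
        matrix = intr.build_matrix(panel_records, panel_partitions)
        pair = mk.design_primer_pair(
            panel_records[0], "rps16", mk.DesignConstraints(product_target=400)
        )
        preds = [mk.predict_amplicon(r, pair) for r in panel_records]
        table = mk.band_groups(preds, size_resolution_bp=10)
        assert sorted(map(sorted, table.joint_groups)) == [
            ["A1", "A2", "A3"], ["B1", "B2", "B3"]
        ]


class TestDesign:
    def test_matches_exhaustive_oracle(self):
        # one synthetic gene: 100 bp exons around a 250 bp intron
        rng = np.random.default_rng(12)
        lead = "".join(rng.choice(list("ACGT"), size=200))
        exon1 = "".join(rng.choice(list("ACGT"), p=[.28,.22,.22,.28], size=100))
        intron = "".join(rng.choice(list("ACGT"), size=250))
        exon2 = "".join(rng.choice(list("ACGT"), p=[.28,.22,.22,.28], size=100))
        tail = "".join(rng.choice(list("ACGT"), size=200))
        seq = lead + exon1 + intron + exon2 + tail
        rec = PlastomeRecord("D", seq)
        rec.features.append(
            __import__("plastidpoly.records", fromlist=["GeneFeature"]).GeneFeature(
                "toyg", FeatureClass.PROTEIN_CODING, "+",
                [(200, 300), (550, 650)],
            )
        )
        cons = mk.DesignConstraints(product_target=400)
        got = mk.design_primer_pair(rec, "toyg", cons)

        # oracle: enumerate every window of both exons independently
        def windows(s):
            out = []
            for ln in range(cons.primer_len[0], cons.primer_len[1] + 1):
                for off in range(0, len(s) - ln + 1):
                    p = s[off : off + ln]
                    gc = 100 * (p.count("G") + p.count("C")) / ln
                    tm = mk.primer_tm(p)
                    if cons.gc_range[0] <= gc <= cons.gc_range[1] and \
                       cons.tm_range[0] <= tm <= cons.tm_range[1]:
                        out.append((off, p))
            return out

        best = None
        for foff, fp in windows(exon1):
            for roff, rp in windows(revcomp(exon2)):
                product = (100 - foff) + 250 + (100 - roff)
                key = (abs(product - 400), foff, roff)
                if best is None or key < best[0]:
                    best = (key, fp, rp, product)
        assert (got.forward, got.reverse) == (best[1], best[2])
        # realized product agrees with the in-silico amplification
        pred = mk.predict_amplicon(rec, got)
        assert pred.product_size_bp == best[3]

    def test_intronless_gene_rejected(self, base_record):
        with pytest.raises(mk.PrimerDesignError, match="no intron"):
            mk.design_primer_pair(base_record, "psbA")

    def test_unknown_gene_rejected(self, base_record):
        with pytest.raises(mk.PrimerDesignError, match="no such gene"):
            mk.design_primer_pair(base_record, "nothere")

    def test_infeasible_constraints_reported(self, base_record):
        cons = mk.DesignConstraints(gc_range=(95.0, 100.0))
        with pytest.raises(mk.PrimerDesignError, match="GC"):
            mk.design_primer_pair(base_record, "rpl22", cons)

    def test_product_deltas_equal_intron_deltas_for_all_pairs(
        self, panel_records, panel_partitions
    ):
        matrix = intr.build_matrix(panel_records, panel_partitions)
        ref = panel_records[0]
        for row in intr.polymorphic_genes(matrix, 10):
            # pick a pair that anneals in every accession
            pair = None
            for cand in mk.design_primer_candidates(
                ref, row.gene_name,
                mk.DesignConstraints(product_target=400),
                intron_index=row.intron_index,
            ):
                preds = [mk.predict_amplicon(r, cand) for r in panel_records]
                if all(p.product_size_bp is not None for p in preds):
                    pair = cand
                    break
            assert pair is not None, row.gene_name
            sizes = {p.accession: p.product_size_bp for p in preds}
            for a in matrix.accessions:
                for b in matrix.accessions:
                    assert sizes[a] - sizes[b] == (
                        row.length_bp[a] - row.length_bp[b]
                    )


class TestPublishedPrimerTable:
    def test_pairs_satisfy_marker_invariants(self):
        names = [p.marker_name for p in mk.PUBLISHED_PRIMERS]
        assert names == ["rpl22", "petB", "clpP", "ndhA", "rps16"]
        for p in mk.PUBLISHED_PRIMERS:
            lo, hi = p.target_size_range
            assert lo <= hi
            assert 18 <= len(p.forward) <= 25
            assert 18 <= len(p.reverse) <= 25

    def test_bad_primer_rejected(self):
        with pytest.raises(ValueError, match="length"):
            mk.PrimerPair("x", "ACGT", "ACGTACGTACGTACGTACGT")
        with pytest.raises(ValueError, match="non-ACGT"):
            mk.PrimerPair("x", "ACGTACGTACGTNCGTACGT", "ACGTACGTACGTACGTACGT")
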