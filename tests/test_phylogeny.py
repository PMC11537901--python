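"""Concatenated matrices, model distances, NJ recovery, bootstrap support."""

import math
import random

import dendropy
import numpy as np
import pytest

from plastidpoly import phylogeny as ph
from plastidpoly import synth

from helpers import random_additive_tree


def matrix_from_rows(rows: dict[str, str]) -> ph.ConcatenatedMatrix:
    return ph.ConcatenatedMatrix(
        accessions=list(rows), genes=["toy"], rows=rows
    )


@pytest.fixture(scope="module")
def panel_cds_matrix(panel_records):
    return ph.build_matrix(panel_records, mode="cds")


@pytest.fixture(scope="module")
def panel_intron_matrix(panel_records):
    return ph.build_matrix(panel_records, mode="cds_plus_intron")


class TestDistances:
    def test_identical_rows_zero(self):
        m = matrix_from_rows({"a": "ACGT" * 25, "b": "ACGT" * 25})
        assert ph.distance(m, "p").get("a", "b") == 0.0

    def test_p_distance_arithmetic(self):
        row_a = "A" * 100
        row_b = "C" * 2 + "A" * 98
        m = matrix_from_rows({"a": row_a, "b": row_b})
        assert ph.distance(m, "p").get("a", "b") == pytest.approx(0.02)

    def test_jc69_closed_form(self):
        row_a = "A" * 100
        row_b = "C" * 2 + "A" * 98
        m = matrix_from_rows({"a": row_a, "b": row_b})
        expected = -0.75 * math.log(1 - 4 * 0.02 / 3)
        assert ph.distance(m, "jc69").get("a", "b") == pytest.approx(expected)

    def test_jc69_saturated_rejected(self):
        m = matrix_from_rows({"a": "A" * 100, "b": "C" * 80 + "A" * 20})
        with pytest.raises(ValueError, match="jc69"):
            ph.distance(m, "jc69")

    def test_k2p_closed_form(self):
        # 3 transitions (A<->G) and 1 transversion (A<->C) over 100 sites
        row_a = "A" * 100
        row_b = "G" * 3 + "C" + "A" * 96
        m = matrix_from_rows({"a": row_a, "b": row_b})
        P, Q = 0.03, 0.01
        expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
        assert ph.distance(m, "k2p").get("a", "b") == pytest.approx(expected)

    def test_gap_and_n_columns_excluded(self):
        m = matrix_from_rows({"a": "ACGT" + "A" * 6, "b": "-NGT" + "A" * 6})
        # only 8 comparable columns, all equal
        assert ph.distance(m, "p").get("a", "b") == 0.0

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        rows = {
            name: "".join(rng.choice(list("ACGT"), size=80))
            for name in "abcd"
        }
        d1 = ph.distance(matrix_from_rows(rows), "p")
        shuffled = {k: rows[k] for k in ["c", "a", "d", "b"]}
        d2 = ph.distance(matrix_from_rows(shuffled), "p")
        for x in "abcd":
            for y in "abcd":
                if x != y:
                    assert d1.get(x, y) == pytest.approx(d2.get(x, y))


class TestNeighborJoining:
    def test_three_taxa_additive_branch_lengths(self):
        taxa = ["a", "b", "c"]
        vals = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = ph.nj_tree(ph.DistanceMatrix(taxa, vals))
        lengths = {c.name: bl for c, bl in tree.root.children}
        assert lengths == {"a": 2.0, "b": 3.0, "c": 7.0}

    def test_four_taxon_known_tree_recovered(self):
        # hand-built additive matrix for ((a,b),(c,d)) with internal edge 3
        taxa = ["a", "b", "c", "d"]
        vals = np.array(
            [
                [0, 3, 9, 10],
                [3, 0, 10, 11],
                [9, 10, 0, 5],
                [10, 11, 5, 0],
            ],
            dtype=float,
        )
        tree = ph.nj_tree(ph.DistanceMatrix(taxa, vals))
        assert tree.has_bipartition({"a", "b"})
        assert tree.has_bipartition({"c", "d"})

    def test_recovers_random_additive_trees(self):
        rng = random.Random(11)
        for _ in range(12):
            n = rng.randint(5, 8)
            taxa, dist, true_bips = random_additive_tree(rng, n)
            vals = np.zeros((n, n))
            for i, x in enumerate(taxa):
                for j, y in enumerate(taxa):
                    if i != j:
                        vals[i, j] = dist[(x, y)]
            tree = ph.nj_tree(ph.DistanceMatrix(taxa, vals))
            assert tree.bipartitions() == true_bips

    def test_agrees_with_dendropy_nj_topology(self):
        rng = random.Random(12)
        taxa, dist, true_bips = random_additive_tree(rng, 7)
        n = len(taxa)
        vals = np.zeros((n, n))
        for i, x in enumerate(taxa):
            for j, y in enumerate(taxa):
                if i != j:
                    vals[i, j] = dist[(x, y)]
        mine = ph.nj_tree(ph.DistanceMatrix(taxa, vals))
        csv = "," + ",".join(taxa) + "\n"
        for i, x in enumerate(taxa):
            csv += x + "," + ",".join(str(vals[i, j]) for j in range(n)) + "\n"
        import io as _io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            _io.StringIO(csv), delimiter=","
        )
        dtree = pdm.nj_tree()
        dtree.encode_bipartitions()
        ref = dendropy.Tree.get(
            data=mine.newick(include_support=False),
            schema="newick",
            taxon_namespace=dtree.taxon_namespace,
        )
        ref.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(
            dtree, ref
        ) == 0

    def test_asymmetric_matrix_rejected(self):
        vals = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            ph.nj_tree(ph.DistanceMatrix(["a", "b", "c"], vals))


class TestConcatenatedMatrix:
    def test_identical_accessions_identical_rows(self, base_and_manifest):
        base, manifest = base_and_manifest
        twin = synth.derive_accession(base, manifest, [], "T2", seed=21)
        m = ph.build_matrix([base, twin], mode="cds")
        assert m.rows[base.accession_id] == m.rows["T2"]

    def test_single_substitution_changes_one_column(self, base_and_manifest):
        base, manifest = base_and_manifest
        edited = synth.derive_accession(
            base, manifest, [synth.SubstitutionEdit(1)], "SUB1", seed=22
        )
        m = ph.build_matrix([base, edited], mode="cds")
        diffs = [
            i
            for i, (x, y) in enumerate(
                zip(m.rows[base.accession_id], m.rows["SUB1"])
            )
            if x != y
        ]
        assert len(diffs) == 1

    def test_rps12_excluded_only_in_intron_mode(self, panel_records):
        cds = ph.build_matrix(panel_records[:2], mode="cds")
        with_introns = ph.build_matrix(panel_records[:2], mode="cds_plus_intron")
        assert "rps12" in cds.genes
        assert "rps12" not in with_introns.genes

    def test_rows_equal_length_and_gene_order_fixed(self, panel_intron_matrix):
        m = panel_intron_matrix
        widths = {len(r) for r in m.rows.values()}
        assert len(widths) == 1
        assert m.genes == sorted(m.genes, key=str.lower)

    def test_missing_gene_dropped_with_contract_kept(self, base_and_manifest):
        base, manifest = base_and_manifest
        twin = synth.derive_accession(base, manifest, [], "T3", seed=23)
        twin.features = [f for f in twin.features if f.gene_name != "matK"]
        m = ph.build_matrix([base, twin], mode="cds")
        assert "matK" not in m.genes


class TestBootstrap:
    def test_same_seed_reproducible(self, panel_cds_matrix):
        m = panel_cds_matrix
        t1 = ph.bootstrap(m, n_replicates=50, seed=9)
        t2 = ph.bootstrap(m, n_replicates=50, seed=9)
        assert t1.newick() == t2.newick()

    def test_designed_split_supported(self, panel_intron_matrix):
        m = panel_intron_matrix
        tree = ph.bootstrap(m, n_replicates=200, seed=4)
        assert tree.has_bipartition({"A1", "A2", "A3"})
        supports = {
            side: node.support for node, side in tree.internal_edges()
        }
        split = frozenset({"B1", "B2", "B3"})
        assert supports[split] >= 95.0

    def test_identical_rows_star_tree_low_support(self):
        rows = {name: "ACGT" * 50 for name in "abcde"}
        m = matrix_from_rows(rows)
        tree = ph.bootstrap(m, n_replicates=20, seed=1)
        for _, bl in tree.root.children:
            assert bl == 0.0

    def test_invalid_replicate_count(self, panel_records):
        m = ph.build_matrix(panel_records[:3], mode="cds")
        with pytest.raises(ValueError):
            ph.bootstrap(m, n_replicates=0, seed=1)


class TestWholeGenomeMode:
    def test_two_cluster_split_in_all_three_modes(
        self, panel_records, panel_cds_matrix, panel_intron_matrix
    ):
        from plastidpoly import quadripartite as quad

        split = {"A1", "A2", "A3"}
        for mode, m in (("cds", panel_cds_matrix),
                        ("cds_plus_intron", panel_intron_matrix)):
            assert ph.nj_tree(ph.distance(m, "p")).has_bipartition(split), mode
        rotated = [quad.canonicalize(r, 1000)[0] for r in panel_records]
        m = ph.whole_genome_matrix(rotated)
        assert ph.nj_tree(ph.distance(m, "p")).has_bipartition(split)
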