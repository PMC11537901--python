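"""Concatenated-CDS matrices, model distances, neighbor joining, bootstrap.

The maternal-lineage tree is reconstructed from the concatenation of the
protein-coding genes shared by every accession (IR duplicates collapsed to
one copy; the trans-spliced rps12 is excluded when introns are included).
Distance models: p-distance, Jukes-Cantor (jc69) and Kimura two-parameter
(k2p). Tree building is canonical neighbor joining with deterministic
tie-breaking; internal-edge support comes from column bootstrap.

Full likelihood tree inference is deliberately out of scope: the quantity
of interest here is cluster concordance (which accessions share a maternal
lineage), for which distance + NJ on near-identical plastomes is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .records import FeatureClass, PlastomeRecord, revcomp, span_extract
from .align import DEFAULT_SCORING, Scoring, gotoh, anchored_global_alignment


# ---------------------------------------------------------------------------
# concatenated matrices

@dataclass
class ConcatenatedMatrix:
    accessions: list[str]
    genes: list[str]
    rows: dict[str, str]  # accession -> concatenated (aligned) sequence
    gene_bounds: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))


def _gene_sequence(record: PlastomeRecord, name: str, mode: str) -> str | None:
    """Spliced CDS, or the unspliced footprint when introns are included.

    IR duplicates collapse to the first annotated copy.
    """
    feats = record.genes(name)
    if not feats:
        return None
    f = feats[0]
    n = len(record.sequence)
    if mode == "cds":
        from .records import spliced_sequence

        return spliced_sequence(record, f)
    # cds_plus_intron: contiguous genomic footprint in gene orientation
    spans = f.exon_spans
    if f.is_trans_spliced:
        return None  # multi-locus genes have no contiguous footprint
    lo = min(s for s, _ in spans)
    hi = max(e for _, e in spans)
    seq = span_extract((lo, hi), record.sequence)
    return revcomp(seq) if f.strand == "-" else seq


def shared_protein_coding_genes(
    records: list[PlastomeRecord], mode: str = "cds"
) -> list[str]:
    """Alphabetical protein-coding genes present in every accession.

    In cds_plus_intron mode trans-spliced genes (rps12) drop out because
    their footprint is not contiguous.
    """
    sets = []
    for rec in records:
        names = set()
        for f in rec.features:
            if f.feature_class is not FeatureClass.PROTEIN_CODING:
                continue
            if mode == "cds_plus_intron" and f.is_trans_spliced:
                continue
            names.add(f.gene_name.lower())
        sets.append(names)
    shared = set.intersection(*sets)
    # preserve annotated case from the first record
    case = {}
    for f in records[0].features:
        case.setdefault(f.gene_name.lower(), f.gene_name)
    return sorted((case.get(g, g) for g in shared), key=str.lower)


def _pair_align(a: str, b: str, scoring: Scoring) -> tuple[str, str]:
    """Global alignment, anchored for long near-identical pairs."""
    from .align import TooDivergentError, normalize_gaps

    if len(a) * len(b) > 250_000:
        try:
            return anchored_global_alignment(a, b, scoring)
        except TooDivergentError:
            if len(a) * len(b) > 9_000_000:
                raise
    return normalize_gaps(*gotoh(a, b, scoring), scoring)


def _star_align(seqs: dict[str, str], scoring: Scoring) -> dict[str, str]:
    """Star multiple alignment against the first accession's sequence.

    Equal-length inputs are used positionally (plastome coding sequences are
    column-compatible when unindeled); otherwise each row is aligned to the
    reference row and merged on reference coordinates.
    """
    names = list(seqs)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) == 1:
        return dict(seqs)
    ref_name = names[0]
    ref = seqs[ref_name]
    pairwise = {}
    for name in names[1:]:
        pairwise[name] = _pair_align(ref, seqs[name], scoring)
    # max insertion length after each ref position (index 0 = before ref)
    ins = [0] * (len(ref) + 1)
    for a, _ in pairwise.values():
        pos = 0
        run = 0
        for c in a:
            if c == "-":
                run += 1
            else:
                ins[pos] = max(ins[pos], run)
                run = 0
                pos += 1
        ins[len(ref)] = max(ins[len(ref)], run)
    def project(a_aln: str, b_aln: str) -> str:
        out = []
        pos = 0
        run: list[str] = []
        for ca, cb in zip(a_aln, b_aln):
            if ca == "-":
                run.append(cb)
            else:
                out.append("-" * (ins[pos] - len(run)) + "".join(run))
                out.append(cb)
                run = []
                pos += 1
        out.append("-" * (ins[len(ref)] - len(run)) + "".join(run))
        return "".join(out)

    aligned = {ref_name: project(ref, ref)}
    for name, (a, b) in pairwise.items():
        aligned[name] = project(a, b)
    return aligned


def build_matrix(
    records: list[PlastomeRecord],
    mode: str = "cds",
    scoring: Scoring = DEFAULT_SCORING,
) -> ConcatenatedMatrix:
    """Per-gene aligned, concatenated sequence matrix (fixed gene order).

    ``mode``: 'cds' joins spliced coding sequences; 'cds_plus_intron' joins
    unspliced gene footprints (rps12 excluded). Genes missing in any
    accession are excluded to keep the shared-by-all contract.
    """
    if mode not in ("cds", "cds_plus_intron"):
        raise ValueError(f"unknown mode: {mode}")
    genes = shared_protein_coding_genes(records, mode)
    accs = [r.accession_id for r in records]
    pieces: dict[str, list[str]] = {a: [] for a in accs}
    bounds: dict[str, tuple[int, int]] = {}
    offset = 0
    for gene in genes:
        per_acc = {}
        skip = False
        for rec in records:
            s = _gene_sequence(rec, gene, mode)
            if s is None:
                skip = True
                break
            per_acc[rec.accession_id] = s
        if skip:
            continue
        aligned = _star_align(per_acc, scoring)
        width = len(next(iter(aligned.values())))
        for a in accs:
            pieces[a].append(aligned[a])
        bounds[gene] = (offset, offset + width)
        offset += width
    rows = {a: "".join(pieces[a]) for a in accs}
    widths = {len(r) for r in rows.values()}
    assert len(widths) == 1, "concatenated rows differ in length"
    return ConcatenatedMatrix(accessions=accs, genes=list(bounds),
                              rows=rows, gene_bounds=bounds)


def whole_genome_matrix(
    records: list[PlastomeRecord], scoring: Scoring = DEFAULT_SCORING
) -> ConcatenatedMatrix:
    """Whole-plastome matrix: positional when lengths are within 0.5%,
    otherwise star-aligned on the first accession."""
    seqs = {r.accession_id: r.sequence for r in records}
    lens = [len(s) for s in seqs.values()]
    if (max(lens) - min(lens)) / max(lens) > 0.005:
        aligned = _star_align(seqs, scoring)
    else:
        if len(set(lens)) == 1:
            aligned = seqs
        else:
            aligned = _star_align(seqs, scoring)
    return ConcatenatedMatrix(
        accessions=list(seqs),
        genes=["whole_genome"],
        rows=aligned,
        gene_bounds={"whole_genome": (0, len(next(iter(aligned.values()))))},
    )


# ---------------------------------------------------------------------------
# distances

@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: "np.ndarray"  # symmetric, zero diagonal

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)


def _rows_to_array(matrix: ConcatenatedMatrix) -> "np.ndarray":
    return np.array(
        [
            np.frombuffer(matrix.rows[a].encode(), dtype=np.uint8)
            for a in matrix.accessions
        ]
    )


def _distance_from_array(
    taxa: list[str], arr: "np.ndarray", model: str
) -> DistanceMatrix:
    usable = (arr != ord("-")) & (arr != ord("N"))
    purine = (arr == ord("A")) | (arr == ord("G"))
    n = len(taxa)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m = usable[i] & usable[j]
            comparable = int(m.sum())
            if comparable == 0:
                raise ValueError(f"no comparable sites: {taxa[i]} vs {taxa[j]}")
            diff = m & (arr[i] != arr[j])
            ndiff = int(diff.sum())
            ts = int((diff & (purine[i] == purine[j])).sum())
            tv = ndiff - ts
            p = ndiff / comparable
            if model == "p":
                d = p
            elif model == "jc69":
                if p >= 0.75:
                    raise ValueError(f"jc69 undefined at p={p:.3f} >= 0.75")
                d = -0.75 * math.log(1 - 4 * p / 3)
            elif model == "k2p":
                P, Q = ts / comparable, tv / comparable
                arg1 = 1 - 2 * P - Q
                arg2 = 1 - 2 * Q
                if arg1 <= 0 or arg2 <= 0:
                    raise ValueError("k2p undefined for these frequencies")
                d = -0.5 * math.log(arg1 * math.sqrt(arg2))
            else:
                raise ValueError(f"unknown model: {model}")
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(taxa=list(taxa), values=vals)


def distance(matrix: ConcatenatedMatrix, model: str = "p") -> DistanceMatrix:
    """Pairwise model distances over non-gap shared columns.

    p: proportion of differing sites. jc69: -3/4 ln(1 - 4p/3).
    k2p: -1/2 ln((1-2P-Q) sqrt(1-2Q)) with P transitions, Q transversions.
    """
    if len(matrix.accessions) < 2:
        raise ValueError("need at least 2 rows")
    return _distance_from_array(
        matrix.accessions, _rows_to_array(matrix), model
    )


# ---------------------------------------------------------------------------
# neighbor joining

@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name or ""]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self, include_support: bool = True) -> str:
        return self._nwk(include_support) + ";"

    def _nwk(self, sup: bool) -> str:
        if not self.children:
            return self.name or ""
        inner = ",".join(
            f"{c._nwk(sup)}:{bl:.6f}" for c, bl in self.children
        )
        label = ""
        if sup and self.support is not None:
            label = f"{self.support:.0f}"
        return f"({inner}){label}"


@dataclass
class AccessionTree:
    root: TreeNode
    taxa: list[str]

    def newick(self, include_support: bool = True) -> str:
        return self.root.newick(include_support)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the side not containing taxa[0]."""
        all_taxa = set(self.taxa)
        anchor = self.taxa[0]
        parts: set[frozenset[str]] = set()

        def walk(node: TreeNode):
            for child, _ in node.children:
                side = set(child.leaves())
                if anchor in side:
                    side = all_taxa - side
                if 1 < len(side) < len(all_taxa) - 1:
                    parts.add(frozenset(side))
                walk(child)

        walk(self.root)
        return parts

    def has_bipartition(self, taxa: set[str]) -> bool:
        side = frozenset(taxa if self.taxa[0] not in taxa
                         else set(self.taxa) - set(taxa))
        return side in self.bipartitions()

    def internal_edges(self) -> list[tuple[TreeNode, frozenset[str]]]:
        """(child node, bipartition side) for every internal edge."""
        all_taxa = set(self.taxa)
        anchor = self.taxa[0]
        out = []

        def walk(node: TreeNode):
            for child, _ in node.children:
                if child.children:
                    side = set(child.leaves())
                    if anchor in side:
                        side = all_taxa - side
                    if 1 < len(side) < len(all_taxa) - 1:
                        out.append((child, frozenset(side)))
                walk(child)

        walk(self.root)
        return out


def nj_tree(distmat: DistanceMatrix) -> AccessionTree:
    """Canonical neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion break lexicographically on the joined taxon
    pair. Negative branch lengths are clamped to zero with the remainder
    shifted to the sibling edge. The returned tree is unrooted, represented
    with a trifurcating root (or bifurcating for 2 taxa).
    """
    D = distmat.values
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    taxa = list(distmat.taxa)
    if len(taxa) < 2:
        raise ValueError("need >= 2 taxa")
    nodes: dict[str, TreeNode] = {t: TreeNode(name=t) for t in taxa}
    # active working copy
    labels = list(taxa)
    d = {
        (a, b): float(D[i, j])
        for i, a in enumerate(taxa)
        for j, b in enumerate(taxa)
        if i != j
    }
    if len(taxa) == 2:
        a, b = labels
        root = TreeNode(children=[(nodes[a], d[(a, b)] / 2),
                                  (nodes[b], d[(a, b)] / 2)])
        return AccessionTree(root=root, taxa=taxa)
    counter = 0
    while len(labels) > 3:
        r = len(labels)
        total = {a: sum(d[(a, b)] for b in labels if b != a) for a in labels}
        best = None
        for ai in range(r):
            for bi in range(ai + 1, r):
                a, b = labels[ai], labels[bi]
                q = (r - 2) * d[(a, b)] - total[a] - total[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = d[(a, b)]
        la = 0.5 * dab + (total[a] - total[b]) / (2 * (r - 2))
        lb = dab - la
        # clamp negatives, shifting the remainder to the sibling edge
        if la < 0:
            lb += -la
            la = 0.0
        if lb < 0:
            la += -lb
            lb = 0.0
        new_label = f"_n{counter}"
        counter += 1
        parent = TreeNode(children=[(nodes[a], la), (nodes[b], lb)])
        nodes[new_label] = parent
        for c in labels:
            if c in (a, b):
                continue
            duc = 0.5 * (d[(a, c)] + d[(b, c)] - dab)
            d[(new_label, c)] = d[(c, new_label)] = max(duc, 0.0)
        labels = [c for c in labels if c not in (a, b)] + [new_label]
    a, b, c = sorted(labels)
    la = 0.5 * (d[(a, b)] + d[(a, c)] - d[(b, c)])
    lb = 0.5 * (d[(a, b)] + d[(b, c)] - d[(a, c)])
    lc = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
    root = TreeNode(
        children=[(nodes[a], max(la, 0.0)), (nodes[b], max(lb, 0.0)),
                  (nodes[c], max(lc, 0.0))]
    )
    return AccessionTree(root=root, taxa=taxa)


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap(
    matrix: ConcatenatedMatrix,
    n_replicates: int = 1000,
    seed: int = 0,
    model: str = "p",
) -> AccessionTree:
    """Column bootstrap; supports (% of replicates) mapped onto the full tree.

    Edges of zero length (no signal) can legitimately show low support.
    Reproducible for a fixed seed (counter-based generator).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    full = nj_tree(distance(matrix, model))
    arr = _rows_to_array(matrix)
    n_cols = arr.shape[1]
    rng = np.random.Generator(np.random.Philox(key=seed))
    counts: dict[frozenset[str], int] = {
        side: 0 for _, side in full.internal_edges()
    }
    for _ in range(n_replicates):
        pick = rng.integers(0, n_cols, size=n_cols)
        try:
            rep_dist = _distance_from_array(
                matrix.accessions, arr[:, pick], model
            )
            rep_tree = nj_tree(rep_dist)
        except ValueError:
            continue  # saturated replicate under a log-model
        parts = rep_tree.bipartitions()
        for side in counts:
            if side in parts:
                counts[side] += 1
    for node, side in full.internal_edges():
        node.support = 100.0 * counts[side] / n_replicates
    return full
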