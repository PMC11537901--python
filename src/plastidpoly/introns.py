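"""Per-gene intron lengths across accessions and the length-variance screen.

Intron length is defined purely from annotation coordinates: the genomic gap
between consecutive exons in gene orientation, circular-aware. Exonic bases
are never counted and no re-alignment is involved. Trans-spliced junctions
(exons joined from separate loci, as in plastid rps12) are not introns and
are skipped; only cis gaps are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .quadripartite import QuadripartitePartition
from .records import GeneFeature, PlastomeRecord

#: a cis intron longer than this is not credible in a plastome; on a
#: trans-spliced feature, junction gaps beyond it are classified trans
#: (the largest real plastid intron, trnK-UUU, is ~2.5 kb)
MAX_CIS_INTRON_BP = 4000


def junction_gaps(
    feature: GeneFeature, genome_length: int
) -> list[tuple[int, int, bool]]:
    """Per exon junction: (genomic gap start, gap length, is_cis).

    Gap start/length are on the genome (the intron's own span); for a trans
    junction the values are meaningless and is_cis is False.
    """
    out = []
    for k in range(len(feature.exon_spans) - 1):
        sa, sb = feature.exon_strands[k], feature.exon_strands[k + 1]
        (s1, e1), (s2, e2) = feature.exon_spans[k], feature.exon_spans[k + 1]
        if sa != sb:
            out.append((0, 0, False))
            continue
        lo = e1 if sa == "+" else e2
        hi = s2 if sa == "+" else s1
        gap = (hi - lo) % genome_length
        if feature.is_trans_spliced and (gap == 0 or gap > MAX_CIS_INTRON_BP):
            out.append((0, 0, False))
            continue
        if not feature.is_trans_spliced and gap > genome_length // 2:
            raise ValueError(
                f"{feature.gene_name}: overlapping exons at junction {k} "
                f"(apparent gap {gap} of {genome_length})"
            )
        out.append((lo % genome_length, gap, True))
    return out


def cis_intron_intervals(
    feature: GeneFeature, genome_length: int
) -> list[tuple[int, int]]:
    """Genomic (start, length) of each cis intron, in gene 5'->3' order."""
    return [
        (lo, gap) for lo, gap, is_cis in junction_gaps(feature, genome_length)
        if is_cis
    ]


def locus_footprints(
    feature: GeneFeature, genome_length: int
) -> list[tuple[int, int]]:
    """Contiguous genomic footprints of a feature, split at trans junctions.

    A cis gene yields one interval (exons plus introns); a trans-spliced gene
    yields one interval per locus.
    """
    groups: list[list[tuple[int, int]]] = [[feature.exon_spans[0]]]
    for span, (_, _, is_cis) in zip(
        feature.exon_spans[1:], junction_gaps(feature, genome_length)
    ):
        if is_cis:
            groups[-1].append(span)
        else:
            groups.append([span])
    return [(min(s for s, _ in g), max(e for _, e in g)) for g in groups]


def intron_lengths(record: PlastomeRecord, feature: GeneFeature) -> list[int]:
    """Cis intron lengths of one feature, in gene orientation."""
    if len(feature.exon_spans) < 2:
        raise ValueError(f"{feature.gene_name}: no introns (single exon)")
    return [gap for _, gap in cis_intron_intervals(feature, len(record.sequence))]


@dataclass
class IntronRecord:
    """One (gene, intron index) row across accessions."""

    gene_name: str
    intron_index: int  # 1-based, gene orientation
    region: str  # LSC | SSC | IR
    length_bp: dict[str, int]  # accession -> length

    @property
    def variance_bp(self) -> int:
        """Length variance as printed in comparative tables: max - min."""
        vals = list(self.length_bp.values())
        return max(vals) - min(vals)


@dataclass
class IntronMatrix:
    accessions: list[str]
    records: list[IntronRecord]
    #: genes present with introns in only part of the accession set
    excluded: dict[str, str] = field(default_factory=dict)

    def row(self, gene: str, intron_index: int = 1) -> IntronRecord:
        for r in self.records:
            if r.gene_name.lower() == gene.lower() and r.intron_index == intron_index:
                return r
        raise KeyError(f"{gene} intron {intron_index}")

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.records:
            row = {
                "gene": r.gene_name,
                "intron_index": r.intron_index,
                "region": r.region,
            }
            row.update({acc: r.length_bp[acc] for acc in self.accessions})
            row["variance_bp"] = r.variance_bp
            rows.append(row)
        return pd.DataFrame(rows)


class IRCopyMismatchError(ValueError):
    """The two IR copies of a gene disagree on an intron length."""


def _region_label(part: QuadripartitePartition, pos: int) -> str:
    region = part.region_of(pos)
    return "IR" if region.startswith("IR") else region


def _per_accession_introns(
    record: PlastomeRecord, part: QuadripartitePartition
) -> dict[tuple[str, int], tuple[int, str]]:
    """(gene, intron_index) -> (length, region) with IR duplicates collapsed."""
    n = len(record.sequence)
    by_key: dict[tuple[str, int], list[tuple[int, str]]] = {}
    for f in record.features:
        if len(f.exon_spans) < 2:
            continue
        for idx, (lo, gap) in enumerate(cis_intron_intervals(f, n), start=1):
            mid = (lo + gap // 2) % n
            region = _region_label(part, mid)
            by_key.setdefault((f.gene_name.lower(), idx), []).append((gap, region))
    out: dict[tuple[str, int], tuple[int, str]] = {}
    for key, values in by_key.items():
        lengths = {v[0] for v in values}
        if len(lengths) > 1:
            raise IRCopyMismatchError(
                f"{record.accession_id}/{key[0]} intron {key[1]}: IR copies "
                f"disagree on length: {sorted(lengths)}"
            )
        # IR copies collapse to one row; region 'IR' wins if any copy is there
        region = "IR" if any(v[1] == "IR" for v in values) else values[0][1]
        out[key] = (values[0][0], region)
    return out


def build_matrix(
    records: list[PlastomeRecord],
    partitions: list[QuadripartitePartition],
) -> IntronMatrix:
    """Intron-length matrix over the genes intron-bearing in ALL accessions.

    Genes missing (or intronless) in some accession are excluded from the
    common set and listed in ``matrix.excluded``.
    """
    if not records:
        raise ValueError("need at least 1 accession")
    per_acc = {
        rec.accession_id: _per_accession_introns(rec, part)
        for rec, part in zip(records, partitions)
    }
    accessions = [r.accession_id for r in records]
    common = set.intersection(*(set(m) for m in per_acc.values()))
    all_keys = set.union(*(set(m) for m in per_acc.values()))
    excluded = {
        f"{g} intron {i}": "absent in some accessions"
        for g, i in sorted(all_keys - common)
    }
    # preserve case of gene names as annotated in the first record
    case = {}
    for f in records[0].features:
        case.setdefault(f.gene_name.lower(), f.gene_name)
    rows = []
    for gene, idx in sorted(common):
        lengths = {acc: per_acc[acc][(gene, idx)][0] for acc in accessions}
        region = per_acc[accessions[0]][(gene, idx)][1]
        rows.append(
            IntronRecord(
                gene_name=case.get(gene, gene),
                intron_index=idx,
                region=region,
                length_bp=lengths,
            )
        )
    return IntronMatrix(accessions=accessions, records=rows, excluded=excluded)


def polymorphic_genes(
    matrix: IntronMatrix, min_variance_bp: int = 10
) -> list[IntronRecord]:
    """Rows with length variance >= threshold, sorted by variance descending."""
    hits = [r for r in matrix.records if r.variance_bp >= min_variance_bp]
    return sorted(hits, key=lambda r: (-r.variance_bp, r.gene_name.lower(),
                                       r.intron_index))


def group_accessions_by_intron_profile(
    matrix: IntronMatrix,
) -> list[list[str]]:
    """Partition accessions into groups sharing identical intron-length vectors."""
    profiles: dict[tuple[int, ...], list[str]] = {}
    for acc in matrix.accessions:
        vec = tuple(r.length_bp[acc] for r in matrix.records)
        profiles.setdefault(vec, []).append(acc)
    return sorted(profiles.values(), key=lambda g: (-len(g), g[0]))
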