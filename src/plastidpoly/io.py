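"""GenBank / FASTA input and output for plastome records.

Biopython does the flat-file parsing; this module maps annotations onto the
package's circular-aware coordinate model (0-based half-open, exons ordered
5'->3' in gene orientation) and back.
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .records import FeatureClass, GeneFeature, PlastomeRecord

_TYPED = {"CDS": FeatureClass.PROTEIN_CODING, "tRNA": FeatureClass.TRNA,
          "rRNA": FeatureClass.RRNA}


def _classify_by_name(name: str) -> FeatureClass:
    low = name.lower()
    if low.startswith("trn"):
        return FeatureClass.TRNA
    if low.startswith("rrn"):
        return FeatureClass.RRNA
    return FeatureClass.PROTEIN_CODING


def _feature_name(feat) -> str | None:
    for key in ("gene", "locus_tag", "product"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return None


def _merge_origin_parts(
    spans: list[tuple[int, int]], strands: list[str], genome_length: int
) -> tuple[list[tuple[int, int]], list[str]]:
    """Fuse adjacent exon parts that abut across the origin into one wrapped span.

    GenBank writes an origin-spanning exon of a circular molecule as two
    joined parts; biologically it is a single exon, not a zero-length intron.
    """
    out_spans: list[tuple[int, int]] = []
    out_strands: list[str] = []
    for span, strand in zip(spans, strands):
        if out_spans and out_strands[-1] == strand:
            ps, pe = out_spans[-1]
            s, e = span
            if strand == "+" and pe % genome_length == s:
                out_spans[-1] = (ps, e)
                continue
            if strand == "-" and e % genome_length == ps:
                out_spans[-1] = (s, pe)
                continue
        out_spans.append(span)
        out_strands.append(strand)
    return out_spans, out_strands


def _to_gene_feature(feat, fclass: FeatureClass, genome_length: int) -> GeneFeature | None:
    name = _feature_name(feat)
    if name is None:
        return None
    spans: list[tuple[int, int]] = []
    strands: list[str] = []
    for part in feat.location.parts:
        spans.append((int(part.start), int(part.end)))
        strands.append("-" if part.strand == -1 else "+")
    spans, strands = _merge_origin_parts(spans, strands, genome_length)
    mixed = len(set(strands)) > 1
    trans = mixed or "trans_splicing" in feat.qualifiers
    strand = strands[0]
    return GeneFeature(
        gene_name=name,
        feature_class=fclass,
        strand=strand,
        exon_spans=spans,
        is_trans_spliced=trans,
        exon_strands=strands,
    )


def _single_record(path: str, fmt: str) -> SeqRecord:
    try:
        records = list(SeqIO.parse(path, fmt))
    except Exception as exc:  # malformed flat file
        raise ValueError(f"{path}: cannot parse as {fmt}: {exc}") from exc
    if len(records) != 1:
        raise ValueError(
            f"{path}: expected a single {fmt} record, found {len(records)}"
        )
    rec = records[0]
    if len(rec.seq) == 0:
        raise ValueError(f"{path}: record {rec.id} has zero-length sequence")
    return rec


def read_genbank(path: str) -> PlastomeRecord:
    """Read a single-record GenBank flat file into a PlastomeRecord.

    Exon structure is taken from the spliced feature (CDS/tRNA/rRNA) when one
    exists for a locus; bare ``gene`` features are used only for loci with no
    typed feature. GenBank 1-based inclusive coordinates become 0-based
    half-open.
    """
    rec = _single_record(path, "genbank")
    n = len(rec.seq)
    topology = rec.annotations.get("topology", "circular")
    features: list[GeneFeature] = []
    typed_names: set[str] = set()
    for feat in rec.features:
        if feat.type in _TYPED:
            gf = _to_gene_feature(feat, _TYPED[feat.type], n)
            if gf is not None:
                features.append(gf)
                typed_names.add(gf.gene_name.lower())
    for feat in rec.features:
        if feat.type == "gene":
            name = _feature_name(feat)
            if name is None or name.lower() in typed_names:
                continue
            gf = _to_gene_feature(feat, _classify_by_name(name), n)
            if gf is not None:
                features.append(gf)
    organism = rec.annotations.get("organism", "") or ""
    out = PlastomeRecord(
        accession_id=rec.id if rec.id != "<unknown id>" else rec.name,
        sequence=str(rec.seq),
        organism=organism,
        is_circular=(topology == "circular"),
        features=features,
        source_format="genbank",
    )
    out.validate()
    return out


def read_fasta(path: str) -> PlastomeRecord:
    """Read a single-sequence FASTA file (no features)."""
    if os.path.getsize(path) == 0:
        raise ValueError(f"{path}: empty FASTA file")
    rec = _single_record(path, "fasta")
    return PlastomeRecord(
        accession_id=rec.id,
        sequence=str(rec.seq),
        organism="",
        is_circular=True,
        features=[],
        source_format="fasta",
    )


def write_fasta(record: PlastomeRecord, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{record.accession_id}\n")
        seq = record.sequence
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def _location_for(spans, strands, genome_length: int):
    parts = []
    for (s, e), strand in zip(spans, strands):
        istrand = -1 if strand == "-" else 1
        if e > s:
            parts.append(SimpleLocation(s, e, istrand))
        else:  # wrapped exon -> two GenBank parts
            if strand == "+":
                parts.append(SimpleLocation(s, genome_length, istrand))
                parts.append(SimpleLocation(0, e, istrand))
            else:
                parts.append(SimpleLocation(0, e, istrand))
                parts.append(SimpleLocation(s, genome_length, istrand))
    return parts[0] if len(parts) == 1 else CompoundLocation(parts)


def write_genbank(record: PlastomeRecord, path: str) -> None:
    """Serialize a PlastomeRecord to a single-record GenBank flat file."""
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.accession_id,
        name=record.accession_id[:16].replace(".", "_"),
        description=record.organism or "synthetic plastome",
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if record.is_circular else "linear"
    rec.annotations["organism"] = record.organism
    type_for = {
        FeatureClass.PROTEIN_CODING: "CDS",
        FeatureClass.TRNA: "tRNA",
        FeatureClass.RRNA: "rRNA",
    }
    n = len(record.sequence)
    for gf in record.features:
        loc = _location_for(gf.exon_spans, gf.exon_strands, n)
        quals = {"gene": [gf.gene_name]}
        if gf.is_trans_spliced:
            quals["trans_splicing"] = [""]
        rec.features.append(
            SeqFeature(loc, type=type_for[gf.feature_class], qualifiers=quals)
        )
    SeqIO.write([rec], path, "genbank")


def read_any(path: str) -> PlastomeRecord:
    """Read GenBank or FASTA based on file content."""
    with open(path) as fh:
        head = fh.read(1)
    return read_fasta(path) if head == ">" else read_genbank(path)


def read_many(paths: Iterable[str]) -> list[PlastomeRecord]:
    return [read_any(p) for p in paths]
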