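"""Core data model for annotated plastomes.

Coordinates are 0-based half-open throughout the package; GenBank's 1-based
inclusive convention is converted at the I/O boundary. Windows on a circular
genome may wrap the origin, in which case ``end < start`` and the window
covers ``[start, L) + [0, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def span_length(span: tuple[int, int], genome_length: int) -> int:
    """Length of a half-open span; wrapped spans (end < start) allowed."""
    s, e = span
    return e - s if e > s else (genome_length - s) + e


def span_extract(span: tuple[int, int], sequence: str) -> str:
    s, e = span
    return sequence[s:e] if e > s else sequence[s:] + sequence[:e]


class FeatureClass(str, Enum):
    PROTEIN_CODING = "protein_coding"
    TRNA = "tRNA"
    RRNA = "rRNA"


@dataclass(frozen=True)
class SequenceWindow:
    """Half-open span on a (possibly circular) genome.

    A wrapped window has ``end < start`` and length ``(L - start) + end``.
    """

    start: int
    end: int

    def length(self, genome_length: int) -> int:
        if self.end >= self.start:
            return self.end - self.start
        return (genome_length - self.start) + self.end

    def wraps(self) -> bool:
        return self.end < self.start

    def extract(self, sequence: str) -> str:
        if self.end >= self.start:
            return sequence[self.start : self.end]
        return sequence[self.start :] + sequence[: self.end]

    def positions(self, genome_length: int) -> Iterator[int]:
        """Iterate genome positions covered by the window, 5'-to-3' on +."""
        if self.end >= self.start:
            yield from range(self.start, self.end)
        else:
            yield from range(self.start, genome_length)
            yield from range(0, self.end)

    def contains(self, pos: int, genome_length: int) -> bool:
        if self.end >= self.start:
            return self.start <= pos < self.end
        return pos >= self.start or pos < self.end

    def midpoint(self, genome_length: int) -> int:
        return (self.start + self.length(genome_length) // 2) % genome_length


@dataclass
class GeneFeature:
    """One annotated gene with its exon structure.

    ``exon_spans`` are ordered 5'->3' in gene orientation: for a minus-strand
    gene the first span is the most downstream one in genome coordinates.
    Cis intron count equals ``len(exon_spans) - 1`` for non-trans-spliced
    features.
    """

    gene_name: str
    feature_class: FeatureClass
    strand: str  # '+' or '-'
    exon_spans: list[tuple[int, int]]
    is_ir_copy: bool = False
    is_trans_spliced: bool = False
    # strand per exon; only differs from `strand` for trans-spliced genes
    exon_strands: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exon_spans:
            raise ValueError(f"{self.gene_name}: feature has no exon spans")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_name}: strand must be '+' or '-'")
        if not self.exon_strands:
            self.exon_strands = [self.strand] * len(self.exon_spans)
        if len(self.exon_strands) != len(self.exon_spans):
            raise ValueError(f"{self.gene_name}: exon_strands length mismatch")
        if not self.is_trans_spliced and any(
            s != self.strand for s in self.exon_strands
        ):
            raise ValueError(
                f"{self.gene_name}: mixed exon strands on a cis-spliced gene"
            )

    @property
    def n_cis_introns(self) -> int:
        if not self.is_trans_spliced:
            return len(self.exon_spans) - 1
        # junctions between exons on different strands are trans junctions
        return sum(
            1
            for a, b in zip(self.exon_strands, self.exon_strands[1:])
            if a == b
        )

    def span(self) -> tuple[int, int]:
        """Genomic footprint (min start, max end) over all exons (non-wrapping)."""
        starts = [s for s, _ in self.exon_spans]
        ends = [e for _, e in self.exon_spans]
        return min(starts), max(ends)

    def copy(self) -> "GeneFeature":
        return replace(
            self,
            exon_spans=list(self.exon_spans),
            exon_strands=list(self.exon_strands),
        )


@dataclass
class PlastomeRecord:
    """A plastome: circular sequence plus ordered gene features."""

    accession_id: str
    sequence: str
    organism: str = ""
    is_circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    source_format: str = "genbank"

    def __post_init__(self) -> None:
        if not self.accession_id:
            raise ValueError("accession_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.accession_id}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"{self.accession_id}: ambiguity characters other than N "
                f"are not supported: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        """Check feature spans lie within the genome.

        Wrapped spans (end < start) are accepted only on circular records.
        """
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.exon_spans:
                ok = 0 <= s < n and 0 <= e <= n and s != e
                if ok and e < s and not self.is_circular:
                    ok = False
                if not ok:
                    raise ValueError(
                        f"{self.accession_id}/{f.gene_name}: exon span "
                        f"({s},{e}) invalid for genome length {n}"
                    )

    def genes(self, name: str) -> list[GeneFeature]:
        key = name.lower()
        return [f for f in self.features if f.gene_name.lower() == key]

    def gene_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.features:
            seen.setdefault(f.gene_name, None)
        return list(seen)

    def subsequence(self, window: SequenceWindow) -> str:
        return window.extract(self.sequence)

    def rotated(self, offset: int) -> "PlastomeRecord":
        """Rotate the circular sequence so genome position ``offset`` becomes 0."""
        if not self.is_circular:
            raise ValueError(f"{self.accession_id}: cannot rotate a linear record")
        n = len(self.sequence)
        offset %= n
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats = []
        for f in self.features:
            g = f.copy()
            g.exon_spans = [
                ((s - offset) % n, ((e - offset - 1) % n) + 1)
                for s, e in f.exon_spans
            ]
            feats.append(g)
        return PlastomeRecord(
            accession_id=self.accession_id,
            sequence=seq,
            organism=self.organism,
            is_circular=True,
            features=feats,
            source_format=self.source_format,
        )


def spliced_sequence(record: PlastomeRecord, feature: GeneFeature) -> str:
    """Concatenated exon sequence in 5'->3' gene orientation.

    Minus-strand exons are reverse-complemented. Exons are joined in the
    annotated 5'->3' order, which for trans-spliced genes is not genome order.
    """
    n = len(record.sequence)
    parts = []
    for (s, e), strand in zip(feature.exon_spans, feature.exon_strands):
        if e > n or s >= n:
            raise ValueError(
                f"{feature.gene_name}: exon ({s},{e}) beyond sequence of "
                f"length {n}"
            )
        if e < s and not record.is_circular:
            raise ValueError(
                f"{feature.gene_name}: wrapped exon ({s},{e}) on a linear record"
            )
        sub = span_extract((s, e), record.sequence)
        parts.append(revcomp(sub) if strand == "-" else sub)
    return "".join(parts)
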