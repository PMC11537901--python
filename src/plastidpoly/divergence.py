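"""Pairwise divergence scanning against a reference plastome.

Each query is globally aligned to the reference (anchor-chain-and-fill),
identity is computed in sliding windows of reference coordinates, InDels are
called from gap runs with flanking-gene context, and low-identity windows
are merged into ranked divergent regions. This mirrors the classic
visual-alignment divergence plots at the data level: windows of percent
identity on a 50-100% scale, conserved coding regions, variable spacers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import (
    DEFAULT_SCORING,
    Scoring,
    anchored_global_alignment,
)
from .records import PlastomeRecord


@dataclass
class PairwiseAlignment:
    """Gapped global alignment of query against reference."""

    ref_accession: str
    query_accession: str
    ref_aligned: str
    query_aligned: str

    def __post_init__(self) -> None:
        if len(self.ref_aligned) != len(self.query_aligned):
            raise ValueError("aligned rows differ in length")

    @property
    def ref_sequence(self) -> str:
        return self.ref_aligned.replace("-", "")

    @property
    def query_sequence(self) -> str:
        return self.query_aligned.replace("-", "")

    def columns(self):
        """Yield (ref_pos or None, is_match, ref_char, query_char)."""
        pos = 0
        for rc, qc in zip(self.ref_aligned, self.query_aligned):
            if rc == "-":
                yield None, False, rc, qc
            else:
                yield pos, rc == qc, rc, qc
                pos += 1


def align_to_reference(
    ref: PlastomeRecord,
    query: PlastomeRecord,
    scoring: Scoring = DEFAULT_SCORING,
    anchor_k: int = 20,
) -> PairwiseAlignment:
    """Global alignment of two canonically rotated plastomes.

    Callers should rotate both records to the canonical LSC start first
    (see quadripartite.canonicalize); the alignment itself is linear.
    """
    ra, qa = anchored_global_alignment(
        ref.sequence, query.sequence, scoring=scoring, k=anchor_k
    )
    return PairwiseAlignment(ref.accession_id, query.accession_id, ra, qa)


@dataclass
class IdentityProfile:
    ref_accession: str
    query_accession: str
    window_bp: int
    step_bp: int
    window_starts: list[int]
    window_identity: list[float]

    def min_identity(self) -> float:
        return min(self.window_identity)


def windowed_identity(
    alignment: PairwiseAlignment, window_bp: int = 100, step_bp: int = 25
) -> IdentityProfile:
    """Percent identity per reference-coordinate window.

    Identity = matching columns / columns assigned to the window x 100.
    Gap columns count as non-matches; insertion columns (gap in the
    reference) are assigned to the window of the preceding reference base.
    """
    ref_len = len(alignment.ref_sequence)
    # per-column assignment to a reference position
    assigned: list[tuple[int, bool]] = []
    last_pos = 0
    for pos, is_match, _, _ in alignment.columns():
        if pos is None:
            assigned.append((last_pos, False))
        else:
            assigned.append((pos, is_match))
            last_pos = pos
    if window_bp >= ref_len:
        matches = sum(1 for _, m in assigned if m)
        return IdentityProfile(
            alignment.ref_accession,
            alignment.query_accession,
            window_bp,
            step_bp,
            [0],
            [100.0 * matches / len(assigned)],
        )
    starts = list(range(0, ref_len - window_bp + 1, step_bp))
    # bucket columns by ref position for fast windowing
    per_pos_total = [0] * ref_len
    per_pos_match = [0] * ref_len
    for pos, m in assigned:
        per_pos_total[pos] += 1
        per_pos_match[pos] += 1 if m else 0
    # prefix sums
    ct = [0]
    cm = [0]
    for t, m in zip(per_pos_total, per_pos_match):
        ct.append(ct[-1] + t)
        cm.append(cm[-1] + m)
    idents = []
    for s in starts:
        e = s + window_bp
        total = ct[e] - ct[s]
        match = cm[e] - cm[s]
        idents.append(100.0 * match / total if total else 0.0)
    return IdentityProfile(
        alignment.ref_accession,
        alignment.query_accession,
        window_bp,
        step_bp,
        starts,
        idents,
    )


@dataclass(frozen=True)
class IndelCall:
    ref_position: int
    length_bp: int
    kind: str  # 'deletion_in_query' | 'insertion_in_query'
    flanking_genes: tuple[str | None, str | None] = (None, None)


def call_indels(
    alignment: PairwiseAlignment, ref: PlastomeRecord | None = None
) -> list[IndelCall]:
    """Gap runs of the alignment as InDel calls in reference coordinates.

    A deletion-in-query is a gap run in the query row (its reference span
    starts at ref_position); an insertion-in-query is a gap run in the
    reference row (anchored at the following reference position). Flanking
    genes come from the reference annotation when provided.
    """
    calls: list[IndelCall] = []
    pos = 0  # current ref position
    i = 0
    ra, qa = alignment.ref_aligned, alignment.query_aligned
    n = len(ra)
    while i < n:
        if qa[i] == "-":
            start = pos
            length = 0
            while i < n and qa[i] == "-":
                length += 1
                pos += 1
                i += 1
            calls.append(IndelCall(start, length, "deletion_in_query"))
        elif ra[i] == "-":
            length = 0
            while i < n and ra[i] == "-":
                length += 1
                i += 1
            calls.append(IndelCall(pos, length, "insertion_in_query"))
        else:
            pos += 1
            i += 1
    if ref is not None:
        calls = [
            IndelCall(c.ref_position, c.length_bp, c.kind,
                      _flanking_genes(ref, c.ref_position))
            for c in calls
        ]
    return calls


def _flanking_genes(ref: PlastomeRecord, pos: int) -> tuple[str | None, str | None]:
    """Nearest gene ending at/before pos and nearest gene starting after.

    Trans-spliced genes contribute one interval per locus, so a multi-locus
    gene never swallows the loci between its parts.
    """
    from .introns import locus_footprints

    left = None
    right = None
    left_end = -1
    right_start = None
    n = len(ref.sequence)
    for f in ref.features:
        for s, e in locus_footprints(f, n):
            if s <= pos < e:
                return (f.gene_name, f.gene_name)  # inside a gene locus
            if e <= pos and e > left_end:
                left_end, left = e, f.gene_name
            if s > pos and (right_start is None or s < right_start):
                right_start, right = s, f.gene_name
    return (left, right)


@dataclass(frozen=True)
class DivergentRegion:
    start: int  # ref coords, half-open
    end: int
    min_identity: float
    gene_context: tuple[str, ...] = field(default=())


def divergent_regions(
    profiles: list[IdentityProfile],
    identity_threshold: float = 90.0,
    ref: PlastomeRecord | None = None,
) -> list[DivergentRegion]:
    """Maximal low-identity intervals, merged across accessions and ranked.

    Windows below the threshold in ANY profile are unioned; overlapping
    window spans merge into intervals labeled by overlapping or flanking
    reference genes. Ranked by minimum identity ascending.
    """
    if not profiles:
        raise ValueError("no identity profiles given")
    intervals: list[tuple[int, int, float]] = []
    for p in profiles:
        for s, ident in zip(p.window_starts, p.window_identity):
            if ident < identity_threshold:
                intervals.append((s, s + p.window_bp, ident))
    if not intervals:
        return []
    intervals.sort()
    merged: list[list[float]] = []
    for s, e, ident in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] = min(merged[-1][2], ident)
        else:
            merged.append([s, e, ident])
    out = []
    for s, e, ident in merged:
        context: tuple[str, ...] = ()
        if ref is not None:
            context = _gene_context(ref, int(s), int(e))
        out.append(DivergentRegion(int(s), int(e), float(ident), context))
    return sorted(out, key=lambda r: (r.min_identity, r.start))


def _gene_context(ref: PlastomeRecord, start: int, end: int) -> tuple[str, ...]:
    from .introns import locus_footprints

    n = len(ref.sequence)
    overlapping = []
    for f in ref.features:
        if any(s < end and start < e for s, e in locus_footprints(f, n)):
            overlapping.append(f.gene_name)
    if overlapping:
        return tuple(dict.fromkeys(overlapping))
    left, right = _flanking_genes(ref, start)
    label = f"{left or 'origin'}-{right or 'end'}"
    return (label,)


def profiles_to_frame(profiles: list[IdentityProfile]):
    """Long-form table of windowed identities for TSV export."""
    import pandas as pd

    rows = []
    for p in profiles:
        for s, ident in zip(p.window_starts, p.window_identity):
            rows.append(
                {
                    "ref": p.ref_accession,
                    "query": p.query_accession,
                    "window_start": s,
                    "identity_pct": round(ident, 2),
                }
            )
    return pd.DataFrame(rows)


def indels_to_bed(calls: list[IndelCall], ref_accession: str) -> str:
    """BED lines (0-based half-open) for InDel calls."""
    lines = []
    for c in calls:
        end = c.ref_position + (c.length_bp if c.kind == "deletion_in_query" else 1)
        name = f"{c.kind}:{c.length_bp}bp"
        if c.flanking_genes != (None, None):
            name += f":{c.flanking_genes[0]}|{c.flanking_genes[1]}"
        lines.append(f"{ref_accession}\t{c.ref_position}\t{end}\t{name}")
    return "\n".join(lines) + ("\n" if lines else "")
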