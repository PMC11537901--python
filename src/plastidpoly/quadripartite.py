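"""Inverted-repeat detection and quadripartite partitioning.

The detector finds maximal exact inverted-repeat pairs on the circular
sequence by seed-and-extend over k-mers shared between the genome and its
reverse complement. The longest pair defines IRa/IRb; the two inter-IR arcs
become LSC (longer) and SSC (shorter). All coordinates are 0-based half-open
on the circle.

An inverted-repeat pair (i, j, L) satisfies
``sequence[j:j+L] == revcomp(sequence[i:i+L])`` (circularly). Maximality is
taken under the constraint that the two copies stay disjoint on the circle;
a self-reverse-complementary (palindromic) stretch therefore yields a hit
whose copies are its two halves.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import PlastomeRecord, SequenceWindow, revcomp, span_extract


class NotQuadripartiteError(ValueError):
    """No inverted repeat long enough to define IRa/IRb."""


class AmbiguousIRError(ValueError):
    """The two longest IR hits overlap; partition is ill-defined."""


@dataclass(frozen=True)
class IRHit:
    """One maximal inverted-repeat pair; span_b is the revcomp of span_a."""

    span_a: SequenceWindow
    span_b: SequenceWindow
    length: int


@dataclass(frozen=True)
class QuadripartitePartition:
    lsc: SequenceWindow
    ssc: SequenceWindow
    ira: SequenceWindow
    irb: SequenceWindow
    genome_length: int

    @property
    def lengths(self) -> dict[str, int]:
        n = self.genome_length
        return {
            "LSC": self.lsc.length(n),
            "SSC": self.ssc.length(n),
            "IRa": self.ira.length(n),
            "IRb": self.irb.length(n),
        }

    def window(self, region: str) -> SequenceWindow:
        return {"LSC": self.lsc, "SSC": self.ssc,
                "IRa": self.ira, "IRb": self.irb}[region]

    def region_of(self, pos: int) -> str:
        for name in ("LSC", "IRa", "SSC", "IRb"):
            if self.window(name).contains(pos, self.genome_length):
                return name
        raise ValueError(f"position {pos} not covered")  # pragma: no cover

    def region_gc(self, sequence: str) -> dict[str, float]:
        return {
            name: gc_content(self.window(name).extract(sequence))
            for name in ("LSC", "SSC", "IRa", "IRb")
        }


def gc_content(sequence: str, digits: int | None = None) -> float:
    """GC percentage over unambiguous bases; N is excluded from the denominator."""
    if not sequence:
        raise ValueError("gc_content of empty sequence is undefined")
    gc = sequence.count("G") + sequence.count("C")
    at = sequence.count("A") + sequence.count("T")
    if gc + at == 0:
        raise ValueError("gc_content undefined: no unambiguous bases")
    pct = 100.0 * gc / (gc + at)
    return round(pct, digits) if digits is not None else pct


def _match(seq: str, x: int, y: int) -> bool:
    """True when seq[x] is the Watson-Crick complement of seq[y] (N never matches)."""
    a, b = seq[x], seq[y]
    if a == "N" or b == "N":
        return False
    return (a, b) in (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


def _hit_from_run(n: int, i: int, j: int, length: int) -> IRHit | None:
    """Normalize a maximal run into an IRHit (copy pair or palindrome split)."""
    if length == n:  # whole circle self-reverse-complementary: split at 0
        half = n // 2
        return IRHit(SequenceWindow(0, half), SequenceWindow(half, n % n or n), half)
    if i == j:  # self-palindromic run: the two halves pair with each other
        half = length // 2
        if half == 0:
            return None
        mid = (i + half) % n
        b_start = (i + length - half) % n  # skips the middle base if length is odd
        end = (i + length) % n
        return IRHit(SequenceWindow(i, mid), SequenceWindow(b_start, end), half)
    a, b = sorted(((i, length), (j, length)))
    return IRHit(
        SequenceWindow(a[0], (a[0] + length) % n),
        SequenceWindow(b[0], (b[0] + length) % n),
        length,
    )


def find_inverted_repeats(sequence: str, min_ir_len: int) -> list[IRHit]:
    """All maximal exact inverted-repeat pairs of length >= min_ir_len.

    Seed-and-extend: k-mers of the genome are indexed; k-mers of the reverse
    complement are looked up and each seed extended to a maximal match on the
    circle. Results are sorted by length descending, then by start positions.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if n < 2 * min_ir_len:
        raise ValueError(
            f"sequence length {n} < 2 x min_ir_len ({min_ir_len})"
        )
    k = min(16, min_ir_len)
    doubled = sequence + sequence
    index: dict[str, list[int]] = {}
    for p in range(n):
        kmer = doubled[p : p + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(p)
    rc = revcomp(sequence)
    rc_doubled = rc + rc

    seen: set[tuple[int, int, int]] = set()
    consumed: set[tuple[int, int]] = set()  # (diagonal, seed pos) already in a run
    hits: dict[tuple[int, int, int], IRHit] = {}
    for p in range(n):
        kmer = rc_doubled[p : p + k]
        for i0 in index.get(kmer, ()):
            diag = (i0 - p) % n
            if (diag, i0) in consumed:
                continue
            # S[i0:i0+k] == RC[p:p+k]; extend circularly in S-vs-RC space
            i, p0, length = i0, p, k
            run = _extend(sequence, rc, n, i, p0, length)
            i, p0, length = run
            for t in range(length):
                consumed.add((diag, (i + t) % n))
            j = (n - p0 - length) % n
            key = (min(i, j), max(i, j), length)
            if key in seen:
                continue
            seen.add(key)
            if i == j or length >= min_ir_len:
                hit = _hit_from_run(n, i, j, length)
                if hit is not None and hit.length >= min_ir_len:
                    hk = (hit.span_a.start, hit.span_b.start, hit.length)
                    hits[hk] = hit
    out = sorted(
        hits.values(),
        key=lambda h: (-h.length, h.span_a.start, h.span_b.start),
    )
    return out


def _extend(seq: str, rc: str, n: int, i: int, p: int, length: int):
    """Extend an exact S-vs-revcomp(S) match maximally on the circle."""
    # left
    while length < n and seq[(i - 1) % n] == rc[(p - 1) % n] and seq[(i - 1) % n] != "N":
        i = (i - 1) % n
        p = (p - 1) % n
        length += 1
    # right
    while length < n and seq[(i + length) % n] == rc[(p + length) % n] and seq[(i + length) % n] != "N":
        length += 1
    return i, p, length


def find_inverted_repeats_bruteforce(sequence: str, min_ir_len: int) -> list[IRHit]:
    """O(n^2) oracle: scan every diagonal of S vs revcomp(S) for maximal runs.

    Independent of the seed-and-extend path; used for verification.
    """
    import numpy as np

    sequence = sequence.upper()
    n = len(sequence)
    if n < 2 * min_ir_len:
        raise ValueError(
            f"sequence length {n} < 2 x min_ir_len ({min_ir_len})"
        )
    s = np.frombuffer(sequence.encode(), dtype=np.uint8)
    comp_map = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCA\0"):
        comp_map[a] = b
    comp = comp_map[s]  # complement of each base; N -> 0 never matches
    rev = comp[::-1]
    hits: dict[tuple[int, int, int], IRHit] = {}
    for c in range(n):
        # comp[(c-1-t) % n] as a function of t is rev rolled by c
        ind = s == np.roll(rev, c)
        if int(ind.sum()) < min_ir_len:  # max run length <= number of matches
            continue
        runs = _circular_runs(ind, min_len=min_ir_len)
        for a, length in runs:
            # map diagonal run [a, a+length) to the S-vs-RC pair convention
            i = a
            p = (n - c + a) % n
            j = (n - p - length) % n
            hit = _hit_from_run(n, min(i, j), max(i, j), length) if i != j else _hit_from_run(n, i, j, length)
            if hit is not None and hit.length >= min_ir_len:
                hk = (hit.span_a.start, hit.span_b.start, hit.length)
                hits[hk] = hit
    return sorted(
        hits.values(),
        key=lambda h: (-h.length, h.span_a.start, h.span_b.start),
    )


def _circular_runs(ind, min_len: int = 1) -> list[tuple[int, int]]:
    """Maximal runs of True (length >= min_len) in a circular boolean array."""
    import numpy as np

    n = len(ind)
    if ind.all():
        return [(0, n)]
    if not ind.any():
        return []
    r = int(np.argmin(ind))  # a False position; rotate it to the front
    rolled = np.roll(ind, -r).astype(np.int8)
    d = np.diff(np.concatenate(([0], rolled, [0])))
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0]
    lengths = ends - starts
    keep = lengths >= min_len
    return [
        (int((s + r) % n), int(ln))
        for s, ln in zip(starts[keep], lengths[keep])
    ]


def partition(
    record: PlastomeRecord, min_ir_len: int = 1000
) -> QuadripartitePartition:
    """Partition a circular plastome into LSC/SSC/IRa/IRb.

    The longest IR hit defines the repeat pair; the longer inter-IR arc is
    LSC. Region lengths are invariant under rotation of the input.
    """
    seq = record.sequence
    n = len(seq)
    hits = find_inverted_repeats(seq, min_ir_len)
    if not hits:
        raise NotQuadripartiteError(
            f"{record.accession_id}: no inverted repeat >= {min_ir_len} bp"
        )
    top = hits[0]
    if len(hits) > 1 and _hits_overlap(top, hits[1], n):
        raise AmbiguousIRError(
            f"{record.accession_id}: two longest IR hits overlap: "
            f"{top} vs {hits[1]}"
        )
    a, b = top.span_a, top.span_b
    arc1 = SequenceWindow(a.end % n, b.start)  # after copy A, before copy B
    arc2 = SequenceWindow(b.end % n, a.start)  # after copy B, before copy A
    l1, l2 = arc1.length(n), arc2.length(n)
    if l1 == 0 or l2 == 0:
        raise NotQuadripartiteError(
            f"{record.accession_id}: an inter-IR arc is empty"
        )
    if l1 != l2:
        lsc_is_arc1 = l1 > l2
    else:
        lsc_is_arc1 = _arc_tiebreak(record, arc1, arc2)
    if lsc_is_arc1:
        lsc, ssc = arc1, arc2
        ira, irb = b, a  # IRa follows LSC in LSC->IRa->SSC->IRb order
    else:
        lsc, ssc = arc2, arc1
        ira, irb = a, b
    return QuadripartitePartition(lsc=lsc, ssc=ssc, ira=ira, irb=irb,
                                  genome_length=n)


def _hits_overlap(h1: IRHit, h2: IRHit, n: int) -> bool:
    def covered(w: SequenceWindow) -> set[int]:
        return set(w.positions(n))

    c1 = covered(h1.span_a) | covered(h1.span_b)
    c2 = covered(h2.span_a) | covered(h2.span_b)
    return bool(c1 & c2)


def _arc_tiebreak(record, arc1, arc2) -> bool:
    """True if arc1 should be LSC: more genes, then lower GC."""
    n = len(record.sequence)

    def ngenes(arc):
        return sum(
            1
            for f in record.features
            if arc.contains(f.exon_spans[0][0], n)
        )

    g1, g2 = ngenes(arc1), ngenes(arc2)
    if g1 != g2:
        return g1 > g2
    return gc_content(arc1.extract(record.sequence)) <= gc_content(
        arc2.extract(record.sequence)
    )


def canonicalize(record: PlastomeRecord, min_ir_len: int = 1000):
    """Rotate so LSC starts at 0 with order LSC, IRa, SSC, IRb.

    Returns (rotated record, partition of the rotated record).
    """
    part = partition(record, min_ir_len)
    rotated = record.rotated(part.lsc.start)
    return rotated, partition(rotated, min_ir_len)


def duplicated_in_ir(
    record: PlastomeRecord, part: QuadripartitePartition
) -> tuple[list[str], list[str]]:
    """Gene names with one complete copy in each IR, plus boundary-straddlers.

    Side effect: features fully inside an IR window get ``is_ir_copy=True``.
    Returns (duplicated_names, boundary_gene_names).
    """
    n = part.genome_length
    in_ira: set[str] = set()
    in_irb: set[str] = set()
    boundary: list[str] = []
    placement: list[tuple] = []  # (feature, fully inside an IR?)
    for f in record.features:
        placed = False
        for win, bucket in ((part.ira, in_ira), (part.irb, in_irb)):
            inside = all(
                win.contains(s, n) and win.contains((e - 1) % n, n)
                for s, e in f.exon_spans
            )
            if inside:
                bucket.add(f.gene_name)
                placed = True
        placement.append((f, placed))
        if not placed:
            touches_ir = any(
                part.region_of(s).startswith("IR")
                or part.region_of((e - 1) % n).startswith("IR")
                for s, e in f.exon_spans
            )
            if touches_ir:
                boundary.append(f.gene_name)
    dup = sorted(in_ira & in_irb, key=str.lower)
    dup_low = {d.lower() for d in dup}
    for f, placed in placement:
        if placed and f.gene_name.lower() in dup_low:
            f.is_ir_copy = True
    return dup, sorted(set(boundary), key=str.lower)


def gene_counts(record: PlastomeRecord, convention: str = "all_copies") -> dict:
    """Gene tallies per feature class under an explicit duplication convention.

    ``all_copies`` counts every annotated feature (IR duplicates twice);
    ``unique`` counts distinct gene names once.
    """
    from collections import Counter

    if convention == "all_copies":
        c = Counter(f.feature_class.value for f in record.features)
    elif convention == "unique":
        seen = {}
        for f in record.features:
            seen.setdefault(f.gene_name.lower(), f.feature_class.value)
        c = Counter(seen.values())
    else:
        raise ValueError(f"unknown convention: {convention}")
    total = sum(c.values())
    return {
        "total": total,
        "protein_coding": c.get("protein_coding", 0),
        "tRNA": c.get("tRNA", 0),
        "rRNA": c.get("rRNA", 0),
    }


def region_table(records: list[PlastomeRecord], min_ir_len: int = 1000):
    """Per-accession region statistics table (one row per accession)."""
    import pandas as pd

    rows = []
    for rec in records:
        part = partition(rec, min_ir_len)
        gc_by_region = part.region_gc(rec.sequence)
        dup, _ = duplicated_in_ir(rec, part)
        counts = gene_counts(rec)
        rows.append(
            {
                "accession": rec.accession_id,
                "genome_bp": len(rec.sequence),
                "lsc_bp": part.lengths["LSC"],
                "ssc_bp": part.lengths["SSC"],
                "ir_bp": part.lengths["IRa"],
                "gc_pct": gc_content(rec.sequence, 2),
                "gc_lsc": round(gc_by_region["LSC"], 2),
                "gc_ssc": round(gc_by_region["SSC"], 2),
                "gc_ir": round(gc_by_region["IRa"], 2),
                "n_genes": counts["total"],
                "n_ir_duplicated": len(dup),
            }
        )
    return pd.DataFrame(rows)
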