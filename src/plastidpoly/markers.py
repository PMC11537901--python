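"""InDel markers: primer binding, in-silico amplification, band grouping.

Carries the five published intron-flanking primer pairs, predicts amplicon
sizes on circular templates (product size measured 5' end of the forward
primer to 5' end of the reverse primer, inclusive of both footprints), and
bins accessions into band groups at a configurable gel resolution. New
exon-anchored pairs can be designed around any polymorphic intron.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import GeneFeature, PlastomeRecord, revcomp
from .introns import cis_intron_intervals


@dataclass(frozen=True)
class PrimerPair:
    marker_name: str
    forward: str
    reverse: str
    target_size_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not (15 <= len(p) <= 30):
                raise ValueError(
                    f"{self.marker_name} {label} primer length {len(p)} "
                    "outside 15-30 nt"
                )
            if set(p) - set("ACGT"):
                raise ValueError(f"{self.marker_name} {label}: non-ACGT base")


#: the published intron-flanking marker set (products ~400 bp on a gel)
PUBLISHED_PRIMERS: list[PrimerPair] = [
    PrimerPair("rpl22", "ATCGTGAAACGTGACATCTG", "GCGGTCCTATGAAGAAACACT", (428, 448)),
    PrimerPair("petB", "TCCAATGGTTCTTACTCAGGGA", "ACGGCTCAAACAGAAACACC", (399, 410)),
    PrimerPair("clpP", "ACTATGATGGCTCCGTTGCT", "ACGTCTAGCATTCCCTCACG", (390, 403)),
    PrimerPair("ndhA", "GTAGGATGGATAACTATCGGC", "GTACTCCCCATGACACGATT", (486, 514)),
    PrimerPair("rps16", "CGTACGGCTCGAGAAAATTC", "CACCGAAGTAATGTCTAAACCCA", (368, 411)),
]


@dataclass(frozen=True)
class BindingSite:
    """Primer annealing site: start of the footprint on the + strand, 0-based.

    For a '-' site the primer anneals to the + strand's reverse complement;
    its 5' end sits at ``start + len(primer) - 1`` on the + strand.
    """

    start: int
    strand: str  # '+' or '-'


def find_binding_sites(
    sequence: str,
    primer: str,
    max_mismatch: int = 0,
    three_prime_exact: int = 3,
    circular: bool = True,
) -> list[BindingSite]:
    """All annealing positions of a primer on both strands.

    Hamming mismatches up to ``max_mismatch`` are tolerated except in the
    last ``three_prime_exact`` 3'-terminal bases, which must match exactly.
    Circular templates are searched across the origin. Sites are sorted by
    (start, strand).
    """
    primer = primer.upper()
    if len(primer) < 15:
        raise ValueError("primer shorter than 15 nt")
    sequence = sequence.upper()
    n = len(sequence)
    m = len(primer)
    template = sequence + sequence[: m - 1] if circular else sequence
    sites: list[BindingSite] = []
    if max_mismatch == 0:
        # exact annealing: delegate the scan to substring search
        for strand in "+-":
            probe = primer if strand == "+" else revcomp(primer)
            start = template.find(probe)
            while start != -1 and start < n:
                sites.append(BindingSite(start, strand))
                start = template.find(probe, start + 1)
        sites.sort(key=lambda s: (s.start, s.strand))
        return sites
    for strand in "+-":
        probe = primer if strand == "+" else revcomp(primer)
        # on '-', the primer 3' end corresponds to the START of the + window
        if strand == "+":
            exact_idx = range(m - three_prime_exact, m)
        else:
            exact_idx = range(0, three_prime_exact)
        for i in range(n):
            window = template[i : i + m]
            if len(window) < m:
                break
            mm = 0
            ok = True
            for k in range(m):
                if window[k] != probe[k]:
                    if k in exact_idx:
                        ok = False
                        break
                    mm += 1
                    if mm > max_mismatch:
                        ok = False
                        break
            if ok:
                sites.append(BindingSite(i, strand))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def find_binding_sites_bruteforce(
    sequence: str, primer: str, max_mismatch: int = 0, three_prime_exact: int = 3
) -> list[BindingSite]:
    """Position-by-position oracle over the circle; for verification."""
    primer = primer.upper()
    sequence = sequence.upper()
    n, m = len(sequence), len(primer)
    sites = []
    for strand in "+-":
        for i in range(n):
            window = "".join(sequence[(i + k) % n] for k in range(m))
            target = window if strand == "+" else revcomp(window)
            # compare primer 5'->3' against its annealing target
            mism = [a != b for a, b in zip(primer, target)]
            if any(mism[-three_prime_exact:]):
                continue
            if sum(mism) <= max_mismatch:
                sites.append(BindingSite(i, strand))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


@dataclass
class AmpliconPrediction:
    accession: str
    marker_name: str
    product_size_bp: int | None
    forward_site: BindingSite | None = None
    reverse_site: BindingSite | None = None
    ambiguous: bool = False


def predict_amplicon(
    record: PlastomeRecord,
    pair: PrimerPair,
    max_product: int = 5000,
    max_mismatch: int = 0,
) -> AmpliconPrediction:
    """Smallest convergent forward/reverse product within ``max_product``.

    Product size runs from the forward primer's 5' end to the reverse
    primer's 5' end along the amplified strand (circular-aware). Equal-size
    alternatives set the ``ambiguous`` flag.
    """
    seq = record.sequence
    n = len(seq)
    f_sites = find_binding_sites(seq, pair.forward, max_mismatch,
                                 circular=record.is_circular)
    r_sites = find_binding_sites(seq, pair.reverse, max_mismatch,
                                 circular=record.is_circular)
    best: list[tuple[int, BindingSite, BindingSite]] = []
    lf, lr = len(pair.forward), len(pair.reverse)
    for fs in f_sites:
        for rs in r_sites:
            if fs.strand == "+" and rs.strand == "-":
                start5 = fs.start
                end5 = rs.start + lr - 1  # reverse primer 5' end on + strand
                size = (end5 - start5) % n + 1
            elif fs.strand == "-" and rs.strand == "+":
                start5 = rs.start
                end5 = fs.start + lf - 1
                size = (end5 - start5) % n + 1
            else:
                continue
            if size >= lf + lr and size <= max_product:
                best.append((size, fs, rs))
    if not best:
        return AmpliconPrediction(record.accession_id, pair.marker_name, None)
    best.sort(key=lambda t: (t[0], t[1].start, t[2].start))
    size, fs, rs = best[0]
    ambiguous = len(best) > 1 and best[1][0] == size
    return AmpliconPrediction(
        record.accession_id, pair.marker_name, size, fs, rs, ambiguous
    )


@dataclass
class BandGroupTable:
    """Per-marker product sizes and the derived band-pattern grouping."""

    sizes: dict[str, dict[str, int | None]]  # marker -> accession -> size
    resolution_bp: int
    groups: dict[str, list[list[str]]] = field(default_factory=dict)
    joint_groups: list[list[str]] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        markers = sorted(self.sizes)
        accs = sorted({a for m in self.sizes.values() for a in m})
        return pd.DataFrame(
            {m: [self.sizes[m].get(a) for a in accs] for m in markers},
            index=accs,
        )


def band_groups(
    predictions: list[AmpliconPrediction], size_resolution_bp: int = 1
) -> BandGroupTable:
    """Bin accessions by rounded product size, per marker and jointly.

    ``size_resolution_bp`` ~10 emulates agarose-gel resolution; accessions
    with no product form their own null-band class.
    """
    sizes: dict[str, dict[str, int | None]] = {}
    for p in predictions:
        sizes.setdefault(p.marker_name, {})[p.accession] = p.product_size_bp

    def binned(size: int | None):
        if size is None:
            return None
        return round(size / size_resolution_bp)

    table = BandGroupTable(sizes=sizes, resolution_bp=size_resolution_bp)
    accessions = sorted({a for m in sizes.values() for a in m})
    joint: dict[tuple, list[str]] = {}
    for marker, per_acc in sizes.items():
        classes: dict[object, list[str]] = {}
        for acc in sorted(per_acc):
            classes.setdefault(binned(per_acc[acc]), []).append(acc)
        table.groups[marker] = sorted(classes.values(), key=lambda g: g[0])
    for acc in accessions:
        key = tuple(binned(sizes[m].get(acc)) for m in sorted(sizes))
        joint.setdefault(key, []).append(acc)
    table.joint_groups = sorted(joint.values(), key=lambda g: g[0])
    return table


# ---------------------------------------------------------------------------
# primer design

def primer_tm(primer: str) -> float:
    """Wallace rule: 2(A+T) + 4(G+C). Deterministic, for design filters only."""
    at = primer.count("A") + primer.count("T")
    gc = primer.count("G") + primer.count("C")
    return 2.0 * at + 4.0 * gc


@dataclass(frozen=True)
class DesignConstraints:
    product_target: int = 400
    primer_len: tuple[int, int] = (18, 23)
    gc_range: tuple[float, float] = (40.0, 60.0)
    tm_range: tuple[float, float] = (50.0, 66.0)


class PrimerDesignError(ValueError):
    """No feasible pair; the message reports which constraint failed."""


def _candidates(exon_seq: str, cons: DesignConstraints):
    """(offset, primer) candidates within one exon, 5'->3' on the exon."""
    lo, hi = cons.primer_len
    out = []
    for length in range(lo, hi + 1):
        for off in range(0, len(exon_seq) - length + 1):
            p = exon_seq[off : off + length]
            gc = 100.0 * (p.count("G") + p.count("C")) / length
            if not (cons.gc_range[0] <= gc <= cons.gc_range[1]):
                continue
            tm = primer_tm(p)
            if not (cons.tm_range[0] <= tm <= cons.tm_range[1]):
                continue
            out.append((off, p))
    return out


def design_primer_candidates(
    record: PlastomeRecord,
    gene: str,
    constraints: DesignConstraints | None = None,
    intron_index: int = 1,
    limit: int | None = None,
) -> list[PrimerPair]:
    """Ranked exon-anchored candidate pairs flanking a gene's cis intron.

    The forward primer lies in the exon upstream of the intron, the reverse
    primer (reverse-complemented) in the downstream exon; the product spans
    the intron. Ranking is deterministic: smaller |product - target| first,
    then leftmost forward footprint, then leftmost reverse.
    """
    cons = constraints or DesignConstraints()
    feats = record.genes(gene)
    if not feats:
        raise PrimerDesignError(f"no such gene: {gene}")
    feat = feats[0]
    if len(feat.exon_spans) < 2:
        raise PrimerDesignError(f"{gene}: gene has no intron")
    intervals = cis_intron_intervals(feat, len(record.sequence))
    if intron_index > len(intervals):
        raise PrimerDesignError(f"{gene}: no cis intron #{intron_index}")
    intron_len = intervals[intron_index - 1][1]
    # exons flanking the intron_index-th cis junction, read in gene orientation
    from .introns import junction_gaps

    gaps = junction_gaps(feat, len(record.sequence))
    cis_positions = [k for k, (_, _, is_cis) in enumerate(gaps) if is_cis]
    k = cis_positions[intron_index - 1]
    up = _exon_seq(record, feat, k)
    down = _exon_seq(record, feat, k + 1)
    fwd_cands = _candidates(up, cons)
    rev_cands = _candidates(revcomp(down), cons)
    if not fwd_cands or not rev_cands:
        side = "forward exon" if not fwd_cands else "reverse exon"
        raise PrimerDesignError(
            f"{gene}: no primer in the {side} satisfies length "
            f"{cons.primer_len}, GC {cons.gc_range}, Tm {cons.tm_range}"
        )
    ranked = []
    for foff, fp in fwd_cands:
        # product: rest of upstream exon after forward 5' + intron + distance
        # from downstream-exon start to the reverse primer 5' end
        up_part = len(up) - foff
        for roff, rp in rev_cands:
            down_part = len(down) - roff
            product = up_part + intron_len + down_part
            ranked.append(
                ((abs(product - cons.product_target), foff, roff), fp, rp, product)
            )
    ranked.sort(key=lambda t: t[0])
    if limit is not None:
        ranked = ranked[:limit]
    return [
        PrimerPair(
            marker_name=gene,
            forward=fp,
            reverse=rp,
            target_size_range=(product, product),
        )
        for _, fp, rp, product in ranked
    ]


def design_primer_pair(
    record: PlastomeRecord,
    gene: str,
    constraints: DesignConstraints | None = None,
    intron_index: int = 1,
) -> PrimerPair:
    """Best exon-anchored pair flanking a gene's cis intron (see
    design_primer_candidates for the ranking)."""
    return design_primer_candidates(
        record, gene, constraints, intron_index, limit=1
    )[0]


def _exon_seq(record: PlastomeRecord, feat: GeneFeature, exon_index: int) -> str:
    """One exon's sequence in gene orientation (index into the 5'->3' list)."""
    from .records import span_extract

    span = feat.exon_spans[exon_index]
    strand = feat.exon_strands[exon_index]
    seq = span_extract(span, record.sequence)
    return revcomp(seq) if strand == "-" else seq
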