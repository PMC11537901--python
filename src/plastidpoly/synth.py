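"""Synthetic quadripartite plastomes with a ground-truth manifest.

The generator emits small circular genomes shaped like real plastomes — an
exact inverted-repeat pair, region-dependent GC, annotated genes with cis
introns, an IR-duplicated gene and a trans-spliced two-locus gene — at a toy
scale where the quadratic verification oracles run in seconds. Derived
accessions differ from the base genome only by planted, logged edits
(intron InDels, intergenic InDels, coding substitutions), so every
downstream screen has an exact expected answer.

All randomness flows from one explicit seed through numpy's counter-based
Philox generator: the same seed yields the same bytes on any platform.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .records import FeatureClass, GeneFeature, PlastomeRecord, revcomp


class InfeasibleSpecError(ValueError):
    """The synthetic layout cannot be realized; message lists violations."""


@dataclass
class GenePlan:
    """Where and how one gene is planted.

    ``offset`` is relative to the start of its region (for IR genes, within
    IRa; the IRb copy is derived automatically). ``trans_locus`` optionally
    places a 5' exon at a second locus: (region, offset, strand, exon_bp).
    """

    name: str
    feature_class: FeatureClass
    region: str  # 'LSC' | 'SSC' | 'IR'
    offset: int
    exons: list[int]
    introns: list[int] = field(default_factory=list)
    strand: str = "+"
    trans_locus: tuple[str, int, str, int] | None = None

    @property
    def footprint(self) -> int:
        return sum(self.exons) + sum(self.introns)

    def __post_init__(self) -> None:
        if len(self.introns) != len(self.exons) - 1:
            raise InfeasibleSpecError(
                f"{self.name}: need len(exons)-1 introns, got {len(self.introns)}"
            )


@dataclass
class SyntheticSpec:
    genome_bp: int
    lsc_bp: int
    ssc_bp: int
    ir_bp: int
    gc_lsc: float = 34.0
    gc_ssc: float = 30.0
    gc_ir: float = 43.0
    #: coding exons are GC-richer than the intergenic background
    gc_exon: float = 44.0
    genes: list[GenePlan] = field(default_factory=list)

    def validate(self) -> None:
        problems = []
        if self.lsc_bp + self.ssc_bp + 2 * self.ir_bp != self.genome_bp:
            problems.append("lsc + ssc + 2*ir must equal genome_bp")
        if self.lsc_bp <= self.ssc_bp:
            problems.append("lsc_bp must exceed ssc_bp")
        region_len = {"LSC": self.lsc_bp, "SSC": self.ssc_bp, "IR": self.ir_bp}
        used: dict[str, list[tuple[int, int, str]]] = {r: [] for r in region_len}
        for g in self.genes:
            loci = [(g.region, g.offset, g.footprint, g.name)]
            if g.trans_locus:
                tr, toff, _, tlen = g.trans_locus
                loci.append((tr, toff, tlen, g.name + "/trans"))
            for region, off, size, label in loci:
                if region not in region_len:
                    problems.append(f"{label}: unknown region {region}")
                    continue
                if off < 2 or off + size > region_len[region] - 2:
                    problems.append(
                        f"{label}: [{off},{off + size}) does not fit in "
                        f"{region} ({region_len[region]} bp)"
                    )
                used[region].append((off, off + size, label))
        for region, spans in used.items():
            spans.sort()
            for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
                if s2 < e1:
                    problems.append(f"{region}: {n1} overlaps {n2}")
        if problems:
            raise InfeasibleSpecError("; ".join(problems))

    def region_start(self, region: str) -> int:
        return {
            "LSC": 0,
            "IRa": self.lsc_bp,
            "IR": self.lsc_bp,
            "SSC": self.lsc_bp + self.ir_bp,
            "IRb": self.lsc_bp + self.ir_bp + self.ssc_bp,
        }[region]


def default_spec() -> SyntheticSpec:
    """The study-like toy genome: 15.6 kb, LSC/IRa/SSC/IRb, real intron sizes.

    Intron lengths mirror the polymorphism screen's genes (rpl22 111,
    rps16 905, petB 788, clpP 830+624, trnL-UAA 516, ndhB 669, ndhA 1,132,
    rps12 cis 540); region GC targets 34/30/43 reflect plastome composition.
    """
    P, T, R = FeatureClass.PROTEIN_CODING, FeatureClass.TRNA, FeatureClass.RRNA
    genes = [
        GenePlan("psbA", P, "LSC", 40, [420]),
        GenePlan("rps12", P, "LSC", 500, [232, 26], [540], strand="-",
                 trans_locus=("SSC", 20, "-", 114)),
        GenePlan("matK", P, "LSC", 1330, [150]),
        GenePlan("rpl22", P, "LSC", 1520, [90, 120], [111]),
        GenePlan("rps16", P, "LSC", 1900, [40, 230], [880], strand="-"),
        GenePlan("petB", P, "LSC", 3120, [60, 240], [788]),
        GenePlan("trnT-GGU", T, "LSC", 4280, [72]),
        GenePlan("psbD", P, "LSC", 4700, [300]),
        GenePlan("clpP", P, "LSC", 5040, [70, 290, 230], [830, 624], strand="-"),
        GenePlan("trnL-UAA", T, "LSC", 7120, [35, 50], [516]),
        GenePlan("rrn16", R, "IR", 100, [600]),
        GenePlan("ndhB", P, "IR", 800, [150, 140], [669]),
        GenePlan("ndhF", P, "SSC", 850, [350], strand="-"),
        GenePlan("ndhA", P, "SSC", 1250, [170, 160], [1132], strand="-"),
    ]
    return SyntheticSpec(
        genome_bp=15600, lsc_bp=8000, ssc_bp=2800, ir_bp=2400, genes=genes
    )


def pyrus_like_spec() -> SyntheticSpec:
    """A 160 kb-scale variant of the default layout (for scale exercises)."""
    spec = default_spec()
    return SyntheticSpec(
        genome_bp=160_000,
        lsc_bp=88_000,
        ssc_bp=19_200,
        ir_bp=26_400,
        genes=[
            GenePlan(
                g.name, g.feature_class, g.region, g.offset * 10, g.exons,
                g.introns, g.strand,
                None if g.trans_locus is None else (
                    g.trans_locus[0], g.trans_locus[1] * 10,
                    g.trans_locus[2], g.trans_locus[3],
                ),
            )
            for g in spec.genes
        ],
    )


# ---------------------------------------------------------------------------
# edits

@dataclass(frozen=True)
class IntronEdit:
    """InDel centered in a gene's cis intron; delta > 0 inserts, < 0 deletes."""

    gene: str
    delta: int
    intron_index: int = 1


@dataclass(frozen=True)
class IntergenicEdit:
    """InDel in the middle of the largest gene-free gap of a region."""

    region: str  # 'LSC' or 'SSC'
    delta: int


@dataclass(frozen=True)
class SubstitutionEdit:
    """n substitutions at deterministic positions in single-copy coding exons."""

    n: int


Edit = IntronEdit | IntergenicEdit | SubstitutionEdit


@dataclass
class Op:
    """One primitive sequence operation in base-genome coordinates."""

    pos: int
    n_del: int
    insert: str
    note: str = ""

    @property
    def delta(self) -> int:
        return len(self.insert) - self.n_del


@dataclass
class TruthManifest:
    """Ground truth for a generated accession set."""

    spec: SyntheticSpec
    boundaries: dict[str, tuple[int, int]]  # base-genome region windows
    gene_spans: dict[str, list[tuple[int, int]]]  # base exon spans per feature key
    accessions: dict[str, list[Op]] = field(default_factory=dict)

    def replay(self, base_sequence: str, accession: str) -> str:
        """Reapply the logged ops; must reproduce the emitted sequence exactly."""
        seq = base_sequence
        for op in sorted(self.accessions[accession], key=lambda o: -o.pos):
            seq = seq[: op.pos] + op.insert + seq[op.pos + op.n_del :]
        return seq

    def to_json(self) -> str:
        payload = {
            "spec": {
                k: v
                for k, v in asdict(self.spec).items()
            },
            "boundaries": self.boundaries,
            "gene_spans": self.gene_spans,
            "accessions": {
                acc: [asdict(op) for op in ops]
                for acc, ops in self.accessions.items()
            },
        }
        return json.dumps(payload, indent=1, default=str)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=seed, counter=sum(stream)))


def _random_bases(rng: np.random.Generator, n: int, gc_pct: float) -> str:
    p_gc = gc_pct / 100.0
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


def make_base_plastome(
    spec: SyntheticSpec, seed: int, accession_id: str = "BASE"
) -> tuple[PlastomeRecord, TruthManifest]:
    """Generate the base genome: exact IR pair, region GC, planted genes."""
    spec.validate()
    rng = _rng(seed, 0)
    n = spec.genome_bp

    features: list[GeneFeature] = []
    for plan in spec.genes:
        features.extend(_plant_gene(plan, spec))
    features.sort(key=lambda f: min(s for s, _ in f.exon_spans))

    # background GC is compensated per region so that, with the GC-richer
    # exons overwritten on top, each region still meets its GC target
    exon_bp = {"LSC": 0, "SSC": 0, "IR": 0}
    irb_start = spec.lsc_bp + spec.ir_bp + spec.ssc_bp
    for f in features:
        for s, e in f.exon_spans:
            if s >= irb_start:
                continue
            exon_bp[_region_of_pos(s, spec)] += e - s

    def bg(target: float, region_len: int, region: str) -> float:
        ex = exon_bp[region]
        if ex == 0:
            return target
        val = (target * region_len - spec.gc_exon * ex) / (region_len - ex)
        return min(max(val, 5.0), 95.0)

    lsc = _random_bases(rng, spec.lsc_bp, bg(spec.gc_lsc, spec.lsc_bp, "LSC"))
    ira = _random_bases(rng, spec.ir_bp, bg(spec.gc_ir, spec.ir_bp, "IR"))
    ssc = _random_bases(rng, spec.ssc_bp, bg(spec.gc_ssc, spec.ssc_bp, "SSC"))
    seq = list(lsc + ira + ssc + ira)  # IRb placeholder, mirrored below

    # overwrite exon positions with GC-richer coding-like sequence, then
    # derive IRb so IR gene copies stay exact
    for f in features:
        for s, e in f.exon_spans:
            if s >= irb_start:
                continue  # the IRb twin inherits from the mirror
            exon = _random_bases(rng, e - s, spec.gc_exon)
            seq[s:e] = list(exon)
    seq[irb_start:n] = list(revcomp("".join(seq[spec.lsc_bp : spec.lsc_bp + spec.ir_bp])))
    _fix_ir_boundaries(seq, spec, rng)
    record = PlastomeRecord(
        accession_id=accession_id,
        sequence="".join(seq),
        organism="synthetic plastome",
        is_circular=True,
        features=features,
        source_format="genbank",
    )
    record.validate()
    manifest = TruthManifest(
        spec=spec,
        boundaries={
            "LSC": (0, spec.lsc_bp),
            "IRa": (spec.lsc_bp, spec.lsc_bp + spec.ir_bp),
            "SSC": (spec.lsc_bp + spec.ir_bp, spec.lsc_bp + spec.ir_bp + spec.ssc_bp),
            "IRb": (spec.lsc_bp + spec.ir_bp + spec.ssc_bp, n),
        },
        gene_spans={
            _feature_key(f): list(f.exon_spans) for f in features
        },
    )
    manifest.accessions[accession_id] = []
    return record, manifest


def _feature_key(f: GeneFeature) -> str:
    return f"{f.gene_name}@{min(s for s, _ in f.exon_spans)}"


def _fix_ir_boundaries(seq: list[str], spec: SyntheticSpec, rng) -> None:
    """Mutate single-copy bases flanking the IRs so the repeat cannot extend."""
    n = spec.genome_bp
    la = spec.lsc_bp                      # IRa start
    ra = la + spec.ir_bp                  # IRa end (first SSC base)
    lb = ra + spec.ssc_bp                 # IRb start
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    # extension pair 1: base before IRa (last LSC base) vs base after IRb (pos 0)
    while seq[la - 1] == comp[seq[0]]:
        seq[0] = "ACGT"[rng.integers(4)]
    # extension pair 2: base after IRa (first SSC base) vs base before IRb
    while seq[ra] == comp[seq[lb - 1]]:
        seq[ra] = "ACGT"[rng.integers(4)]


def _plant_gene(plan: GenePlan, spec: SyntheticSpec) -> list[GeneFeature]:
    """Compute exon spans for a plan; returns 1 feature, or 2 for IR genes."""
    start = spec.region_start(plan.region) + plan.offset
    # exons/introns are given 5'->3' in gene order; minus-strand genes are
    # laid down reversed on the genome
    exons = plan.exons if plan.strand == "+" else plan.exons[::-1]
    intrs = plan.introns if plan.strand == "+" else plan.introns[::-1]
    spans_genomic: list[tuple[int, int]] = []
    pos = start
    for i, ex in enumerate(exons):
        spans_genomic.append((pos, pos + ex))
        pos += ex
        if i < len(intrs):
            pos += intrs[i]
    # 5'->3' order: minus-strand genes read highest genomic span first
    spans = spans_genomic if plan.strand == "+" else spans_genomic[::-1]
    strands = [plan.strand] * len(spans)
    trans = False
    if plan.trans_locus is not None:
        tr, toff, tstrand, tlen = plan.trans_locus
        tstart = spec.region_start(tr) + toff
        spans = [(tstart, tstart + tlen)] + spans
        strands = [tstrand] + strands
        trans = True
    feat = GeneFeature(
        gene_name=plan.name,
        feature_class=plan.feature_class,
        strand=strands[-1] if trans else plan.strand,
        exon_spans=spans,
        is_trans_spliced=trans,
        exon_strands=strands,
    )
    if plan.region != "IR":
        return [feat]
    # mirror the IRa copy into IRb on the opposite strand
    mirrored = [
        (_mirror(e, spec), _mirror(s, spec)) for s, e in spans
    ]
    flipped = ["-" if s == "+" else "+" for s in strands]
    twin = GeneFeature(
        gene_name=plan.name,
        feature_class=plan.feature_class,
        strand=flipped[0],
        exon_spans=mirrored,
        is_trans_spliced=trans,
        exon_strands=flipped,
    )
    return [feat, twin]


def _mirror(pos: int, spec: SyntheticSpec) -> int:
    """Map a coordinate inside IRa to its reverse-complement twin in IRb.

    Maps half-open boundaries consistently: IRa start <-> IRb end.
    """
    la = spec.lsc_bp
    lb = la + spec.ir_bp + spec.ssc_bp
    return lb + (la + spec.ir_bp - pos)


# ---------------------------------------------------------------------------
# derived accessions

def derive_accession(
    base: PlastomeRecord,
    manifest: TruthManifest,
    edits: list[Edit],
    accession_id: str,
    seed: int,
) -> PlastomeRecord:
    """Apply planted edits to the base genome, shifting annotation consistently.

    Edits inside an IR are co-applied to the twin copy so the repeat stays
    exact. The op log is appended to the manifest under ``accession_id``.
    """
    spec = manifest.spec
    rng = _rng(seed, 1)
    ops: list[Op] = []
    for edit in edits:
        if isinstance(edit, IntronEdit):
            ops.extend(_intron_ops(base, spec, edit, rng))
        elif isinstance(edit, IntergenicEdit):
            ops.append(_intergenic_op(base, spec, edit, rng))
        elif isinstance(edit, SubstitutionEdit):
            ops.extend(_substitution_ops(base, spec, edit, rng))
        else:  # pragma: no cover
            raise TypeError(f"unknown edit type: {edit!r}")
    _check_disjoint(ops)
    seq, features = _apply_ops(base, ops)
    rec = PlastomeRecord(
        accession_id=accession_id,
        sequence=seq,
        organism=base.organism,
        is_circular=True,
        features=features,
        source_format="genbank",
    )
    rec.validate()
    manifest.accessions[accession_id] = ops
    return rec


def _cis_intron_interval(
    feat: GeneFeature, index: int, genome_length: int
) -> tuple[int, int]:
    """Genomic (start, end) of the index-th cis intron (1-based, gene order)."""
    from .introns import cis_intron_intervals

    intervals = cis_intron_intervals(feat, genome_length)
    if index < 1 or index > len(intervals):
        raise ValueError(f"{feat.gene_name}: no cis intron #{index}")
    lo, gap = intervals[index - 1]
    return lo, lo + gap


def _intron_ops(base, spec, edit: IntronEdit, rng) -> list[Op]:
    feats = base.genes(edit.gene)
    if not feats:
        raise ValueError(f"no such gene: {edit.gene}")
    n = len(base.sequence)
    ops = []
    primary = feats[0]
    lo, hi = _cis_intron_interval(primary, edit.intron_index, n)
    ilen = hi - lo
    if edit.delta < 0 and -edit.delta >= ilen:
        raise ValueError(
            f"{edit.gene}: cannot delete {-edit.delta} bp from a {ilen} bp intron"
        )
    if edit.delta < 0:
        ndel, ins = -edit.delta, ""
        pos = lo + (ilen - ndel) // 2
    else:
        ndel = 0
        region = _region_of_pos(lo, spec)
        gc = {"LSC": spec.gc_lsc, "SSC": spec.gc_ssc, "IR": spec.gc_ir}[region]
        ins = _random_bases(rng, edit.delta, gc)
        pos = lo + ilen // 2
    ops.append(Op(pos, ndel, ins, f"intron {edit.gene}#{edit.intron_index}"))
    if _region_of_pos(pos, spec) == "IR":
        # co-edit the twin copy to keep the inverted repeat exact
        if ndel:
            mpos = _mirror(pos + ndel, spec)
            ops.append(Op(mpos, ndel, "", f"IR twin of {edit.gene}"))
        else:
            mpos = _mirror(pos, spec)
            ops.append(Op(mpos, 0, revcomp(ins), f"IR twin of {edit.gene}"))
    return ops


def _intergenic_op(base, spec, edit: IntergenicEdit, rng) -> Op:
    if edit.region not in ("LSC", "SSC"):
        raise ValueError("intergenic edits are supported in LSC/SSC only")
    rs = spec.region_start(edit.region)
    rlen = spec.lsc_bp if edit.region == "LSC" else spec.ssc_bp
    # gene-free gaps within the region; a locus occupies exons AND cis introns
    from .introns import locus_footprints

    occupied = sorted(
        (s, e)
        for f in base.features
        for s, e in locus_footprints(f, len(base.sequence))
        if rs <= s < rs + rlen
    )
    gaps = []
    prev = rs + 2
    for s, e in occupied:
        if s > prev:
            gaps.append((prev, s))
        prev = max(prev, e)
    if rs + rlen - 2 > prev:
        gaps.append((prev, rs + rlen - 2))
    lo, hi = max(gaps, key=lambda g: g[1] - g[0])
    mid = (lo + hi) // 2
    if edit.delta < 0:
        ndel = -edit.delta
        if ndel >= hi - lo:
            raise ValueError(f"{edit.region}: gap too small for {ndel} bp deletion")
        return Op(mid - ndel // 2, ndel, "", f"intergenic {edit.region}")
    gc = {"LSC": spec.gc_lsc, "SSC": spec.gc_ssc}[edit.region]
    return Op(mid, 0, _random_bases(rng, edit.delta, gc), f"intergenic {edit.region}")


def _substitution_ops(base, spec, edit: SubstitutionEdit, rng) -> list[Op]:
    candidates: list[int] = []
    for f in base.features:
        if f.feature_class is not FeatureClass.PROTEIN_CODING:
            continue
        if any(_region_of_pos(s, spec) == "IR" for s, _ in f.exon_spans):
            continue
        for s, e in f.exon_spans:
            candidates.extend(range(s, e))
    if edit.n > len(candidates):
        raise ValueError("not enough single-copy coding positions")
    chosen = rng.choice(len(candidates), size=edit.n, replace=False)
    ops = []
    for idx in sorted(int(i) for i in chosen):
        pos = candidates[idx]
        old = base.sequence[pos]
        alt = "ACGT".replace(old, "")
        new = alt[rng.integers(3)]
        ops.append(Op(pos, 1, new, "substitution"))
    return ops


def _region_of_pos(pos: int, spec: SyntheticSpec) -> str:
    if pos < spec.lsc_bp:
        return "LSC"
    if pos < spec.lsc_bp + spec.ir_bp:
        return "IR"
    if pos < spec.lsc_bp + spec.ir_bp + spec.ssc_bp:
        return "SSC"
    return "IR"


def _check_disjoint(ops: list[Op]) -> None:
    spans = sorted((op.pos, op.pos + max(op.n_del, 1)) for op in ops)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("planted edits overlap; choose different loci")


def _apply_ops(base: PlastomeRecord, ops: list[Op]):
    seq = base.sequence
    for op in sorted(ops, key=lambda o: -o.pos):
        seq = seq[: op.pos] + op.insert + seq[op.pos + op.n_del :]
    features = []
    for f in base.features:
        g = f.copy()
        g.exon_spans = [
            (_shift(s, ops), _shift(e, ops)) for s, e in f.exon_spans
        ]
        g.is_ir_copy = False
        features.append(g)
    return seq, features


def _shift(coord: int, ops: list[Op]) -> int:
    out = coord
    for op in ops:
        if op.n_del > 1 and op.pos < coord < op.pos + op.n_del:
            raise ValueError("edit overlaps an annotated feature boundary")
        if coord > op.pos:
            out += op.delta
    return out


# ---------------------------------------------------------------------------
# accession panels

@dataclass
class GroupDesign:
    """A named group of accessions sharing one planted edit set."""

    name: str
    n_members: int
    edits: list[Edit] = field(default_factory=list)
    diagnostic_substitutions: int = 0


def make_accession_panel(
    groups: list[GroupDesign],
    seed: int,
    spec: SyntheticSpec | None = None,
    private_substitutions: int = 0,
) -> tuple[list[PlastomeRecord], TruthManifest]:
    """Panel of accessions in designed groups.

    Members of a group share the group's edits (hence identical intron-length
    vectors); ``diagnostic_substitutions`` adds group-specific coding
    substitutions, ``private_substitutions`` adds per-accession ones.
    """
    spec = spec or default_spec()
    base, manifest = make_base_plastome(spec, seed)
    records: list[PlastomeRecord] = []
    for gi, group in enumerate(groups):
        group_edits = list(group.edits)
        if group.diagnostic_substitutions:
            group_edits.append(SubstitutionEdit(group.diagnostic_substitutions))
        for m in range(group.n_members):
            acc = f"{group.name}{m + 1}"
            # group edits keyed by group seed; private ones by member seed
            rec = _derive_with_mixed_seeds(
                base, manifest, group_edits, acc,
                group_seed=(seed + 101 * (gi + 1)) % (2**31),
                member_seed=(seed + 101 * (gi + 1) + 7919 * (m + 1)) % (2**31),
                private=private_substitutions,
            )
            records.append(rec)
    return records, manifest


def _derive_with_mixed_seeds(
    base, manifest, group_edits, acc, group_seed, member_seed, private
):
    # group-shared ops from the group seed, so members match byte-for-byte
    rng_group = _rng(group_seed, 1)
    spec = manifest.spec
    ops: list[Op] = []
    for edit in group_edits:
        if isinstance(edit, IntronEdit):
            ops.extend(_intron_ops(base, spec, edit, rng_group))
        elif isinstance(edit, IntergenicEdit):
            ops.append(_intergenic_op(base, spec, edit, rng_group))
        elif isinstance(edit, SubstitutionEdit):
            ops.extend(_substitution_ops(base, spec, edit, rng_group))
    if private:
        rng_member = _rng(member_seed, 2)
        for _ in range(16):  # retry draws that collide with existing ops
            cand = _substitution_ops(base, spec, SubstitutionEdit(private), rng_member)
            try:
                _check_disjoint(ops + cand)
                ops.extend(cand)
                break
            except ValueError:
                continue
        else:  # pragma: no cover
            raise ValueError("could not place private substitutions")
    _check_disjoint(ops)
    seq, features = _apply_ops(base, ops)
    rec = PlastomeRecord(
        accession_id=acc,
        sequence=seq,
        organism=base.organism,
        is_circular=True,
        features=features,
        source_format="genbank",
    )
    rec.validate()
    manifest.accessions[acc] = ops
    return rec


def two_group_panel(seed: int) -> tuple[list[PlastomeRecord], TruthManifest]:
    """The study-shaped default panel: two maternal groups of three.

    Group B differs from group A by the screen's stated InDel sizes
    (rpl22 -20, petB +10, clpP intron 2 +10, ndhA +24, rps16 +25), a 22-bp
    intergenic deletion in LSC and a 5-bp one in SSC, plus 50 diagnostic
    coding substitutions; members carry 2 private substitutions each.
    """
    groups = [
        GroupDesign("A", 3),
        GroupDesign(
            "B",
            3,
            edits=[
                IntronEdit("rpl22", -20),
                IntronEdit("petB", +10),
                IntronEdit("clpP", +10, intron_index=2),
                IntronEdit("ndhA", +24),
                IntronEdit("rps16", +25),
                IntergenicEdit("LSC", -22),
                IntergenicEdit("SSC", -5),
            ],
            diagnostic_substitutions=50,
        ),
    ]
    return make_accession_panel(groups, seed, private_substitutions=2)
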