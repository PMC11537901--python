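# Methods

This note documents the models, conventions and numerical choices behind
plastidpoly, and what the synthetic test bed does and does not establish.

## Coordinate model

All internal coordinates are 0-based half-open; GenBank's 1-based inclusive
convention is converted only at the I/O boundary. Windows and exon spans on
a circular genome may wrap the origin (`end < start`), and every length,
extraction and gap computation is circular-aware. Exon lists are ordered
5′→3′ in gene orientation, so a minus-strand gene lists its highest-
coordinate exon first; an exon written in GenBank as two parts abutting
across the origin is fused into one wrapped span rather than read as a
zero-length intron. When both a `gene` and a `CDS`/`tRNA`/`rRNA` feature
annotate one locus, exon structure is taken from the spliced feature. Gene
identity is the annotated name verbatim (lowercased for matching, anticodon
suffixes kept); synonyms are never remapped. Ambiguity codes other than N
are rejected at parse time because GC accounting and exact primer matching
need a closed alphabet.

## Inverted-repeat detection and partition

An inverted-repeat pair (i, j, L) satisfies
`seq[j:j+L] == revcomp(seq[i:i+L])` on the circle. The detector indexes
k-mers (k = min(16, min_ir_len)) of the genome, looks up k-mers of the
reverse complement, and extends each seed to a maximal run; maximality is
taken under the constraint that the two copies remain disjoint, so a
self-reverse-complementary stretch yields a hit whose copies are its two
halves. Only exact repeats are reported (no mismatch tolerance): plastome
IRs are exact in assembled records, and exactness keeps the detector
verifiable against an independent O(n²) oracle that scans every diagonal of
the sequence against its reverse complement (`find_inverted_repeats_bruteforce`).

The longest hit defines IRa/IRb (default `min_ir_len` 1,000 bp; real
plastome IRs are ~26 kb). The two inter-IR arcs become LSC (longer) and SSC
(shorter); an equal-length tie goes to the arc with more annotated genes,
then to the arc with lower GC. Region lengths follow the exact repeat
extent, which may differ by a few bases from lengths derived from a
submitter's annotation; this is the documented caveat for comparisons with
published region tables. Canonical linearization rotates the genome so LSC
starts at 0 with order LSC–IRa–SSC–IRb, making coordinates comparable
across accessions. GC content is 100·(G+C)/(A+C+G+T) with N excluded from
the denominator.

Gene tallies are reported under an explicit duplication convention
(`all_copies` counts each annotated feature, IR twins twice; `unique`
counts names once) because published totals mix conventions — e.g. counting
8 rRNA genes (4 species × 2 IR copies) inside a "functional genes" total.

## Intron catalog and the variance screen

A cis intron's length is the genomic gap between consecutive exons in gene
orientation, computed purely from annotation coordinates — never by
re-alignment — so the screen is exactly reproducible from deposited
records. On trans-spliced features, junctions whose exons sit on different
strands, or whose gap exceeds 4,000 bp (`MAX_CIS_INTRON_BP`; the largest
real plastid intron, in trnK-UUU, is ~2.5 kb), are classified trans and
skipped: plastid *rps12* therefore contributes one cis intron. Two-intron
genes (*clpP*, *ycf3*) are keyed (gene, intron index) with the index in
gene orientation. IR-duplicated introns are collapsed to one row after an
equality check between the copies; disagreement raises an error rather than
averaging. Region labels come from the partition region containing the
intron midpoint. The polymorphism statistic is the table convention
max − min (bp) across accessions ("length variance"); note that some prose
summaries of the same data quote different per-gene figures than their own
table (e.g. 43 vs 25 bp for *rps16*) — the table's max − min definition is
implemented, and the discrepancy is only noted here. The default screening
threshold is 10 bp, the level at which all five published marker genes are
recovered on the deposited set.

## In-silico PCR and marker design

Binding sites allow Hamming mismatches up to `max_mismatch` (default 0 —
the published markers were designed on these very genomes, and exactness
keeps product sizes integer-verifiable) with the last 3 bases of the 3′ end
always exact; circular templates are searched across the origin. Product
size runs from the forward primer's 5′ end to the reverse primer's 5′ end
inclusive, matching gel expectations. The smallest convergent product under
`max_product` (5,000 bp) wins; equal-size alternatives set an ambiguity
flag. Band groups bin product sizes at a resolution (1 bp for exact work,
~10 bp to emulate agarose gels) per marker and jointly.

Designed pairs are exon-anchored: forward in the exon upstream of the
target intron, reverse (reverse-complemented) in the downstream exon, so
the product spans the intron and size differences equal intron-length
differences exactly. Constraints: primer length 18–23 nt, GC 40–60%, Tm by
the Wallace rule 2(A+T)+4(G+C) in 50–66 °C — deliberately thermodynamics-
free and deterministic. Ranking is smaller |product − target| first, then
leftmost forward, then leftmost reverse. The pipeline walks the ranked
candidates and keeps the first pair that amplifies cleanly in every input
accession, since a polymorphic exon position can silently break a single
accession's binding site under the exact-match policy.

## Divergence scan

Queries are aligned to the reference after both are canonically rotated.
The aligner chains maximal unique exact matches (k = 20 seeds, extended,
colinearly chained by total length) and closes inter-anchor segments with
an affine-gap Gotoh fill: match +1, mismatch −1, gap open −4, gap extend
−1. The published analysis delegated alignment to an external
visualization suite; fixing this scheme instead makes the scan reproducible
and lets the anchored path be checked against a full dynamic-programming
oracle (same score, same gap placement) on small fixtures. Because optimal
alignments are unique only up to gap sliding, every alignment is
canonicalized by shifting each gap run as far left as the score allows;
InDel positions are therefore reported at their leftmost equivalent
placement. Anchor coverage below 50% of the reference raises a
"too divergent" error.

Windowed identity (default 100 bp window, 25 bp step, mirroring a 50–100%
identity display) is matches / columns assigned to the window × 100, gaps
counting as mismatches and insertion columns assigned to the preceding
reference base. Divergent regions are maximal runs of windows below the
threshold (default 90%), merged across accessions and labeled with
overlapping or flanking reference genes; IR-duplicated divergence is seen
once per copy and not deduplicated further.

## Phylogeny

The concatenated matrix uses the protein-coding genes shared by every
accession, IR duplicates collapsed to the first copy, in alphabetical order
(topology is order-invariant; the order fixes determinism). `cds` mode
joins spliced coding sequences; `cds_plus_intron` joins unspliced gene
footprints, which excludes trans-spliced genes (*rps12*) since they have no
contiguous footprint. Equal-length gene sets are used positionally;
unequal-length sets are star-aligned against the first accession with the
divergence-scan scoring. Distances are computed over non-gap shared
columns: p-distance, JC69 (−¾ ln(1 − 4p/3), undefined at p ≥ 0.75) and K2P
(−½ ln((1 − 2P − Q)√(1 − 2Q))).

Tree building is canonical neighbor joining with lexicographic tie-breaking
on the joined pair; negative branch lengths are clamped to zero with the
remainder shifted to the sibling edge. Bootstrap resamples alignment
columns with replacement, rebuilds the tree per replicate, and maps
internal-edge bipartition frequencies onto the full-data tree; replicates
saturating a log-distance are skipped and count against support. The
distance+NJ+bootstrap route deliberately replaces full likelihood
inference: the quantity the analysis rests on is cluster concordance
(which accessions share a maternal plastome lineage), for which distances
on near-identical genomes are exact, and the NJ implementation is checked
against an independent library and against additive matrices where NJ
provably recovers the generating tree. Caveat: among accessions with zero
signal (identical rows), NJ's deterministic tie-breaking resolves the star
arbitrarily and the bootstrap then reproduces the same arbitrary
resolution, so short edges inside a clonal group can show nontrivial
support; only edges with positive length carry information.

## Synthetic plastomes

The generator is the package's test bed and defines its study conditions.
The default genome is a 15.6 kb quadripartite circle (LSC 8,000 / IRa 2,400
/ SSC 2,800 / IRb 2,400) — small enough that the quadratic oracles run in
seconds — with region GC targets 34/30/43% (coding exons generated at 44%
with the intergenic background compensated so regions still meet their
targets), an exact IR pair whose boundaries are locked against accidental
single-base extension, and 14 genes carrying the real screen's intron
lengths: *rpl22* 111, *rps16* 880, *petB* 788, *clpP* 830+624, *trnL-UAA*
516, *ndhA* 1,132, the IR-duplicated *ndhB* 669, and a trans-spliced
*rps12* with a 540 bp cis intron and a 5′ exon on another region. A
"pyrus-like" 160 kb preset exists for scale exercises.

Derived accessions apply logged edits — intron InDels centered in the
intron, intergenic InDels in the largest gene-free gap, substitutions at
single-copy coding positions — with annotation coordinates shifted
consistently and IR edits mirrored into the twin copy to preserve repeat
exactness. The manifest replays every accession byte-exactly. The default
two-group panel mirrors the published group structure: group B differs from
group A by the stated InDel sizes (rpl22 −20, petB +10, clpP intron 2 +10,
ndhA +24, rps16 +25), a 22-bp LSC and a 5-bp SSC intergenic deletion, and
50 group-diagnostic coding substitutions; each member adds 2 private
substitutions. All randomness flows from one seed through a counter-based
generator (numpy Philox), so identical seeds give identical bytes across
platforms.

What passing on synthetic data does not show: the generator plants exact
IRs, clean annotations and independent point edits. It does not emulate
annotation errors, IR boundary expansion/contraction, heteroplasmy,
sequencing artifacts, or homology between accessions beyond the shared
base genome, so results on real records additionally depend on annotation
quality and the exactness of deposited IRs.

## Degenerate inputs and tie-breaks

Empty or all-N sequences make GC undefined (error). Genomes without an IR
of the minimum length raise a "not quadripartite" error; two overlapping
top IR hits raise an ambiguity error listing both. A gene absent from one
accession drops out of the common intron set and is listed in a sidecar.
Primer design failures report the violated constraint. Pipeline stages are
isolated: a failing stage is logged and reported (exit 3) without aborting
the others; configuration errors abort before any compute (exit 2).

## Problem sizes used in the checks

The automated checks run the detector-vs-oracle comparison on dozens of
random genomes of 2–20 kb, the panel screens on the six-accession default
panel, alignment-vs-oracle comparisons on fixtures up to ~5 kb, and
bootstrap at 200 replicates (1,000 remains the pipeline default); these
sizes were chosen so the whole verification is a matter of a few minutes
while every check stays exact rather than approximate.
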