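# plastidpoly

Comparative analysis of annotated chloroplast (plastid) genomes, built around
the screens used to separate maternal lineages in closely related crop
accessions (the motivating system is *Pyrus* — Asian pear cultivars plus a
*Malus* outgroup, 19 plastomes of ~160 kb):

1. **Quadripartite structure** — detect the inverted-repeat pair (IRa/IRb)
   from sequence alone by seed-and-extend over exact matches between the
   circular genome and its reverse complement, then partition the circle into
   LSC (large single copy), SSC (small single copy), IRa and IRb, with
   per-region length and GC statistics.
2. **Intron-length polymorphism screen** — extract every cis intron length
   from annotation coordinates across accessions, collapse IR-duplicated
   genes after an equality check, and rank genes by length variance
   (max − min, bp). Trans-spliced genes (plastid *rps12*) contribute only
   their cis intron.
3. **InDel markers in silico** — hold the five published intron-flanking
   primer pairs (*rpl22*, *petB*, *clpP*, *ndhA*, *rps16*), design new
   exon-anchored pairs around any polymorphic intron, predict amplicon sizes
   on the circular template (5′-end to 5′-end, both footprints included),
   and bin accessions into band groups at gel resolution.
4. **Divergence scan** — align each accession to a reference plastome by
   anchor-chain-and-fill global alignment (match +1, mismatch −1, gap open
   −4, extend −1; leftmost gap placement), report windowed percent identity
   (default 100 bp / 25 bp step), InDel calls with flanking-gene context,
   and merged divergent regions.
5. **Maternal-lineage phylogeny** — concatenate the protein-coding genes
   shared by all accessions (spliced CDS, or unspliced gene footprints with
   *rps12* excluded), compute p/JC69/K2P distances, build a neighbor-joining
   tree with deterministic tie-breaking, and attach column-bootstrap
   supports.

A first-class synthetic-plastome generator (`plastidpoly.synth`) produces
small circular quadripartite genomes with planted IRs, genes, introns,
InDels and substitutions plus a ground-truth manifest, so the whole pipeline
is verifiable against exact expected answers without downloading anything.

## Worked example

Generate a two-group panel of six accessions (groups differ by the stated
InDel sizes: *rpl22* 20 bp, *petB* 10 bp, *clpP* intron 2 10 bp, *ndhA*
24 bp, *rps16* 25 bp, plus a 22-bp and a 5-bp intergenic deletion and 50
group-diagnostic coding substitutions), then run the screens:

```bash
plastidpoly synth --preset two-groups --seed 7 -o fixtures
plastidpoly partition fixtures/A1.gb fixtures/B1.gb -o table1.tsv
```

```
accession  genome_bp  lsc_bp  ssc_bp  ir_bp  gc_pct  gc_lsc  gc_ssc  gc_ir  n_genes  n_ir_duplicated
       A1      15600    8000    2800   2400   35.99   34.46   29.57  42.29       16                2
       B1      15622    8003    2819   2400   36.01   34.47   29.66  42.29       16                2
```

B1 is 22 bp longer overall; its LSC carries the net +3 bp of planted edits
(−20 +10 −22 +10 +25) and its SSC the +19 (+24 −5); the IR is untouched.
GC is highest in the IR and lowest in the SSC, as in real plastomes.

```bash
plastidpoly introns fixtures/*.gb -o table3.tsv --min-variance 10
```

```
polymorphic (variance >= 10 bp):
  rps16 intron 1: 25 bp
  ndhA intron 1: 24 bp
  rpl22 intron 1: 20 bp
  clpP intron 2: 10 bp
  petB intron 1: 10 bp
```

Every planted InDel reappears exactly as its length variance; the
IR-located *ndhB* intron and the *rps12* cis intron stay flat.

```bash
plastidpoly tree fixtures/*.gb --mode cds_plus_intron --bootstrap 200 --seed 42 -o tree.nwk
```

```
(B2:0.000241,B3:0.000241,(B1:0.000241,(A3:0.000121,(A1:0.000243,A2:0.000243)59:0.000000)100:0.005231)24:0.000000);
```

The A-vs-B bipartition (the designed maternal split) carries 100% bootstrap
support; edges inside each group have near-zero length and weak support, as
expected when members differ only by a couple of private substitutions.

The same stages run end-to-end from a flat YAML config
(`plastidpoly run --config run.cfg`), producing `table1.tsv`, `table3.tsv`,
`bands.tsv`, `divergence/`, `tree.nwk` and `run.log`, with exit codes
0 (success), 2 (config error), 3 (stage failure).

## Working with the deposited pear plastomes

The analyses reproduce the published *Pyrus* statistics when run on the 19
deposited GenBank records (OK545532, KX904342, KX450877, OK545533, KX825882,
KX825885, KX450876, OK545534, OK545535, OK545536, KX450881, KX450880,
OK545537, OK545538, OK545529, OK574454, KX450879, OK545530, OK545531). They
are not redistributed here; with network access:

```bash
plastidpoly fetch OK545532 KX904342 ... -o data/deposited
```

after which the deposited-record acceptance tests run against them.

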