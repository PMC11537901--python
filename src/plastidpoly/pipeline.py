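"""End-to-end orchestration: partition -> intron screen -> markers ->
divergence -> tree, from a flat config, with per-stage failure isolation.

Outputs (all deterministic for a fixed config + seed):
  table1.tsv   region statistics per accession
  table3.tsv   intron-length matrix with variance column
  bands.tsv    in-silico amplicon sizes per accession x marker
  divergence/  identity profiles (TSV), InDel calls and divergent regions (BED)
  tree.nwk     bootstrap-annotated neighbor-joining tree
  run.log      package version, parameters, seed, stage status
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import yaml

from . import __version__
from . import divergence as dv
from . import introns as intr
from . import markers as mk
from . import phylogeny as ph
from . import quadripartite as quad
from .io import read_many
from .records import PlastomeRecord

log = logging.getLogger("plastidpoly")


class ConfigError(ValueError):
    """Invalid run configuration (reported before any compute)."""


@dataclass
class RunConfig:
    inputs: list[str] = field(default_factory=list)
    reference: str = ""  # accession id used for divergence scans
    outgroup: str = ""  # accession id for tree orientation/reporting
    outdir: str = "plastidpoly_out"
    seed: int = 0
    min_ir_len: int = 1000
    min_variance: int = 10
    window_bp: int = 100
    step_bp: int = 25
    identity_threshold: float = 90.0
    size_resolution_bp: int = 10
    primers: str = "auto"  # published | design | auto
    product_target: int = 400
    tree_mode: str = "cds_plus_intron"  # cds | cds_plus_intron | whole_genome
    bootstrap_replicates: int = 1000
    distance_model: str = "p"

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a flat mapping")
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ConfigError(f"{path}: unknown config key: {key}")
            setattr(cfg, key, value)
        return cfg


@dataclass
class RunReport:
    stages: dict[str, str] = field(default_factory=dict)  # stage -> ok | error msg
    outputs: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(v == "ok" for v in self.stages.values())


def _validate(config: RunConfig, records: list[PlastomeRecord]) -> None:
    ids = [r.accession_id for r in records]
    if len(records) < 2:
        raise ConfigError("need at least 2 input records")
    if len(set(ids)) != len(ids):
        raise ConfigError(f"duplicate accession ids in inputs: {ids}")
    if config.reference and config.reference not in ids:
        raise ConfigError(
            f"reference {config.reference!r} is not among inputs {ids}"
        )
    if config.outgroup and config.outgroup not in ids:
        raise ConfigError(
            f"outgroup {config.outgroup!r} is not among inputs {ids}"
        )


def run_all(
    config: RunConfig, records: list[PlastomeRecord] | None = None
) -> RunReport:
    """Run every stage; failures are isolated per stage and reported."""
    if records is None:
        if not config.inputs:
            raise ConfigError("no inputs configured")
        records = read_many(config.inputs)
    _validate(config, records)
    reference = config.reference or records[0].accession_id
    os.makedirs(config.outdir, exist_ok=True)
    os.makedirs(os.path.join(config.outdir, "divergence"), exist_ok=True)
    report = RunReport()
    logpath = os.path.join(config.outdir, "run.log")
    handler = logging.FileHandler(logpath, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("plastidpoly %s", __version__)
    for key, val in vars(config).items():
        if key != "inputs":
            log.info("param %s = %r", key, val)
    log.info("inputs: %s", [r.accession_id for r in records])

    state: dict = {}

    def stage(name, fn):
        try:
            fn()
            report.stages[name] = "ok"
            log.info("stage %s: ok", name)
        except Exception as exc:  # noqa: BLE001 - per-stage isolation
            report.stages[name] = f"error: {exc}"
            log.error("stage %s failed: %s", name, exc)

    def s_partition():
        state["partitions"] = {
            r.accession_id: quad.partition(r, config.min_ir_len) for r in records
        }
        table1 = quad.region_table(records, config.min_ir_len)
        path = os.path.join(config.outdir, "table1.tsv")
        table1.to_csv(path, sep="\t", index=False)
        report.outputs["table1"] = path

    def s_introns():
        parts = [state["partitions"][r.accession_id] for r in records]
        matrix = intr.build_matrix(records, parts)
        state["intron_matrix"] = matrix
        path = os.path.join(config.outdir, "table3.tsv")
        matrix.to_frame().to_csv(path, sep="\t", index=False)
        report.outputs["table3"] = path

    def s_markers():
        matrix = state["intron_matrix"]
        ref_rec = next(r for r in records if r.accession_id == reference)
        pairs = _select_primers(config, records, ref_rec, matrix)
        preds = [
            mk.predict_amplicon(rec, pair)
            for pair in pairs
            for rec in records
        ]
        table = mk.band_groups(preds, config.size_resolution_bp)
        state["bands"] = table
        path = os.path.join(config.outdir, "bands.tsv")
        table.to_frame().to_csv(path, sep="\t", index_label="accession")
        report.outputs["bands"] = path

    def s_divergence():
        ref_rec = next(r for r in records if r.accession_id == reference)
        ref_rot, ref_part = quad.canonicalize(ref_rec, config.min_ir_len)
        profiles = []
        all_calls = []
        for rec in records:
            if rec.accession_id == reference:
                continue
            q_rot, _ = quad.canonicalize(rec, config.min_ir_len)
            aln = dv.align_to_reference(ref_rot, q_rot)
            profiles.append(
                dv.windowed_identity(aln, config.window_bp, config.step_bp)
            )
            all_calls.extend(
                (rec.accession_id, c) for c in dv.call_indels(aln, ref_rot)
            )
        ddir = os.path.join(config.outdir, "divergence")
        ppath = os.path.join(ddir, "identity.tsv")
        dv.profiles_to_frame(profiles).to_csv(ppath, sep="\t", index=False)
        report.outputs["identity"] = ppath
        bed = os.path.join(ddir, "indels.bed")
        with open(bed, "w") as fh:
            for acc, c in all_calls:
                fh.write(
                    dv.indels_to_bed([c], f"{reference}|{acc}")
                )
        report.outputs["indels"] = bed
        regions = dv.divergent_regions(
            profiles, config.identity_threshold, ref_rot
        )
        rpath = os.path.join(ddir, "divergent_regions.bed")
        with open(rpath, "w") as fh:
            for r in regions:
                fh.write(
                    f"{reference}\t{r.start}\t{r.end}\t"
                    f"{','.join(r.gene_context)}\t{r.min_identity:.1f}\n"
                )
        report.outputs["divergent_regions"] = rpath

    def s_tree():
        if config.tree_mode == "whole_genome":
            rotated = [
                quad.canonicalize(r, config.min_ir_len)[0] for r in records
            ]
            matrix = ph.whole_genome_matrix(rotated)
        else:
            matrix = ph.build_matrix(records, mode=config.tree_mode)
        tree = ph.bootstrap(
            matrix,
            n_replicates=config.bootstrap_replicates,
            seed=config.seed,
            model=config.distance_model,
        )
        path = os.path.join(config.outdir, "tree.nwk")
        with open(path, "w") as fh:
            fh.write(tree.newick() + "\n")
        state["tree"] = tree
        report.outputs["tree"] = path

    stage("partition", s_partition)
    if "partitions" in state:
        stage("introns", s_introns)
    if "intron_matrix" in state:
        stage("markers", s_markers)
    stage("divergence", s_divergence)
    stage("tree", s_tree)
    log.removeHandler(handler)
    handler.close()
    return report


def _select_primers(config, records, ref_rec, matrix) -> list[mk.PrimerPair]:
    """Published pairs when they amplify everywhere; else design new ones."""
    chosen: list[mk.PrimerPair] = []
    covered: set[str] = set()
    if config.primers in ("published", "auto"):
        for pair in mk.PUBLISHED_PRIMERS:
            preds = [mk.predict_amplicon(r, pair) for r in records]
            if all(p.product_size_bp is not None for p in preds):
                chosen.append(pair)
                covered.add(pair.marker_name.lower())
        if config.primers == "published":
            return chosen
    targets = intr.polymorphic_genes(matrix, config.min_variance)
    for row in targets:
        if row.gene_name.lower() in covered:
            continue
        try:
            candidates = mk.design_primer_candidates(
                ref_rec,
                row.gene_name,
                mk.DesignConstraints(product_target=config.product_target),
                intron_index=row.intron_index,
            )
        except mk.PrimerDesignError as exc:
            log.warning("primer design failed for %s: %s", row.gene_name, exc)
            continue
        # keep the best-ranked pair that amplifies cleanly in every accession
        # (polymorphic exon positions can break a binding site); primers that
        # fail to bind somewhere are screened out once, not per pair
        binds: dict[str, bool] = {}

        def _binds_everywhere(primer: str) -> bool:
            if primer not in binds:
                binds[primer] = all(
                    mk.find_binding_sites(r.sequence, primer) for r in records
                )
            return binds[primer]

        pair = None
        for cand in candidates:
            if not (_binds_everywhere(cand.forward)
                    and _binds_everywhere(cand.reverse)):
                continue
            preds = [mk.predict_amplicon(r, cand) for r in records]
            if all(
                p.product_size_bp is not None and not p.ambiguous for p in preds
            ):
                pair = cand
                break
        if pair is None:
            log.warning(
                "no candidate pair for %s amplifies in all accessions",
                row.gene_name,
            )
            continue
        # distinguish the two introns of two-intron genes in the band table
        if row.intron_index > 1:
            pair = mk.PrimerPair(
                f"{row.gene_name}.i{row.intron_index}",
                pair.forward,
                pair.reverse,
                pair.target_size_range,
            )
        chosen.append(pair)
        covered.add(pair.marker_name.lower())
    if not chosen:
        raise RuntimeError("no usable primer pairs (published or designed)")
    return chosen
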