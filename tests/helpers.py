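"""Shared test utilities: random additive trees, deposited-record loading."""

from __future__ import annotations

import random
from pathlib import Path

import pytest

from plastidpoly import io as pio

#: study accession labels -> GenBank accession numbers (cp genome deposits)
DEPOSITED = {
    "AG": "OK545532", "NK": "KX904342", "HKB": "KX450877", "YS": "OK545533",
    "KC": "KX825882", "SG": "KX825885", "WH": "KX450876", "CJ": "OK545534",
    "DG": "OK545535", "CDR": "OK545536", "YL": "KX450881", "DSHS": "KX450880",
    "OPR125": "OK545537", "OPR195": "OK545538", "GD": "OK545529",
    "KZ": "OK574454", "BTL": "KX450879", "MRB": "OK545530", "FJ": "OK545531",
}

DEPOSITED_DIR = Path(__file__).resolve().parent.parent / "data" / "deposited"


def load_deposited(labels=None):
    """Load deposited GenBank records from data/deposited/<ACC>.gb.

    The records are not redistributable inside this repository; fetch them
    once with `plastidpoly fetch <accessions> -o data/deposited`.
    """
    labels = list(labels or DEPOSITED)
    missing = [
        lab for lab in labels
        if not (DEPOSITED_DIR / f"{DEPOSITED[lab]}.gb").exists()
    ]
    if missing:
        pytest.fail(
            "deposited GenBank records not available under "
            f"{DEPOSITED_DIR} (missing: {', '.join(missing)}); fetch them "
            "with: plastidpoly fetch "
            + " ".join(DEPOSITED[m] for m in missing)
            + f" -o {DEPOSITED_DIR}"
        )
    out = {}
    for lab in labels:
        rec = pio.read_genbank(str(DEPOSITED_DIR / f"{DEPOSITED[lab]}.gb"))
        rec.accession_id = lab
        out[lab] = rec
    return out


def random_additive_tree(rng: random.Random, n_taxa: int):
    """Random binary tree with positive branch lengths.

    Returns (taxa, leaf-to-leaf path distances, set of true bipartitions,
    each bipartition given as the side not containing taxa[0]).
    """
    taxa = [f"t{i}" for i in range(n_taxa)]
    nodes = {t: (t,) for t in taxa}
    children: dict = {}
    active = list(taxa)
    counter = 0
    while len(active) > 1:
        a = active.pop(rng.randrange(len(active)))
        b = active.pop(rng.randrange(len(active)))
        parent = f"n{counter}"
        counter += 1
        children[parent] = [(a, rng.uniform(0.05, 0.5)),
                            (b, rng.uniform(0.05, 0.5))]
        nodes[parent] = tuple(sorted(nodes[a] + nodes[b]))
        active.append(parent)
    root = active[0]

    dist: dict[tuple[str, str], float] = {}

    def collect(node):
        if node in children:
            out = {}
            for child, bl in children[node]:
                for leaf, d in collect(child).items():
                    out[leaf] = d + bl
            for child, _ in children[node]:
                sub = collect(child)
                for x in sub:
                    for y in out:
                        if y not in sub:
                            dist[(x, y)] = dist[(y, x)] = out[x] + out[y]
            return out
        return {node: 0.0}

    collect(root)
    all_taxa = frozenset(taxa)
    bips = set()
    for leafset in nodes.values():
        side = frozenset(leafset)
        if taxa[0] in side:
            side = all_taxa - side
        if 1 < len(side) < n_taxa - 1:
            bips.add(side)
    return taxa, dist, bips
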