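"""Synthetic reference trees, alignments and end-to-end fixtures.

The taxonomy half of the package's synthetic-data remit: labeled reference
phylogenies with rank-consistent clades (one "phylum" per clade, lineage
consistent down to genus), optional HGT-like misplaced leaves (a foreign
phylum's *nifH* sitting inside another clade, as horizontally transferred
nitrogenase genes do), plus query placements with known true hosts.  Also
small helpers to grow random trees and evolve Jukes–Cantor sequences along
them, and a writer that materialises a complete pipeline fixture on disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .placement import Placement, ReferenceTree
from .refdb import STOP_CODONS

__all__ = [
    "random_tree",
    "evolve_alignment",
    "clade_tree",
    "clade_queries",
    "CladeTree",
    "random_coding_sequence",
    "write_pipeline_fixture",
]


def random_tree(
    n_leaves: int,
    seed: int = 0,
    branch_range: tuple[float, float] = (0.02, 0.30),
    prefix: str = "L",
) -> ReferenceTree:
    """Grow a random tree by repeatedly splitting a uniformly chosen edge."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    tn = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tn)

    def new_leaf(i: int) -> dendropy.Node:
        nd = dendropy.Node()
        nd.taxon = tn.require_taxon(label=f"{prefix}{i}")
        nd.edge.length = float(rng.uniform(*branch_range))
        return nd

    for i in range(min(3, n_leaves)):
        tree.seed_node.add_child(new_leaf(i + 1))
    for i in range(3, n_leaves):
        splittable = [
            nd
            for nd in tree.preorder_node_iter()
            if nd.parent_node is not None
        ]
        child = splittable[int(rng.integers(len(splittable)))]
        parent = child.parent_node
        total = child.edge.length
        u = float(rng.uniform(0.2, 0.8))
        mid = dendropy.Node()
        parent.remove_child(child)
        parent.add_child(mid)
        mid.edge.length = u * total
        mid.add_child(child)
        child.edge.length = (1.0 - u) * total
        mid.add_child(new_leaf(i + 1))
    return ReferenceTree(tree)


def evolve_alignment(
    rt: ReferenceTree, length: int = 600, seed: int = 0
) -> dict[str, str]:
    """Evolve ungapped sequences along the tree under the Jukes–Cantor model
    (substitution probability 3/4 (1 - e^(-4b/3)) per site on a branch of
    length b)."""
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    node_seq = {id(rt.tree.seed_node): rng.integers(0, 4, size=length)}
    seqs: dict[str, str] = {}
    for nd in rt.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        b = float(nd.edge.length or 0.0)
        p = 0.75 * (1.0 - math.exp(-4.0 * b / 3.0))
        seq = node_seq[id(nd.parent_node)].copy()
        hit = rng.random(length) < p
        if hit.any():
            seq[hit] = (seq[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        node_seq[id(nd)] = seq
        if nd.is_leaf():
            seqs[nd.taxon.label] = "".join(alphabet[seq])
    return seqs


@dataclass
class CladeTree:
    """A labeled clade tree with known geometry."""

    rt: ReferenceTree
    clades: dict[str, list[str]]  # phylum name -> original leaf labels
    hgt_leaves: dict[str, str]  # hgt leaf label -> host phylum name
    stem_edges: dict[str, int]  # phylum name -> stem edge number
    stem_length: float
    leaf_lengths: dict[str, float]


def _lineage(i: int, species: str | None = None) -> tuple:
    lin = [
        ("domain", "Bacteria"),
        ("phylum", f"Phylum{i}"),
        ("class", f"Class{i}"),
        ("order", f"Order{i}"),
        ("family", f"Family{i}"),
        ("genus", f"Genus{i}"),
    ]
    if species is not None:
        lin.append(("species", species))
    return tuple(lin)


def clade_tree(
    n_phyla: int = 4,
    leaves_per_clade: int = 5,
    stem_length: float = 0.30,
    leaf_length_range: tuple[float, float] = (0.10, 0.15),
    seed: int = 0,
    n_hgt: int = 0,
) -> CladeTree:
    """Star of pure-phylum clades.

    Each clade hangs off a central node by a stem of ``stem_length``; leaves
    attach directly to the clade root with branch lengths drawn from
    ``leaf_length_range``.  With the defaults, within-clade patristic
    diameter is <= 0.30 and the minimum between-clade leaf distance is
    >= 0.80.  ``n_hgt`` extra leaves carry a *foreign* phylum's lineage but
    sit inside another clade (round-robin over clades).
    """
    rng = np.random.default_rng(seed)
    lineages: dict[str, tuple] = {}
    clades: dict[str, list[str]] = {}
    hgt: dict[str, str] = {}
    leaf_lengths: dict[str, float] = {}
    clade_strs = []
    hgt_count = 0
    for i in range(1, n_phyla + 1):
        phylum = f"Phylum{i}"
        parts = []
        labels = []
        for j in range(1, leaves_per_clade + 1):
            lab = f"P{i}L{j}"
            bl = float(rng.uniform(*leaf_length_range))
            leaf_lengths[lab] = bl
            parts.append(f"{lab}:{bl:.6f}")
            labels.append(lab)
            lineages[lab] = _lineage(i, species=f"Species{i}_{j}")
        if hgt_count < n_hgt:
            hgt_count += 1
            lab = f"HGT{hgt_count}"
            foreign = (i % n_phyla) + 1
            bl = float(rng.uniform(*leaf_length_range))
            leaf_lengths[lab] = bl
            parts.append(f"{lab}:{bl:.6f}")
            lineages[lab] = _lineage(foreign, species=f"SpeciesHGT{hgt_count}")
            hgt[lab] = phylum
        clade_strs.append("(" + ",".join(parts) + f"):{stem_length:.6f}")
        clades[phylum] = labels
    newick = "(" + ",".join(clade_strs) + ");"
    rt = ReferenceTree.from_newick(newick, leaf_lineages=lineages)
    stem_edges = {}
    for phylum, labels in clades.items():
        mrca = rt.tree.mrca(taxon_labels=labels)
        stem_edges[phylum] = rt.edge_num(mrca.edge)
    return CladeTree(
        rt=rt,
        clades=clades,
        hgt_leaves=hgt,
        stem_edges=stem_edges,
        stem_length=stem_length,
        leaf_lengths=leaf_lengths,
    )


def clade_queries(
    ct: CladeTree,
    n_in_clade: int = 16,
    n_divergent: int = 4,
    seed: int = 0,
    pendant_range: tuple[float, float] = (0.01, 0.03),
    divergent_distal: float = 0.15,
    divergent_pendant: float = 0.05,
) -> tuple[list[Placement], dict[str, str], set[str]]:
    """Query placements with known true phylum.

    In-clade queries attach part-way along a leaf branch (novel strains of
    known references).  Divergent queries attach on a clade's stem,
    ``divergent_distal`` above the clade root — a lineage related to, but
    well outside, the sampled clade, whose nearest reference therefore sits
    at a patristic distance of roughly 0.30-0.35.
    """
    rng = np.random.default_rng(seed)
    phyla = list(ct.clades)
    placements: list[Placement] = []
    truth: dict[str, str] = {}
    divergent: set[str] = set()
    for q in range(n_in_clade):
        phylum = phyla[q % len(phyla)]
        lab = ct.clades[phylum][int(rng.integers(len(ct.clades[phylum])))]
        num = ct.rt.edge_num_for_leaf(lab)
        b = ct.rt.branch_length(num)
        qid = f"Q{q + 1:03d}"
        placements.append(
            Placement(
                query_id=qid,
                edge_num=num,
                distal_length=float(rng.uniform(0.2, 0.8)) * b,
                pendant_length=float(rng.uniform(*pendant_range)),
            )
        )
        truth[qid] = phylum
    for d in range(n_divergent):
        phylum = phyla[d % len(phyla)]
        qid = f"D{d + 1:03d}"
        placements.append(
            Placement(
                query_id=qid,
                edge_num=ct.stem_edges[phylum],
                distal_length=divergent_distal,
                pendant_length=divergent_pendant,
            )
        )
        truth[qid] = phylum
        divergent.add(qid)
    return placements, truth, divergent


_SAFE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


def random_coding_sequence(rng: np.random.Generator, n_codons: int = 111) -> str:
    """A start-codon .. stop-codon flanked random open reading frame."""
    middle = rng.choice(len(_SAFE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_SAFE_CODONS[i] for i in middle) + "TAA"


def write_pipeline_fixture(outdir, seed: int = 0) -> dict[str, str]:
    """Materialise a complete, self-consistent pipeline input set.

    Writes reference FASTA + lineage TSV (curation-clean), the clade tree,
    query placements as jplace, a simulated SIP experiment (counts + fraction
    metadata), and a pipeline config.  Returns the path map.
    """
    import os

    import yaml

    from . import gradient, io as nio
    from .placement import write_placements

    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    ct = clade_tree(seed=seed)
    placements, truth, _ = clade_queries(ct, seed=seed + 1)

    paths = {k: os.path.join(outdir, v) for k, v in {
        "refs": "references.fasta",
        "lineages": "lineages.tsv",
        "tree": "tree.nwk",
        "jplace": "placements.jplace",
        "counts": "sip_counts.tsv",
        "meta": "sip_fractions.tsv",
        "config": "config.yaml",
    }.items()}

    records = [
        (lab, random_coding_sequence(rng), f"{dict(ct.rt.leaf_lineages[lab])['genus']} sp. {lab}")
        for lab in ct.rt.leaf_labels
    ]
    nio.write_fasta(paths["refs"], [(i, s) for i, s, _ in records],
                    descriptions={i: d for i, s, d in records})
    nio.write_lineage_table(paths["lineages"], ct.rt.leaf_lineages)
    with open(paths["tree"], "w") as fh:
        fh.write(ct.rt.to_newick() + "\n")
    write_placements(paths["jplace"], ct.rt, placements)

    taxa = gradient.community(n_taxa=60, seed=seed + 2)
    gconf = gradient.GradientConfig(library_depth=20_000, seed=seed + 3)
    control, treatment = gradient.simulate_experiment(taxa, gconf)
    nio.write_fraction_tables(paths["counts"], paths["meta"], control, treatment)

    config = {
        "seed": seed,
        "reference_fasta": "references.fasta",
        "lineages": "lineages.tsv",
        "tree": "tree.nwk",
        "placements": "placements.jplace",
        "sip_counts": "sip_counts.tsv",
        "sip_metadata": "sip_fractions.tsv",
        "classifier": {"k": 0.48, "annotation_rank": "phylum"},
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    paths["truth"] = truth
    return paths
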