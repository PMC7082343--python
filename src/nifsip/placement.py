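"""Phylogenetic placement of query amplicons on a reference tree.

Two routes are supported:

* ingestion of standard jplace (v3) files produced by external placers
  (SEPP/EPA/pplacer), including the jplace Newick dialect with ``{N}`` edge
  numbers; and
* a built-in deterministic placer that inserts a query on the edge minimising
  a Fitch–Margoliash-weighted least-squares discrepancy between the patristic
  path lengths through the attachment point and pairwise Jukes–Cantor
  distances from the query to every reference leaf.  Pendant and distal
  lengths are fitted per edge by nonnegative (box-constrained) least squares.

The built-in placer is a desk-scale, oracle-verifiable substitute for
maximum-likelihood placement, not a reimplementation of it.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy
import numpy as np

__all__ = [
    "ReferenceTree",
    "Placement",
    "UnplaceableError",
    "JplaceError",
    "read_placements",
    "write_placements",
    "place_query",
    "jc_distance",
]

#: Saturation cap for Jukes–Cantor distances (substitutions/site).
JC_CAP = 5.0

#: Distance floor when forming 1/d^2 placement weights.
_WEIGHT_FLOOR = 1e-6


class UnplaceableError(ValueError):
    """Raised when a query shares no aligned columns with any reference."""


class JplaceError(ValueError):
    """Raised for malformed jplace content."""


# ---------------------------------------------------------------------------
# Reference tree


class ReferenceTree:
    """A reference phylogeny with numbered edges and optional leaf lineages.

    Wraps a :class:`dendropy.Tree`.  Every edge below the seed node gets a
    stable integer number: postorder index for trees built from plain Newick,
    or the file's own numbering for trees read from jplace.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        leaf_lineages: Mapping[str, tuple] | None = None,
        edge_numbers: Mapping[int, dendropy.Edge] | None = None,
    ):
        self.tree = tree
        # rooting is presentational only; fixing it silences dendropy's
        # MRCA-on-unrooted warning without changing any path length
        self.tree.is_rooted = True
        self.leaf_lineages = dict(leaf_lineages or {})
        self._nodes = list(tree.preorder_node_iter())
        self._node_index = {id(nd): i for i, nd in enumerate(self._nodes)}
        self.leaf_labels: list[str] = [
            lf.taxon.label for lf in tree.leaf_node_iter()
        ]
        if len(set(self.leaf_labels)) != len(self.leaf_labels):
            raise ValueError("duplicate leaf labels in reference tree")
        for e in tree.preorder_edge_iter():
            if e.head_node.parent_node is not None and (e.length or 0.0) < 0:
                raise ValueError("negative branch length in reference tree")
        if edge_numbers is None:
            edge_numbers = {}
            num = 0
            for nd in tree.postorder_node_iter():
                if nd.parent_node is not None:
                    edge_numbers[num] = nd.edge
                    num += 1
        self._num_to_edge: dict[int, dendropy.Edge] = dict(edge_numbers)
        self._edge_to_num = {id(e): n for n, e in self._num_to_edge.items()}
        self._leaf_dist_matrix: np.ndarray | None = None
        self._child_leafsets: dict[int, frozenset[str]] | None = None

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(
        cls, source: str, leaf_lineages: Mapping[str, tuple] | None = None
    ) -> "ReferenceTree":
        """Build from a Newick string or a path to a Newick file."""
        if "(" in source:
            tree = dendropy.Tree.get(
                data=source, schema="newick", preserve_underscores=True
            )
        else:
            tree = dendropy.Tree.get(
                path=source, schema="newick", preserve_underscores=True
            )
        return cls(tree, leaf_lineages)

    def to_newick(self, edge_numbers: bool = False) -> str:
        """Newick string; with ``edge_numbers=True``, the jplace ``{N}``
        dialect is produced."""
        return _write_newick(self, with_edge_numbers=edge_numbers) + ";"

    # -- edges -------------------------------------------------------------

    @property
    def edge_nums(self) -> list[int]:
        return sorted(self._num_to_edge)

    def edge(self, num: int) -> dendropy.Edge:
        try:
            return self._num_to_edge[num]
        except KeyError:
            raise KeyError(f"edge {num} not in reference tree") from None

    def edge_num(self, edge: dendropy.Edge) -> int:
        return self._edge_to_num[id(edge)]

    def branch_length(self, num: int) -> float:
        return float(self.edge(num).length or 0.0)

    def edge_num_for_leaf(self, label: str) -> int:
        for lf in self.tree.leaf_node_iter():
            if lf.taxon.label == label:
                return self.edge_num(lf.edge)
        raise KeyError(label)

    # -- distances ---------------------------------------------------------

    def _leaf_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.leaf_labels)}

    def node_leaf_distances(self) -> np.ndarray:
        """Matrix D[node, leaf] of path lengths (nodes in preorder)."""
        if self._leaf_dist_matrix is None:
            n = len(self._nodes)
            adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
            for nd in self._nodes:
                if nd.parent_node is not None:
                    i = self._node_index[id(nd)]
                    j = self._node_index[id(nd.parent_node)]
                    w = float(nd.edge.length or 0.0)
                    adj[i].append((j, w))
                    adj[j].append((i, w))
            D = np.zeros((n, len(self.leaf_labels)))
            for col, lf in enumerate(self.tree.leaf_node_iter()):
                start = self._node_index[id(lf)]
                dist = np.full(n, np.nan)
                dist[start] = 0.0
                stack = [start]
                while stack:
                    u = stack.pop()
                    for v, w in adj[u]:
                        if np.isnan(dist[v]):
                            dist[v] = dist[u] + w
                            stack.append(v)
                D[:, col] = dist
            self._leaf_dist_matrix = D
        return self._leaf_dist_matrix

    def leaves_below(self, edge_num: int) -> frozenset[str]:
        """Leaf labels on the child side of the numbered edge."""
        if self._child_leafsets is None:
            sets: dict[int, frozenset[str]] = {}
            for nd in self.tree.postorder_node_iter():
                if nd.is_leaf():
                    sets[id(nd)] = frozenset({nd.taxon.label})
                else:
                    acc: frozenset[str] = frozenset()
                    for ch in nd.child_nodes():
                        acc |= sets[id(ch)]
                    sets[id(nd)] = acc
            self._child_leafsets = sets
        return self._child_leafsets[id(self.edge(edge_num).head_node)]

    def attachment_leaf_distances(
        self, edge_num: int, distal_length: float
    ) -> dict[str, float]:
        """Path length from a point on an edge to every leaf.

        ``distal_length`` is measured from the edge's child-side node toward
        the parent.  Pendant length is *not* included.
        """
        edge = self.edge(edge_num)
        b = float(edge.length or 0.0)
        if distal_length < -1e-12 or distal_length > b + 1e-9:
            raise ValueError(
                f"distal length {distal_length} outside edge {edge_num} "
                f"(branch length {b})"
            )
        distal_length = min(max(distal_length, 0.0), b)
        D = self.node_leaf_distances()
        child = self._node_index[id(edge.head_node)]
        parent = self._node_index[id(edge.tail_node)]
        below = self.leaves_below(edge_num)
        out: dict[str, float] = {}
        for col, lab in enumerate(self.leaf_labels):
            if lab in below:
                out[lab] = distal_length + D[child, col]
            else:
                out[lab] = (b - distal_length) + D[parent, col]
        return out


# ---------------------------------------------------------------------------
# Placements


@dataclass(frozen=True)
class Placement:
    """Attachment of one query to one reference-tree edge."""

    query_id: str
    edge_num: int
    distal_length: float
    pendant_length: float
    like_weight_ratio: float = 1.0
    is_best: bool = True

    def __post_init__(self) -> None:
        if self.distal_length < 0 or self.pendant_length < 0:
            raise ValueError(
                f"{self.query_id}: negative placement length"
            )
        if not 0.0 <= self.like_weight_ratio <= 1.0:
            raise ValueError(
                f"{self.query_id}: like_weight_ratio outside [0, 1]"
            )


def best_placements(placements: Iterable[Placement]) -> list[Placement]:
    """One placement per query: maximum weight, ties to smallest edge number."""
    by_query: dict[str, Placement] = {}
    for p in placements:
        cur = by_query.get(p.query_id)
        if (
            cur is None
            or p.like_weight_ratio > cur.like_weight_ratio
            or (
                p.like_weight_ratio == cur.like_weight_ratio
                and p.edge_num < cur.edge_num
            )
        ):
            by_query[p.query_id] = p
    return list(by_query.values())


# ---------------------------------------------------------------------------
# jplace I/O


def _parse_jplace_newick(s: str) -> tuple[dendropy.Tree, dict[int, dendropy.Edge]]:
    """Parse the jplace Newick dialect, where every branch may carry an
    ``{N}`` edge number after its length."""
    s = s.strip()
    if s.endswith(";"):
        s = s[:-1]
    pos = 0
    taxa = dendropy.TaxonNamespace()
    edge_map: dict[int, dendropy.Node] = {}

    def error(msg: str) -> JplaceError:
        return JplaceError(f"jplace tree, position {pos}: {msg}")

    def read_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            end = s.index("'", pos + 1)
            lab = s[pos + 1 : end]
            pos = end + 1
            return lab
        start = pos
        while pos < len(s) and s[pos] not in "(),:;{}":
            pos += 1
        return s[start:pos].strip()

    def read_clade() -> dendropy.Node:
        nonlocal pos
        node = dendropy.Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.add_child(read_clade())
                if pos >= len(s):
                    raise error("unterminated clade")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character {s[pos]!r}")
        label = read_label()
        if label:
            if node.child_nodes():
                node.label = label
            else:
                node.taxon = taxa.require_taxon(label=label)
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and (s[pos] in "+-.eE" or s[pos].isdigit()):
                pos += 1
            node.edge.length = float(s[start:pos])
        if pos < len(s) and s[pos] == "{":
            end = s.index("}", pos)
            edge_map[int(s[pos + 1 : end])] = node
            pos = end + 1
        return node

    root = read_clade()
    if pos != len(s):
        raise error("trailing characters after tree")
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    return tree, {num: nd.edge for num, nd in edge_map.items()}


def _fmt_len(x: float) -> str:
    return format(float(x), ".12g")


def _write_newick(rt: ReferenceTree, with_edge_numbers: bool) -> str:
    def render(nd: dendropy.Node) -> str:
        if nd.is_leaf():
            core = nd.taxon.label if nd.taxon else (nd.label or "")
        else:
            core = (
                "(" + ",".join(render(c) for c in nd.child_nodes()) + ")"
                + (nd.label or "")
            )
        if nd.parent_node is not None:
            core += ":" + _fmt_len(nd.edge.length or 0.0)
            if with_edge_numbers and id(nd.edge) in rt._edge_to_num:
                core += "{%d}" % rt.edge_num(nd.edge)
        return core

    return render(rt.tree.seed_node)


_JPLACE_FIELDS = (
    "edge_num",
    "likelihood",
    "like_weight_ratio",
    "distal_length",
    "pendant_length",
)


def read_placements(
    path: str, leaf_lineages: Mapping[str, tuple] | None = None
) -> tuple[ReferenceTree, list[Placement]]:
    """Read a jplace (v3) file: returns the embedded reference tree and all
    placements, with the best placement per query flagged."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise JplaceError(f"{path}: malformed JSON ({exc})") from exc
    for key in ("tree", "placements", "fields"):
        if key not in doc:
            raise JplaceError(f"{path}: missing jplace key {key!r}")
    tree, edge_numbers = _parse_jplace_newick(doc["tree"])
    rt = ReferenceTree(tree, leaf_lineages, edge_numbers)
    fields = list(doc["fields"])
    idx = {}
    for f in ("edge_num", "distal_length", "pendant_length", "like_weight_ratio"):
        if f in fields:
            idx[f] = fields.index(f)
    if "edge_num" not in idx:
        raise JplaceError(f"{path}: fields lack edge_num")

    placements: list[Placement] = []
    for pq in doc["placements"]:
        names = pq.get("n") or [nm for nm, _ in pq.get("nm", [])]
        if not names:
            raise JplaceError(f"{path}: placement without query name")
        for name in names:
            for loc in pq["p"]:
                edge_num = int(loc[idx["edge_num"]])
                if edge_num not in rt._num_to_edge:
                    raise JplaceError(
                        f"{path}: query {name!r} references unknown edge "
                        f"{edge_num}"
                    )
                placements.append(
                    Placement(
                        query_id=name,
                        edge_num=edge_num,
                        distal_length=float(loc[idx["distal_length"]])
                        if "distal_length" in idx
                        else 0.0,
                        pendant_length=float(loc[idx["pendant_length"]])
                        if "pendant_length" in idx
                        else 0.0,
                        like_weight_ratio=float(loc[idx["like_weight_ratio"]])
                        if "like_weight_ratio" in idx
                        else 1.0,
                        is_best=False,
                    )
                )
    best = {(p.query_id, p.edge_num) for p in best_placements(placements)}
    placements = [
        Placement(
            p.query_id,
            p.edge_num,
            p.distal_length,
            p.pendant_length,
            p.like_weight_ratio,
            is_best=(p.query_id, p.edge_num) in best,
        )
        for p in placements
    ]
    return rt, placements


def write_placements(
    path: str, rt: ReferenceTree, placements: Iterable[Placement]
) -> None:
    """Write placements as jplace v3."""
    by_query: dict[str, list[Placement]] = {}
    for p in placements:
        by_query.setdefault(p.query_id, []).append(p)
    doc = {
        "version": 3,
        "tree": rt.to_newick(edge_numbers=True),
        "fields": list(_JPLACE_FIELDS),
        "placements": [
            {
                "p": [
                    [
                        p.edge_num,
                        0.0,
                        p.like_weight_ratio,
                        p.distal_length,
                        p.pendant_length,
                    ]
                    for p in plist
                ],
                "n": [qid],
            }
            for qid, plist in by_query.items()
        ],
        "metadata": {"invocation": "nifsip"},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# Jukes–Cantor distances


def jc_distance(a: str, b: str, cap: float = JC_CAP) -> float | None:
    """Jukes–Cantor distance with pairwise deletion of gap/ambiguous columns.

    Returns ``None`` when the two sequences share no comparable columns, and
    ``cap`` when the observed divergence saturates the JC logarithm.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences differ in column count")
    n = 0
    mism = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "ACGT" and y in "ACGT":
            n += 1
            if x != y:
                mism += 1
    if n == 0:
        return None
    p = mism / n
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return cap
    return min(cap, -0.75 * math.log(arg))


# ---------------------------------------------------------------------------
# Built-in least-squares placer


def _fit_edge(
    y: np.ndarray, s: np.ndarray, w: np.ndarray, b: float
) -> tuple[float, float, float]:
    """Minimise sum w_i (x*s_i + p - y_i)^2 over 0 <= x <= b, p >= 0.

    Returns (x, p, weighted SSE).  Solved exactly by enumerating the active
    sets of the two-variable box-constrained quadratic programme.
    """
    Sw = float(np.sum(w))
    Swy = float(np.sum(w * y))
    Sws = float(np.sum(w * s))
    Swsy = float(np.sum(w * s * y))

    def sse(x: float, p: float) -> float:
        r = x * s + p - y
        return float(np.sum(w * r * r))

    candidates: list[tuple[float, float]] = []
    det = Sw * Sw - Sws * Sws
    if det > 1e-30 * Sw * Sw:
        x0 = (Sw * Swsy - Sws * Swy) / det
        p0 = (Sw * Swy - Sws * Swsy) / det
        candidates.append((x0, p0))
    # one active constraint
    if Sw > 0:
        candidates.append((0.0, Swy / Sw))  # x = 0
        candidates.append((b, (Swy - Sws * b) / Sw))  # x = b
        candidates.append((Swsy / Sw, 0.0))  # p = 0
    # corners
    candidates.extend([(0.0, 0.0), (b, 0.0)])

    best = (0.0, 0.0, math.inf)
    for x, p in candidates:
        if not (-1e-15 <= x <= b + 1e-15) or p < -1e-15:
            continue
        x = min(max(x, 0.0), b)
        p = max(p, 0.0)
        f = sse(x, p)
        if f < best[2] - 1e-18:
            best = (x, p, f)
    return best


def placement_score_components(
    rt: ReferenceTree, distances: Mapping[str, float]
) -> dict[int, tuple[float, float, float]]:
    """Per-edge optimum (distal, pendant, weighted SSE) for given
    query-to-leaf distances.  Exposed for oracle-style testing.

    Leaves absent from ``distances`` are excluded from the fit."""
    labels = [lab for lab in rt.leaf_labels if lab in distances]
    if not labels:
        raise ValueError("no usable query-to-leaf distances")
    d = np.array([distances[lab] for lab in labels], dtype=float)
    w = 1.0 / np.maximum(d, _WEIGHT_FLOOR) ** 2
    D = rt.node_leaf_distances()
    cols = np.array([rt.leaf_labels.index(lab) for lab in labels])
    out: dict[int, tuple[float, float, float]] = {}
    for num in rt.edge_nums:
        edge = rt.edge(num)
        b = float(edge.length or 0.0)
        child = rt._node_index[id(edge.head_node)]
        parent = rt._node_index[id(edge.tail_node)]
        below = rt.leaves_below(num)
        mask = np.array([lab in below for lab in labels])
        s = np.where(mask, 1.0, -1.0)
        c = np.where(mask, D[child, cols], b + D[parent, cols])
        y = d - c
        x, p, f = _fit_edge(y, s, w, b)
        out[num] = (x, p, f)
    return out


def place_query_from_distances(
    query_id: str, rt: ReferenceTree, distances: Mapping[str, float]
) -> Placement:
    """Least-squares insertion given query-to-leaf distances directly."""
    comps = placement_score_components(rt, distances)
    best_num = None
    best = (math.inf, math.inf)
    for num in sorted(comps):
        x, p, f = comps[num]
        if f < best[0] - 1e-12:
            best = (f, num)
            best_num = num
    x, p, _ = comps[best_num]
    return Placement(
        query_id=query_id,
        edge_num=best_num,
        distal_length=x,
        pendant_length=p,
        like_weight_ratio=1.0,
    )


def place_query(
    query_id: str,
    query_seq: str,
    ref_alignment: Mapping[str, str],
    rt: ReferenceTree,
) -> Placement:
    """Place one aligned query on the reference tree.

    The query must be in the reference alignment's coordinate system (same
    column count).  Deterministic: ties across edges break to the smallest
    edge number.
    """
    lengths = {len(v) for v in ref_alignment.values()}
    if len(lengths) != 1:
        raise ValueError("reference alignment columns are ragged")
    (ncol,) = lengths
    if len(query_seq) != ncol:
        raise ValueError(
            f"query {query_id!r} has {len(query_seq)} columns, "
            f"alignment has {ncol}"
        )
    missing = [lab for lab in rt.leaf_labels if lab not in ref_alignment]
    if missing:
        raise ValueError(f"alignment lacks reference leaves: {missing[:5]}")
    distances: dict[str, float] = {}
    dropped = []
    for lab in rt.leaf_labels:
        d = jc_distance(query_seq, ref_alignment[lab])
        if d is None:
            dropped.append(lab)
        else:
            distances[lab] = d
    if not distances:
        raise UnplaceableError(
            f"query {query_id!r} overlaps no reference sequence"
        )
    if dropped:
        warnings.warn(
            f"query {query_id!r}: no aligned overlap with "
            f"{len(dropped)} reference(s); excluded from the fit"
        )
    return place_query_from_distances(query_id, rt, distances)
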