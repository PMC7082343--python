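"""Built-in least-squares placement and jplace interoperability."""

import json
import math

import dendropy
import numpy as np
import pytest

from nifsip.placement import (
    JplaceError,
    Placement,
    ReferenceTree,
    UnplaceableError,
    best_placements,
    jc_distance,
    place_query,
    place_query_from_distances,
    placement_score_components,
    read_placements,
    write_placements,
)
from nifsip.synth import evolve_alignment, random_tree


def graft_oracle_distances(rt: ReferenceTree, placement: Placement):
    """Independent oracle: graft the query as a real leaf on a cloned tree
    and read patristic distances off dendropy's distance matrix."""
    clone = ReferenceTree.from_newick(rt.to_newick())
    edge = clone.edge(placement.edge_num)
    child, parent = edge.head_node, edge.tail_node
    b = float(edge.length or 0.0)
    mid = dendropy.Node()
    parent.remove_child(child)
    parent.add_child(mid)
    mid.edge.length = b - placement.distal_length
    mid.add_child(child)
    child.edge.length = placement.distal_length
    q = dendropy.Node()
    q.taxon = clone.tree.taxon_namespace.require_taxon(label="__QUERY__")
    q.edge.length = placement.pendant_length
    mid.add_child(q)
    pdm = clone.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in clone.tree.taxon_namespace}
    return {
        lab: pdm.patristic_distance(taxa["__QUERY__"], taxa[lab])
        for lab in rt.leaf_labels
    }


class TestJukesCantor:
    def test_zero_and_saturation(self):
        assert jc_distance("ACGT", "ACGT") == 0.0
        assert jc_distance("AAAA", "CCCC") == 5.0  # p = 1 saturates at cap

    def test_pairwise_deletion(self):
        # only the 4 shared ACGT columns are compared, one mismatch
        a, b = "ACGT-N", "ACTTG-"
        n, mism = 4, 1
        p = mism / n
        assert jc_distance(a, b) == pytest.approx(-0.75 * math.log(1 - 4 * p / 3))

    def test_no_overlap_is_none(self):
        assert jc_distance("AC--", "--GT") is None


class TestPlaceQuery:
    def test_identical_to_leaf_attaches_on_terminal_edge(self):
        rt = random_tree(8, seed=11)
        aln = evolve_alignment(rt, 500, seed=12)
        p = place_query("q", aln["L3"], aln, rt)
        assert p.edge_num == rt.edge_num_for_leaf("L3")
        assert p.pendant_length < 1e-6

    def test_known_edge_recovered_from_additive_distances(self):
        """Four-leaf tree, query generated at a known point: the exact
        additive distances identify the generating edge and lengths."""
        rt = ReferenceTree.from_newick(
            "((A:0.10,B:0.12):0.08,(C:0.15,D:0.09):0.11);"
        )
        true_edge = rt.edge_num_for_leaf("C")
        truth = Placement("q", true_edge, distal_length=0.06, pendant_length=0.02)
        dists = graft_oracle_distances(rt, truth)
        p = place_query_from_distances("q", rt, dists)
        assert p.edge_num == true_edge
        assert p.distal_length == pytest.approx(0.06, abs=1e-9)
        assert p.pendant_length == pytest.approx(0.02, abs=1e-9)

    def test_cherry_equidistant_query_lands_on_internal_edge(self):
        rt = ReferenceTree.from_newick("((A:0.1,B:0.1):0.1,C:0.2);")
        cherry_edge = rt.edge_num(
            rt.tree.mrca(taxon_labels=["A", "B"]).edge
        )
        truth = Placement("q", cherry_edge, distal_length=0.05, pendant_length=0.02)
        dists = graft_oracle_distances(rt, truth)
        assert dists["A"] == pytest.approx(dists["B"])
        p = place_query_from_distances("q", rt, dists)
        assert p.edge_num == cherry_edge

    @pytest.mark.parametrize("seed", range(8))
    def test_brute_force_grid_oracle_agrees(self, seed):
        """On small trees the placer's per-edge optimum is at least as good
        as an exhaustive (distal, pendant) grid, and the chosen edge matches
        the grid's best edge."""
        rng = np.random.default_rng(seed)
        rt = random_tree(int(rng.integers(5, 13)), seed=seed + 100)
        truth_edge = int(rng.choice(rt.edge_nums))
        b = rt.branch_length(truth_edge)
        truth = Placement(
            "q",
            truth_edge,
            distal_length=float(rng.uniform(0, b)),
            pendant_length=float(rng.uniform(0.005, 0.05)),
        )
        dists = graft_oracle_distances(rt, truth)
        comps = placement_score_components(rt, dists)
        labels = rt.leaf_labels
        d = np.array([dists[lab] for lab in labels])
        w = 1.0 / np.maximum(d, 1e-6) ** 2
        grid_min: dict[int, float] = {}
        for num in rt.edge_nums:
            blen = rt.branch_length(num)
            base = rt.attachment_leaf_distances(num, 0.0)
            # path to each leaf at distal x: child side base+x, parent side base-x
            below = rt.leaves_below(num)
            sgn = np.array([1.0 if lab in below else -1.0 for lab in labels])
            b0 = np.array([base[lab] for lab in labels])
            best = math.inf
            for x in np.linspace(0, blen, 40):
                path = b0 + sgn * x
                for pend in np.linspace(0, 0.1, 60):
                    sse = float(np.sum(w * (path + pend - d) ** 2))
                    best = min(best, sse)
            grid_min[num] = best
            # analytic optimum is at least as good as every grid point
            assert comps[num][2] <= best + 1e-9
        grid_edge = min(grid_min, key=grid_min.get)
        placed = place_query_from_distances("q", rt, dists)
        assert placed.edge_num == grid_edge == truth_edge

    def test_score_invariant_under_rerooting(self):
        rt = random_tree(9, seed=21)
        truth = Placement("q", rt.edge_nums[3], 0.01, 0.03)
        dists = graft_oracle_distances(rt, truth)
        best = min(f for _, _, f in placement_score_components(rt, dists).values())
        clone = ReferenceTree.from_newick(rt.to_newick())
        internal = [
            nd
            for nd in clone.tree.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
        ][0]
        clone.tree.reroot_at_node(internal)
        rerooted = ReferenceTree(clone.tree)
        best2 = min(
            f for _, _, f in placement_score_components(rerooted, dists).values()
        )
        assert best2 == pytest.approx(best, abs=1e-9)

    def test_column_mismatch_and_unplaceable_errors(self):
        rt = ReferenceTree.from_newick("(A:0.1,B:0.2);")
        aln = {"A": "ACGTACGT", "B": "ACGAACGA"}
        with pytest.raises(ValueError, match="column"):
            place_query("q", "ACGT", aln, rt)
        with pytest.raises(UnplaceableError):
            place_query("q", "--------", aln, rt)


class TestJplace:
    def _roundtrip(self, tmp_path, rt, placements):
        path = str(tmp_path / "p.jplace")
        write_placements(path, rt, placements)
        return read_placements(path)

    def test_roundtrip_preserves_edges_and_lengths(self, tmp_path):
        rt = random_tree(12, seed=5)
        rng = np.random.default_rng(6)
        placements = []
        for i, num in enumerate(rt.edge_nums[:6]):
            b = rt.branch_length(num)
            placements.append(
                Placement(f"q{i}", num, float(rng.uniform(0, b)), 0.01 * (i + 1))
            )
        rt2, back = self._roundtrip(tmp_path, rt, placements)
        assert sorted(rt2.leaf_labels) == sorted(rt.leaf_labels)
        by_id = {p.query_id: p for p in back}
        for p in placements:
            q = by_id[p.query_id]
            assert q.edge_num == p.edge_num
            assert q.distal_length == pytest.approx(p.distal_length, abs=1e-9)
            assert q.pendant_length == pytest.approx(p.pendant_length, abs=1e-9)
        # and the re-read tree preserves branch lengths
        for num in rt.edge_nums:
            assert rt2.branch_length(num) == pytest.approx(
                rt.branch_length(num), abs=1e-9
            )

    def test_best_placement_flagging(self, tmp_path):
        rt = ReferenceTree.from_newick("((A:0.1,B:0.1):0.1,C:0.2);")
        doc = {
            "version": 3,
            "tree": rt.to_newick(edge_numbers=True),
            "fields": [
                "edge_num",
                "likelihood",
                "like_weight_ratio",
                "distal_length",
                "pendant_length",
            ],
            "placements": [
                {"p": [[0, -10.0, 0.7, 0.0, 0.01], [1, -11.0, 0.3, 0.0, 0.01]],
                 "n": ["q1"]}
            ],
        }
        path = tmp_path / "two.jplace"
        path.write_text(json.dumps(doc))
        _, placements = read_placements(str(path))
        best = [p for p in placements if p.is_best]
        assert len(best) == 1
        assert best[0].edge_num == 0 and best[0].like_weight_ratio == 0.7

    def test_unknown_edge_names_query(self, tmp_path):
        rt = ReferenceTree.from_newick("(A:0.1,B:0.2);")
        doc = {
            "version": 3,
            "tree": rt.to_newick(edge_numbers=True),
            "fields": ["edge_num", "distal_length", "pendant_length"],
            "placements": [{"p": [[99, 0.0, 0.0]], "n": ["lost_query"]}],
        }
        path = tmp_path / "bad.jplace"
        path.write_text(json.dumps(doc))
        with pytest.raises(JplaceError, match="lost_query"):
            read_placements(str(path))

    def test_malformed_json_is_io_error(self, tmp_path):
        path = tmp_path / "broken.jplace"
        path.write_text("{not json")
        with pytest.raises(JplaceError, match="JSON"):
            read_placements(str(path))

    def test_tie_breaks_to_smallest_edge_number(self):
        ps = [
            Placement("q", 5, 0, 0, like_weight_ratio=0.5, is_best=False),
            Placement("q", 2, 0, 0, like_weight_ratio=0.5, is_best=False),
        ]
        assert best_placements(ps)[0].edge_num == 2
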