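"""Patristic distances, conserved-rank inference, and empirical k choice."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nifsip.placement import Placement, ReferenceTree
from nifsip.synth import clade_queries, clade_tree, random_tree
from nifsip.taxonomy import (
    ClassifierConfig,
    DistanceMap,
    classify,
    identity_report,
    infer_taxonomy,
    inspection_report,
    neighbors_within_k,
    optimize_k,
    patristic_distances,
    percent_identity,
)
from tests.test_placement import graft_oracle_distances


class TestPatristicDistances:
    def test_two_leaf_hand_sum(self, two_leaf_tree):
        """Query mid-way on the 0.10 branch (distal 0.05, pendant 0.02):
        distances are A: 0.02+0.05 = 0.07 and B: 0.02+0.05+0.20 = 0.27."""
        rt = two_leaf_tree
        p = Placement("q", rt.edge_num_for_leaf("A"), 0.05, 0.02)
        dmap = patristic_distances(rt, p)
        assert dmap.distances["A"] == pytest.approx(0.07)
        assert dmap.distances["B"] == pytest.approx(0.27)

    def test_zero_pendant_at_leaf_node_gives_zero_distance(self, two_leaf_tree):
        rt = two_leaf_tree
        p = Placement("q", rt.edge_num_for_leaf("A"), 0.0, 0.0)
        assert patristic_distances(rt, p).distances["A"] == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_graft_and_path_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rt = random_tree(10, seed=seed)
        num = int(rng.choice(rt.edge_nums))
        p = Placement(
            "q",
            num,
            float(rng.uniform(0, rt.branch_length(num))),
            float(rng.uniform(0, 0.1)),
        )
        mine = patristic_distances(rt, p).distances
        oracle = graft_oracle_distances(rt, p)
        for lab in rt.leaf_labels:
            assert mine[lab] == pytest.approx(oracle[lab], abs=1e-9)


class TestNeighbors:
    def test_strict_inequality_boundary(self):
        dmap = DistanceMap("q", {"a": 0.40, "b": 0.47, "c": 0.48, "d": 0.50})
        assert neighbors_within_k(dmap, 0.48) == {"a", "b"}

    def test_all_at_zero_gives_full_set(self):
        dmap = DistanceMap("q", {"a": 0.0, "b": 0.0})
        assert neighbors_within_k(dmap, 0.1) == {"a", "b"}

    def test_nearest_neighbor_just_beyond_k_stays_unclassified(self):
        """The published boundary case: nearest reference at 0.49 with
        k = 0.48 leaves the query unclassified."""
        dmap = DistanceMap("q", {"ref": 0.49})
        nb = neighbors_within_k(dmap, 0.48)
        a = infer_taxonomy("q", nb, {"ref": (("phylum", "P"),)}, dmap=dmap)
        assert a.status == "unclassified" and a.lineage == ()

    @given(
        st.dictionaries(
            st.text(alphabet="abcdef", min_size=1, max_size=3),
            st.floats(min_value=0, max_value=2, allow_nan=False),
            min_size=1,
            max_size=12,
        ),
        st.floats(min_value=0.01, max_value=1.0),
        st.floats(min_value=0.01, max_value=1.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_neighbor_set_monotone_in_k(self, dists, k1, k2):
        dmap = DistanceMap("q", dists)
        lo, hi = sorted((k1, k2))
        assert neighbors_within_k(dmap, lo) <= neighbors_within_k(dmap, hi)


LIN_A = (("domain", "Bacteria"), ("phylum", "Proteobacteria"),
         ("class", "Deltaproteobacteria"), ("order", "Desulfuromonadales"),
         ("family", "Desulfuromonadaceae"), ("genus", "Desulfuromonas"))


def _lin(**kw):
    out = []
    for rank in ("domain", "phylum", "class", "order", "family", "genus", "species"):
        if rank in kw:
            out.append((rank, kw[rank]))
    return tuple(out)


class TestInferTaxonomy:
    def test_full_unanimity_reaches_genus(self):
        lineages = {"r1": LIN_A, "r2": LIN_A}
        a = infer_taxonomy("q", frozenset({"r1", "r2"}), lineages)
        assert a.status == "classified"
        assert a.depth_achieved == "genus"
        assert a.rank_name("genus") == "Desulfuromonas"

    def test_phylum_conflict_blocks_assignment(self):
        """A single foreign-phylum neighbour (the Acidobacteria vs
        Desulfovibrio situation) leaves the query unclassified at phylum —
        never assigned to either phylum."""
        lineages = {
            "acido": _lin(domain="Bacteria", phylum="Acidobacteria",
                          genus="Holophaga"),
            "dv": _lin(domain="Bacteria", phylum="Proteobacteria",
                       genus="Desulfovibrio"),
        }
        a = infer_taxonomy("q", frozenset(lineages), lineages)
        assert a.status == "unclassified"
        assert a.rank_name("phylum") is None
        assert a.depth_achieved == "domain"

    def test_agreement_truncates_at_class_when_orders_differ(self):
        lineages = {
            "x": _lin(domain="B", phylum="P", **{"class": "C"}, order="O1"),
            "y": _lin(domain="B", phylum="P", **{"class": "C"}, order="O2"),
        }
        a = infer_taxonomy("q", frozenset(lineages), lineages)
        assert a.status == "classified" and a.depth_achieved == "class"

    def test_absent_rank_truncates_rather_than_skips(self):
        lineages = {
            "x": _lin(domain="B", phylum="P", **{"class": "C"}, order="O"),
            "y": _lin(domain="B", phylum="P", order="O"),  # class missing
        }
        a = infer_taxonomy("q", frozenset(lineages), lineages)
        assert a.depth_achieved == "phylum"

    def test_empty_neighbors_unclassified(self):
        a = infer_taxonomy("q", frozenset(), {})
        assert a.status == "unclassified" and a.lineage == ()

    def test_lineage_free_neighbor_warns_and_is_excluded(self):
        lineages = {"r1": LIN_A}
        with pytest.warns(UserWarning, match="no lineage"):
            a = infer_taxonomy("q", frozenset({"r1", "ghost"}), lineages)
        assert a.status == "classified" and a.depth_achieved == "genus"


class TestSyntheticCladeRecovery:
    def test_pure_clade_queries_fully_recovered_at_default_k(self):
        """With rank-consistent clades and no HGT, every query lands in the
        clade's lineage at the deepest unanimous rank (genus here)."""
        ct = clade_tree(seed=3)
        placements, truth, _ = clade_queries(ct, seed=4)
        assignments = classify(ct.rt, placements)
        assert all(a.status == "classified" for a in assignments)
        for a in assignments:
            assert a.rank_name("phylum") == truth[a.query_id]
            assert a.depth_achieved == "genus"

    def test_hgt_leaf_flips_to_unclassified_never_wrong(self):
        """Injecting one foreign-phylum leaf inside a clade turns every
        query whose neighbourhood contains it into unclassified-at-phylum;
        no query is ever assigned the wrong phylum."""
        hgt = clade_tree(seed=5, n_hgt=1)
        placements, truth, _ = clade_queries(hgt, seed=6)
        (hgt_label, host_phylum), = hgt.hgt_leaves.items()
        assignments = classify(hgt.rt, placements)
        flipped = 0
        for a in assignments:
            if hgt_label in a.neighbor_ids:
                flipped += 1
                assert a.rank_name("phylum") is None
            else:
                assert a.rank_name("phylum") == truth[a.query_id]
        # the contaminated clade really did host queries
        assert flipped >= 1

    def test_geometry_matches_stated_radii(self):
        """Clade diameter <= 0.30 and between-phylum leaf separation >= 0.6
        hold by construction."""
        ct = clade_tree(seed=0)
        D = ct.rt.node_leaf_distances()
        idx = {lab: i for i, lab in enumerate(ct.rt.leaf_labels)}
        leaf_nodes = {
            lf.taxon.label: ct.rt._node_index[id(lf)]
            for lf in ct.rt.tree.leaf_node_iter()
        }
        for phylum, labels in ct.clades.items():
            for a in labels:
                for b in labels:
                    assert D[leaf_nodes[a], idx[b]] <= 0.30 + 1e-9
        phyla = list(ct.clades)
        for p1 in phyla:
            for p2 in phyla:
                if p1 >= p2:
                    continue
                for a in ct.clades[p1]:
                    for b in ct.clades[p2]:
                        assert D[leaf_nodes[a], idx[b]] >= 0.6


class TestOptimizeK:
    def test_single_reference_smallest_sufficient_k(self):
        rt = ReferenceTree.from_newick(
            "(R:0.1,X:0.9);", leaf_lineages={"R": _lin(domain="B", phylum="P"),
                                             "X": _lin(domain="B", phylum="Q")}
        )
        p = Placement("q", rt.edge_num_for_leaf("R"), 0.0, 0.1)
        res = optimize_k(rt, [p], grid=[0.05, 0.1, 0.15, 0.2])
        assert res.k_star == 0.15  # smallest grid value exceeding d = 0.1

    def test_curve_peaks_between_clade_radius_and_separation(self):
        """Annotated counts rise, plateau while neighbourhoods stay pure,
        and fall once cross-phylum references enter; the peak (smallest
        maximising k) sits in [0.3, 0.6)."""
        ct = clade_tree(seed=0)
        placements, truth, _ = clade_queries(ct, seed=1)
        res = optimize_k(ct.rt, placements)
        assert res.max_annotated == len(placements)
        assert 0.3 <= res.k_star < 0.6
        curve = res.curve.set_index("k")["annotated"]
        assert curve.loc[1.0] < res.max_annotated  # conflicts at large k
        # tie-break: no smaller k on the grid achieves the maximum
        assert (curve.loc[: res.k_star - 0.005] < res.max_annotated).all()

    def test_grid_validation(self):
        ct = clade_tree(seed=0)
        with pytest.raises(ValueError):
            optimize_k(ct.rt, [], grid=[])
        with pytest.raises(ValueError):
            optimize_k(ct.rt, [], grid=[0.2, 0.1])


class TestIdentityAndInspection:
    def test_percent_identity_arithmetic(self):
        assert percent_identity("ACGT", "ACGT") == 100.0
        a = "A" * 100
        b = "A" * 81 + "C" * 19
        assert percent_identity(a, b) == pytest.approx(81.0)

    def test_identity_report_summary_matches_hand_computation(self):
        qseqs = {f"q{i}": s for i, s in enumerate(
            ["AAAA", "AAAC", "AACC", "ACCC", "AAAA"])}
        rseqs = {"r": "AAAA"}
        idents = [100.0, 75.0, 50.0, 25.0, 100.0]
        assignments = [
            infer_taxonomy(
                f"q{i}", frozenset({"r"}), {"r": LIN_A},
                dmap=DistanceMap(f"q{i}", {"r": 0.1}),
            )
            for i in range(5)
        ]
        df, summary = identity_report(assignments, qseqs, rseqs)
        assert summary["mean"] == pytest.approx(np.mean(idents))
        assert summary["sd"] == pytest.approx(np.std(idents, ddof=1))
        assert summary["min"] == 25.0

    def test_inspection_report_flags(self):
        lineages = {
            "a1": _lin(domain="B", phylum="Acidobacteria"),
            "a2": _lin(domain="B", phylum="Acidobacteria"),
            "p1": _lin(domain="B", phylum="Proteobacteria"),
        }
        consistent = infer_taxonomy("qc", frozenset(), lineages)
        mixed = infer_taxonomy("qm", frozenset(), lineages)
        lonely = infer_taxonomy("ql", frozenset(), lineages)
        dmaps = {
            "qc": DistanceMap("qc", {"a1": 0.55, "a2": 0.6, "p1": 2.0}),
            "qm": DistanceMap("qm", {"a1": 0.55, "p1": 0.6, "a2": 2.0}),
            "ql": DistanceMap("ql", {"a1": 2.0, "a2": 2.0, "p1": 2.0}),
        }
        df = inspection_report(
            [consistent, mixed, lonely], dmaps, lineages, k_loose=0.7
        )
        flags = dict(zip(df["query_id"], df["flag"]))
        assert flags == {
            "qc": "consistent cluster",
            "qm": "no consistent signature",
            "ql": "no neighbors",
        }

    def test_k_loose_must_exceed_k(self):
        with pytest.raises(ValueError):
            inspection_report([], {}, {}, k_loose=0.1, k=0.48)
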