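"""Skeleton construction, level expansion and whole-graph conservation."""

import pytest

from oracles import random_digraph, skeleton_oracle

from skelenet.graph import build_graph, compute_stats
from skelenet.levels import build_skeleton, decompose, expand_levels, whole_graph
from skelenet.model import WHOLE, DriverClass, InteractionType
from conftest import edge


class TestBuildSkeleton:
    def test_off_path_branches_excluded(self):
        """A branch leading to no driver is not part of any driver-pair path."""
        graph = build_graph(
            [edge("D1", "X"), edge("X", "D2"), edge("D1", "Y")],
            {"D1": DriverClass.SYNDROMIC, "D2": DriverClass.SYNDROMIC},
        )
        skeleton = build_skeleton(graph, ["D1", "D2"])
        assert skeleton.nodes == {"D1", "X", "D2"}
        assert skeleton.edges == {("D1", "X"), ("X", "D2")}

    def test_all_tied_shortest_paths_kept(self):
        """Both branches of equal length belong to the skeleton, not just one."""
        graph = build_graph(
            [edge("D1", "A"), edge("A", "D2"), edge("D1", "B"), edge("B", "D2")],
            {"D1": DriverClass.SYNDROMIC, "D2": DriverClass.SYNDROMIC},
        )
        skeleton = build_skeleton(graph, ["D1", "D2"])
        assert skeleton.nodes == {"D1", "A", "B", "D2"}

    def test_disconnected_drivers_reported(self):
        graph = build_graph([], {"D1": DriverClass.SYNDROMIC, "D2": DriverClass.SYNDROMIC})
        skeleton = build_skeleton(graph, ["D1", "D2"])
        assert skeleton.nodes == set() and skeleton.edges == set()
        assert skeleton.unconnected_drivers == ["D1", "D2"]

    def test_single_driver_is_an_error(self):
        graph = build_graph([edge("A", "B")], {"A": DriverClass.SYNDROMIC})
        with pytest.raises(ValueError, match="at least 2"):
            build_skeleton(graph, ["A"])

    def test_tuple_unpacking(self, worked):
        graph, example = worked
        nodes, edges = build_skeleton(graph, example.drivers)
        assert nodes == example.expected_skeleton_nodes

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_union_oracle(self, seed):
        graph, drivers = random_digraph(seed)
        skeleton = build_skeleton(graph, drivers)
        nodes, edges, unconnected = skeleton_oracle(graph, drivers)
        assert skeleton.nodes == nodes
        assert skeleton.edges == edges
        assert skeleton.unconnected_drivers == unconnected


class TestExpandLevels:
    def test_chain_levels_and_saturation(self, chain):
        """D1 -> D2 <- A <- B <- C: A, B, C arrive at levels 1, 2, 3."""
        decomposition = expand_levels(chain, {"D1", "D2"})
        assert decomposition.level_of == {"D1": 0, "D2": 0, "A": 1, "B": 2, "C": 3}
        assert decomposition.saturation_level == 3
        assert [row.new_nodes for row in decomposition.per_level] == [2, 1, 1, 1]

    def test_already_saturated_skeleton(self):
        graph = build_graph([edge("A", "B")])
        decomposition = expand_levels(graph, {"A", "B"})
        assert decomposition.saturation_level == 0
        assert [row.new_nodes for row in decomposition.per_level] == [2]

    def test_isolated_node_labelled_whole(self, worked):
        graph, example = worked
        decomposition = expand_levels(graph, example.expected_skeleton_nodes)
        assert decomposition.level_of["RBP3"] == WHOLE
        assert decomposition.level_of["MT-ND4"] == WHOLE

    def test_max_level_truncates(self, chain):
        decomposition = expand_levels(chain, {"D1", "D2"}, max_level=1)
        assert decomposition.saturation_level == 1
        assert decomposition.level_of["B"] == WHOLE

    def test_within_level_edges_counted_at_arrival(self, worked):
        """Edges joining two same-level newcomers count at that level."""
        graph, example = worked
        decomposition = expand_levels(graph, example.expected_skeleton_nodes)
        rows = {row.level: row for row in decomposition.per_level}
        # level 1 adds 6 nodes and 7 induced edges (incl. the within-shell link)
        assert rows[1].new_nodes == 6 and rows[1].new_edges == 7
        assert rows[2].new_nodes == 5 and rows[2].new_edges == 6

    def test_every_new_node_touches_previous_level(self, worked):
        graph, example = worked
        decomposition = expand_levels(graph, example.expected_skeleton_nodes)
        for symbol, level in decomposition.level_of.items():
            if isinstance(level, int) and level >= 1:
                contacts = graph.parents(symbol) | graph.children(symbol)
                assert any(
                    decomposition.level_of[c] == level - 1 for c in contacts
                ), symbol

    @pytest.mark.parametrize("seed", range(15))
    def test_monotone_nested_and_fixed_point(self, seed):
        graph, drivers = random_digraph(seed)
        skeleton = build_skeleton(graph, drivers)
        decomposition = expand_levels(graph, skeleton.nodes,
                                      unconnected_drivers=skeleton.unconnected_drivers)
        totals_n = [row.total_nodes for row in decomposition.per_level]
        totals_e = [row.total_edges for row in decomposition.per_level]
        assert totals_n == sorted(totals_n) and totals_e == sorted(totals_e)
        # strict node growth until saturation
        assert all(row.new_nodes > 0 for row in decomposition.per_level[1:])
        # fixed point: expanding the saturation set returns it unchanged
        saturated = {
            s for s, lv in decomposition.level_of.items() if isinstance(lv, int)
        }
        again = expand_levels(graph, saturated)
        assert again.saturation_level == 0
        # drivers are level 0 or unconnected
        for d in drivers:
            if d in skeleton.unconnected_drivers:
                assert decomposition.level_of[d] == WHOLE or d not in skeleton.nodes
            else:
                assert decomposition.level_of[d] == 0


class TestWholeGraph:
    def test_whole_is_identity_on_graph(self, worked):
        graph, example = worked
        _, decomposition = decompose(graph, example.drivers)
        nodes, edges = whole_graph(graph, decomposition)
        assert nodes == set(graph.nodes)
        assert edges == {(e.src, e.dst, e.itype) for e in graph.edges()}

    def test_remainder_edges_touch_whole_nodes(self, worked):
        graph, example = worked
        _, decomposition = decompose(graph, example.drivers)
        saturated = {s for s, lv in decomposition.level_of.items() if isinstance(lv, int)}
        _, all_edges = whole_graph(graph, decomposition)
        remainder = {
            (s, d, t) for s, d, t in all_edges if not (s in saturated and d in saturated)
        }
        for s, d, _ in remainder:
            assert decomposition.level_of[s] == WHOLE or decomposition.level_of[d] == WHOLE

    def test_totals_reconcile(self, worked):
        graph, example = worked
        _, decomposition = decompose(graph, example.drivers)
        last = decomposition.per_level[-1]
        whole_nodes, whole_edges = whole_graph(graph, decomposition)
        n_whole_only = len(decomposition.whole_nodes())
        assert last.total_nodes + n_whole_only == len(whole_nodes)
        saturated = {s for s, lv in decomposition.level_of.items() if isinstance(lv, int)}
        remainder = [
            e for e in whole_edges if not (e[0] in saturated and e[1] in saturated)
        ]
        assert last.total_edges + len(remainder) == len(whole_edges)


def test_worked_example_level_table(worked):
    """The bundled dataset reproduces its documented level decomposition."""
    graph, example = worked
    skeleton, decomposition = decompose(graph, example.drivers)
    assert decomposition.level_of == example.expected_levels
    assert decomposition.saturation_level == example.expected_saturation
    assert decomposition.unconnected_drivers == example.expected_unconnected_drivers
    # the self-loop island survives only in the whole graph
    assert decomposition.level_of["GRK1"] == WHOLE
    assert graph.edge_types_between("GRK1", "GRK1") == {InteractionType.UNKNOWN}


def test_skeleton_stats_mirror_structural_relation(worked):
    """In/out averages are each half of the average degree on the skeleton."""
    graph, example = worked
    skeleton, _ = decompose(graph, example.drivers)
    stats = compute_stats(graph, node_subset=skeleton.nodes)
    assert stats.avg_degree == pytest.approx(stats.avg_in_degree + stats.avg_out_degree)
    assert stats.avg_in_degree == pytest.approx(stats.avg_out_degree)
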