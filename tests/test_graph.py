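"""Gate semantics, propagation, design matrices and Boolean dynamics."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from logicnem.errors import CyclicGraphError, ValidationError
from logicnem.graph import (
    GATES,
    STRUCTURES,
    BooleanNetwork,
    Gate,
    PerturbationExperiment,
    SignalingGraph,
    all_structure_patterns,
    build_design_matrix,
    canonical_label,
    effect_pattern,
    gate_truth_table,
    propagate_perturbation,
    steady_state_general,
    transitive_closure,
)

from conftest import triple_experiments, triple_with_gate


class TestGateTruthTables:
    @pytest.mark.parametrize(
        "gate, table",
        [
            ("AND", {(0, 0): 0, (1, 0): 0, (0, 1): 0, (1, 1): 1}),
            ("OR", {(0, 0): 0, (1, 0): 1, (0, 1): 1, (1, 1): 1}),
            ("XOR", {(0, 0): 0, (1, 0): 1, (0, 1): 1, (1, 1): 0}),
            ("NOT-A", {(0, 0): 0, (1, 0): 0, (0, 1): 1, (1, 1): 0}),
            ("NOT-B", {(0, 0): 0, (1, 0): 1, (0, 1): 0, (1, 1): 0}),
        ],
    )
    def test_truth_tables(self, gate, table):
        assert gate_truth_table(gate) == table

    def test_wild_type_never_disrupted(self):
        for gate in GATES:
            assert gate_truth_table(gate)[(0, 0)] == 0

    def test_unknown_gate_rejected(self):
        with pytest.raises(ValidationError, match="NAND"):
            gate_truth_table("NAND")


class TestEffectPatterns:
    def test_known_patterns(self):
        assert effect_pattern("AND") == (0, 0, 1)
        assert effect_pattern("unconnected") == (0, 0, 0)
        assert effect_pattern("NOT-A") == (0, 1, 0)  # A masks B
        assert effect_pattern("NOT-B") == (1, 0, 0)

    def test_patterns_are_a_bijection_onto_the_8_triples(self):
        # oracle: enumerate all 2^3 binary triples directly
        all_triples = set(itertools.product((0, 1), repeat=3))
        patterns = all_structure_patterns()
        assert len(patterns) == 8
        assert set(patterns.values()) == all_triples

    def test_five_gates_three_reductions(self):
        gates = [s for s in STRUCTURES if s in GATES]
        reduced = [s for s in STRUCTURES if s not in GATES]
        assert len(gates) == 5 and len(reduced) == 3


class TestSignalingGraphValidation:
    def test_cycle_rejected(self):
        with pytest.raises(CyclicGraphError, match="steady_state_general"):
            SignalingGraph(("A", "B"), [("A", "B"), ("B", "A")])

    def test_two_parents_need_a_gate(self):
        with pytest.raises(ValidationError, match="no gate"):
            SignalingGraph(("A", "B", "C"), [("A", "C"), ("B", "C")])

    def test_in_degree_three_rejected(self):
        with pytest.raises(ValidationError, match="in-degree 3"):
            SignalingGraph(
                ("A", "B", "C", "D"),
                [("A", "D"), ("B", "D"), ("C", "D")],
                {"D": Gate("AND", "A", "B")},
            )

    def test_gate_parents_must_match_edges(self):
        with pytest.raises(ValidationError, match="gate at 'C'"):
            SignalingGraph(
                ("A", "B", "C"),
                [("A", "C"), ("B", "C")],
                {"C": Gate("AND", "A", "A")},
            )

    def test_json_round_trip(self, nested_graph):
        assert SignalingGraph.from_json(nested_graph.to_json()) == nested_graph

    def test_sif_export(self, nested_graph):
        lines = nested_graph.to_sif().strip().splitlines()
        assert len(lines) == 3
        assert "A\tregulates\tC" in lines


class TestPropagation:
    def test_nested_pathway_knockouts(self, nested_graph):
        # perturbing A hits A, C and D; perturbing D only D
        assert propagate_perturbation(nested_graph, ["A"]).tolist() == [1, 0, 1, 1]
        assert propagate_perturbation(nested_graph, ["D"]).tolist() == [0, 0, 0, 1]
        assert propagate_perturbation(nested_graph, ["B"]).tolist() == [0, 1, 0, 1]

    def test_wild_type_all_zero(self, nested_graph):
        assert propagate_perturbation(nested_graph, []).sum() == 0

    def test_and_gate_needs_both_parents(self, and_triple):
        assert propagate_perturbation(and_triple, ["X"]).tolist() == [1, 0, 0]
        assert propagate_perturbation(and_triple, ["X", "Y"]).tolist() == [1, 1, 1]

    def test_unknown_gene_named_in_error(self, and_triple):
        with pytest.raises(ValidationError, match="Q"):
            propagate_perturbation(and_triple, ["Q"])

    @pytest.mark.parametrize("gate", ["AND", "OR"])
    def test_monotone_gates(self, gate, rng):
        """For AND/OR, enlarging the knockout set never removes disruptions."""
        g = triple_with_gate(gate)
        subsets = [frozenset(s) for r in range(4) for s in itertools.combinations("XYZ", r)]
        for small in subsets:
            for big in subsets:
                if small <= big:
                    d_small = propagate_perturbation(g, small)
                    d_big = propagate_perturbation(g, big)
                    assert (d_big >= d_small).all()

    def test_masking_gates_are_non_monotone(self):
        g = triple_with_gate("NOT-B")
        # X alone disrupts Z, adding Y rescues it
        assert propagate_perturbation(g, ["X"])[2] == 1
        assert propagate_perturbation(g, ["X", "Y"])[2] == 0


class TestDesignMatrix:
    def test_nested_matrix(self, nested_graph):
        phi = build_design_matrix(nested_graph, ["A", "B", "C", "D"])
        expected = np.array(
            [[1, 0, 1, 1], [0, 1, 0, 1], [0, 0, 1, 1], [0, 0, 0, 1]], dtype=np.uint8
        )
        assert np.array_equal(phi.states, expected)

    def test_empty_experiment_list(self, nested_graph):
        phi = build_design_matrix(nested_graph, [])
        assert phi.states.shape == (0, 4)

    def test_wild_type_row_zero(self, nested_graph):
        phi = build_design_matrix(nested_graph, ["WT", "A"])
        assert phi.row("WT").sum() == 0

    @pytest.mark.parametrize("gate", STRUCTURES)
    def test_child_column_matches_effect_pattern(self, gate):
        if gate in GATES:
            g = triple_with_gate(gate)
        elif gate == "A-only":
            g = SignalingGraph(("X", "Y", "Z"), [("X", "Z")])
        elif gate == "B-only":
            g = SignalingGraph(("X", "Y", "Z"), [("Y", "Z")])
        else:
            g = SignalingGraph(("X", "Y", "Z"))
        phi = build_design_matrix(g, ["X", "Y", "X:Y"])
        assert tuple(phi.states[:, 2]) == effect_pattern(gate)

    def test_unknown_gene_in_knockout(self, nested_graph):
        with pytest.raises(ValidationError, match="Q"):
            build_design_matrix(nested_graph, [["A", "Q"]])


def _random_dag(rng, n=4):
    order = rng.permutation(n)
    genes = tuple(f"g{i}" for i in range(n))
    edges = []
    in_deg = [0] * n
    for a in range(n):
        for b in range(a + 1, n):
            u, v = int(order[a]), int(order[b])
            if in_deg[v] < 1 and rng.random() < 0.4:
                edges.append((genes[u], genes[v]))
                in_deg[v] += 1
    return SignalingGraph(genes, edges)


class TestTransitiveClosure:
    def test_chain_closure(self):
        g = SignalingGraph(("A", "B", "C"), [("A", "B"), ("B", "C")])
        assert ("A", "C") in transitive_closure(g).edges

    def test_idempotent(self, nested_graph):
        once = transitive_closure(nested_graph)
        assert transitive_closure(once).edges == once.edges

    def test_matches_brute_force_reachability(self, rng):
        for _ in range(20):
            g = _random_dag(rng)
            closed = set(transitive_closure(g).edges)
            nxg = g.to_networkx()
            oracle = {
                (u, v)
                for u in g.nodes
                for v in g.nodes
                if u != v and nx.has_path(nxg, u, v)
            }
            assert closed == oracle


class TestSteadyStateGeneral:
    def test_matches_propagation_on_acyclic_graphs_exhaustively(self):
        """All 2^n knockout sets of small acyclic graphs give the same answer."""
        graphs = [
            triple_with_gate(g) for g in GATES
        ] + [SignalingGraph(("X", "Y", "Z"), [("X", "Y"), ("Y", "Z")])]
        for graph in graphs:
            for r in range(len(graph.nodes) + 1):
                for ko in itertools.combinations(graph.nodes, r):
                    att = steady_state_general(graph, ko)
                    assert att.is_fixed_point
                    disruption = [1 - s for s in att.states[0]]
                    assert disruption == propagate_perturbation(graph, ko).tolist()

    def test_mutual_activation_fixed_point_all_active(self):
        net = BooleanNetwork(
            ("A", "B"), {"A": (("B",), lambda b: b), "B": (("A",), lambda a: a)}
        )
        att = steady_state_general(net)
        assert att.is_fixed_point and att.states[0] == (1, 1)

    def test_mutual_repression_two_cycle(self):
        net = BooleanNetwork(
            ("A", "B"),
            {"A": (("B",), lambda b: 1 - b), "B": (("A",), lambda a: 1 - a)},
        )
        att = steady_state_general(net)
        assert att.period == 2

    def test_negative_feedback_limit_cycle(self):
        """A activates B, B represses A: the synchronous map is a 4-cycle.

        Oracle: by hand, (1,1)->(0,1)->(0,0)->(1,0)->(1,1) visits all four
        states, so the attractor is a limit cycle of period 4.
        """
        net = BooleanNetwork(
            ("A", "B"),
            {"A": (("B",), lambda b: 1 - b), "B": (("A",), lambda a: a)},
        )
        att = steady_state_general(net)
        assert not att.is_fixed_point
        assert att.period == 4

    def test_knockout_clamped(self):
        net = BooleanNetwork(
            ("A", "B"), {"B": (("A",), lambda a: a)}
        )
        att = steady_state_general(net, knockout=["A"])
        assert att.fixed_point() == {"A": 0, "B": 0}


class TestLabels:
    def test_canonical_double_label_sorted(self):
        assert canonical_label(["Y", "X"]) == "X:Y"
        assert PerturbationExperiment.from_label("X:Y").knocked_out == frozenset("XY")

    def test_wild_type_label(self):
        assert PerturbationExperiment(()).label == "WT"


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_design_matrix_invariant_under_node_relabeling(seed):
    """Permuting gene names permutes rows/columns but not the content."""
    rng = np.random.default_rng(seed)
    g = triple_with_gate(GATES[int(rng.integers(5))])
    exps = triple_experiments()
    phi = build_design_matrix(g, exps)
    perm = rng.permutation(3)
    rename = {old: f"n{perm[i]}" for i, old in enumerate(g.nodes)}
    g2 = SignalingGraph(
        tuple(rename[v] for v in g.nodes),
        [(rename[p], rename[c]) for p, c in g.edges],
        {
            rename[c]: Gate(gt.label, rename[gt.parent_a], rename[gt.parent_b])
            for c, gt in g.gates.items()
        },
    )
    exps2 = [PerturbationExperiment([rename[v] for v in e.knocked_out]) for e in exps]
    phi2 = build_design_matrix(g2, exps2)
    assert np.array_equal(phi.states, phi2.states)
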