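"""Logic-annotated signaling graphs and expected perturbation effects.

A signaling pathway is a directed acyclic graph over perturbed genes
(S-genes).  Perturbation effects propagate downstream: a knockout disrupts
the gene itself and, through the edges, the signal arriving at its
descendants.  A node with exactly two parents carries one of five binary
logic gates -- AND, OR, XOR, NOT-A, NOT-B -- that states how the disruption
indicators of the two incoming signals combine into the disruption of the
child.  Gates are defined on *disruption* bits (1 = the incoming signal is
cut), not on activity states; with this convention the classic nested
effects model is exactly the all-OR special case, because any upstream
perturbation propagates.

Gate semantics (d = child disrupted, given parent-A / parent-B disruption):

========  =====================  ==============================
gate      d(pA, pB)              biological reading
========  =====================  ==============================
AND       pA AND pB              functional overlap / redundancy
OR        pA OR pB               no interaction (classic NEM)
XOR       pA XOR pB              mutual prevention
NOT-A     (NOT pA) AND pB        A masks the effect of B
NOT-B     pA AND (NOT pB)        B masks the effect of A
========  =====================  ==============================

All five gates satisfy d(0, 0) = 0, so the wild type never shows an
expected effect.  The remaining three of the 2^3 response patterns over the
experiments (A knocked out, B knocked out, both) are reducible to simpler
graphs -- keep only the A edge, only the B edge, or neither -- and are
handled as the reduced structure labels ``A-only``, ``B-only`` and
``unconnected``.

The masking orientation is fixed once here: NOT-A means knocking out A
*silences* B's effect (the masked partner's single-knockout effect vanishes
in the double), i.e. "A masks B".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import CyclicGraphError, ValidationError

GATES: tuple[str, ...] = ("AND", "OR", "XOR", "NOT-A", "NOT-B")
REDUCED_STRUCTURES: tuple[str, ...] = ("A-only", "B-only", "unconnected")
#: the 8 distinguishable two-parent response structures
STRUCTURES: tuple[str, ...] = GATES + REDUCED_STRUCTURES

WILD_TYPE_LABEL = "WT"

_GATE_FUNCS: dict[str, Callable[[int, int], int]] = {
    "AND": lambda a, b: a & b,
    "OR": lambda a, b: a | b,
    "XOR": lambda a, b: a ^ b,
    "NOT-A": lambda a, b: (1 - a) & b,
    "NOT-B": lambda a, b: a & (1 - b),
}

_STRUCTURE_FUNCS: dict[str, Callable[[int, int], int]] = {
    **_GATE_FUNCS,
    "A-only": lambda a, b: a,
    "B-only": lambda a, b: b,
    "unconnected": lambda a, b: 0,
}


def gate_truth_table(gate: str) -> dict[tuple[int, int], int]:
    """Full 4-entry truth table of a two-parent gate.

    Keys are ``(pA, pB)`` disruption bits of the ordered parents, the value
    is the child's disruption bit.  ``d(0, 0) == 0`` for every gate.
    """
    try:
        fn = _GATE_FUNCS[gate]
    except KeyError:
        raise ValidationError(
            f"unknown gate {gate!r}; expected one of {', '.join(GATES)}"
        ) from None
    return {(a, b): fn(a, b) for a in (0, 1) for b in (0, 1)}


def effect_pattern(label: str) -> tuple[int, int, int]:
    """Expected child effects ``(d_10, d_01, d_11)`` for a structure label.

    The three bits are the child's disruption when A alone, B alone, and
    both parents are knocked out.  Over the five gates plus the three
    reduced structures this is a bijection onto the 8 binary triples.
    """
    try:
        fn = _STRUCTURE_FUNCS[label]
    except KeyError:
        raise ValidationError(
            f"unknown structure {label!r}; expected one of {', '.join(STRUCTURES)}"
        ) from None
    return (fn(1, 0), fn(0, 1), fn(1, 1))


def canonical_label(knocked_out: Iterable[str]) -> str:
    """Canonical experiment label: sorted gene names joined by ':'."""
    genes = sorted(set(knocked_out))
    return ":".join(genes) if genes else WILD_TYPE_LABEL


@dataclass(frozen=True)
class PerturbationExperiment:
    """A single or double (or empty = wild-type) knockout experiment."""

    knocked_out: frozenset[str]

    def __init__(self, knocked_out: Iterable[str] = ()):
        object.__setattr__(self, "knocked_out", frozenset(knocked_out))

    @property
    def label(self) -> str:
        return canonical_label(self.knocked_out)

    @classmethod
    def from_label(cls, label: str) -> "PerturbationExperiment":
        label = label.strip()
        if label in ("", WILD_TYPE_LABEL, WILD_TYPE_LABEL.lower()):
            return cls(())
        return cls(label.split(":"))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PerturbationExperiment({self.label!r})"


@dataclass(frozen=True)
class Gate:
    """A gate annotation with ordered parent roles A and B."""

    label: str
    parent_a: str
    parent_b: str

    def evaluate(self, p_a: int, p_b: int) -> int:
        return _GATE_FUNCS[self.label](p_a, p_b)

    def normalized(self) -> "Gate":
        """Equivalent gate with parents in lexicographic order.

        Swapping the parent roles exchanges NOT-A and NOT-B and leaves the
        symmetric gates untouched.
        """
        if self.parent_a <= self.parent_b:
            return self
        label = {"NOT-A": "NOT-B", "NOT-B": "NOT-A"}.get(self.label, self.label)
        return Gate(label, self.parent_b, self.parent_a)


class SignalingGraph:
    """Acyclic directed graph over S-genes with per-child logic gates.

    Every node with in-degree 2 must carry a gate naming its two parents in
    the A/B roles; nodes with in-degree <= 1 carry none and in-degree > 2 is
    rejected (the model space considers logics between pairs of regulators
    only).
    """

    __slots__ = ("nodes", "edges", "gates", "_index", "_topo", "_parents", "_hash")

    def __init__(
        self,
        nodes: Sequence[str],
        edges: Iterable[tuple[str, str]] = (),
        gates: Mapping[str, Gate | tuple[str, str, str]] | None = None,
        *,
        _check_gates: bool = True,
    ):
        nodes = tuple(nodes)
        if len(set(nodes)) != len(nodes):
            raise ValidationError("duplicate node identifiers")
        node_set = set(nodes)
        edge_list = []
        seen = set()
        for parent, child in edges:
            if parent not in node_set or child not in node_set:
                raise ValidationError(f"edge ({parent!r}, {child!r}) references unknown node")
            if parent == child:
                raise ValidationError(f"self-loop at {parent!r}")
            if (parent, child) in seen:
                continue
            seen.add((parent, child))
            edge_list.append((parent, child))
        edge_tuple = tuple(sorted(edge_list))

        parents: dict[str, list[str]] = {v: [] for v in nodes}
        for parent, child in edge_tuple:
            parents[child].append(parent)

        gate_map: dict[str, Gate] = {}
        for child, gate in (gates or {}).items():
            if not isinstance(gate, Gate):
                gate = Gate(*gate)
            if gate.label not in GATES:
                raise ValidationError(f"unknown gate label {gate.label!r} at {child!r}")
            gate_map[child] = gate

        if _check_gates:
            for child, pars in parents.items():
                if len(pars) > 2:
                    raise ValidationError(
                        f"node {child!r} has in-degree {len(pars)}; "
                        "the model space allows at most two parents"
                    )
                if len(pars) == 2:
                    gate = gate_map.get(child)
                    if gate is None:
                        raise ValidationError(f"node {child!r} has two parents but no gate")
                    if {gate.parent_a, gate.parent_b} != set(pars):
                        raise ValidationError(
                            f"gate at {child!r} names parents "
                            f"({gate.parent_a!r}, {gate.parent_b!r}) "
                            f"but the edges give {sorted(pars)}"
                        )
                else:
                    if child in gate_map:
                        raise ValidationError(
                            f"node {child!r} has a gate but in-degree {len(pars)}"
                        )

        self.nodes = nodes
        self.edges = edge_tuple
        self.gates = dict(gate_map)
        self._index = {v: i for i, v in enumerate(nodes)}
        self._parents = {v: tuple(p) for v, p in parents.items()}
        self._topo = self._topological_order()
        self._hash = None

    # -- basic protocol -------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalingGraph):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.gates == other.gates
        )

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash((self.nodes, self.edges, tuple(sorted(self.gates.items()))))
        return self._hash

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        gates = {c: g.label for c, g in self.gates.items()}
        return f"SignalingGraph(nodes={list(self.nodes)}, edges={list(self.edges)}, gates={gates})"

    # -- structure ------------------------------------------------------

    def parents(self, node: str) -> tuple[str, ...]:
        return self._parents[node]

    def _topological_order(self) -> tuple[str, ...]:
        in_deg = {v: len(self._parents[v]) for v in self.nodes}
        children: dict[str, list[str]] = {v: [] for v in self.nodes}
        for parent, child in self.edges:
            children[parent].append(child)
        queue = [v for v in self.nodes if in_deg[v] == 0]
        order: list[str] = []
        while queue:
            v = queue.pop()
            order.append(v)
            for c in children[v]:
                in_deg[c] -= 1
                if in_deg[c] == 0:
                    queue.append(c)
        if len(order) != len(self.nodes):
            cycle_nodes = sorted(v for v in self.nodes if in_deg[v] > 0)
            raise CyclicGraphError(
                f"graph contains a directed cycle through {cycle_nodes}; "
                "use steady_state_general for cyclic Boolean networks"
            )
        return tuple(order)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def adjacency(self) -> np.ndarray:
        """Adjacency matrix in node order (parent row, child column)."""
        a = np.zeros((len(self.nodes), len(self.nodes)), dtype=np.uint8)
        for parent, child in self.edges:
            a[self._index[parent], self._index[child]] = 1
        return a

    def gated_triples(self) -> dict[str, tuple[tuple[str, str], str]]:
        """Map gated child -> (sorted parent pair, orientation-normalized gate)."""
        out = {}
        for child, gate in self.gates.items():
            g = gate.normalized()
            out[child] = ((g.parent_a, g.parent_b), g.label)
        return out

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "edges": [list(e) for e in self.edges],
            "gates": {
                c: {"label": g.label, "parent_a": g.parent_a, "parent_b": g.parent_b}
                for c, g in sorted(self.gates.items())
            },
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "SignalingGraph":
        gates = {
            c: Gate(g["label"], g["parent_a"], g["parent_b"])
            for c, g in payload.get("gates", {}).items()
        }
        return cls(payload["nodes"], [tuple(e) for e in payload["edges"]], gates)

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "SignalingGraph":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls.from_dict(payload)

    def to_sif(self, path=None, interaction: str = "regulates") -> str:
        """SIF export: one ``parent <interaction> child`` line per edge."""
        lines = [f"{p}\t{interaction}\t{c}" for p, c in self.edges]
        text = "\n".join(lines) + ("\n" if lines else "")
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def propagate_perturbation(
    graph: SignalingGraph,
    knockout: PerturbationExperiment | Iterable[str],
) -> np.ndarray:
    """Disruption state of every S-gene after a knockout, in node order.

    Directly knocked-out genes are disrupted irreversibly; the remaining
    genes are evaluated in topological order -- a single-parent child
    inherits the parent's disruption bit, a two-parent child applies its
    gate to the parents' bits.  Requires an acyclic graph (guaranteed by
    ``SignalingGraph``); cyclic Boolean networks go through
    ``steady_state_general``.
    """
    if isinstance(knockout, PerturbationExperiment):
        ko = knockout.knocked_out
    else:
        ko = frozenset(knockout)
    unknown = ko - set(graph.nodes)
    if unknown:
        raise ValidationError(f"knockout names unknown gene(s): {sorted(unknown)}")
    state: dict[str, int] = {}
    for node in graph._topo:
        if node in ko:
            state[node] = 1
            continue
        pars = graph._parents[node]
        if not pars:
            state[node] = 0
        elif len(pars) == 1:
            state[node] = state[pars[0]]
        else:
            gate = graph.gates[node]
            state[node] = gate.evaluate(state[gate.parent_a], state[gate.parent_b])
    return np.array([state[v] for v in graph.nodes], dtype=np.uint8)


class DesignMatrix:
    """Expected disruption of every S-gene under every experiment.

    Rows are experiments, columns S-genes; each row is exactly the
    propagation output for its experiment.
    """

    __slots__ = ("genes", "experiments", "states", "_row_index")

    def __init__(
        self,
        genes: Sequence[str],
        experiments: Sequence[PerturbationExperiment],
        states: np.ndarray,
    ):
        self.genes = tuple(genes)
        self.experiments = tuple(experiments)
        states = np.asarray(states, dtype=np.uint8)
        if states.shape != (len(self.experiments), len(self.genes)):
            raise ValidationError(
                f"state matrix shape {states.shape} does not match "
                f"{len(self.experiments)} experiments x {len(self.genes)} genes"
            )
        self.states = states
        self._row_index = {e.label: i for i, e in enumerate(self.experiments)}
        if len(self._row_index) != len(self.experiments):
            raise ValidationError("duplicate experiment labels in design matrix")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.experiments)

    def row(self, label: str) -> np.ndarray:
        try:
            return self.states[self._row_index[label]]
        except KeyError:
            raise ValidationError(f"no experiment {label!r} in design matrix") from None

    def restrict(self, labels: Sequence[str]) -> "DesignMatrix":
        idx = [self._row_index[lbl] for lbl in labels]
        return DesignMatrix(
            self.genes, [self.experiments[i] for i in idx], self.states[idx]
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.states, index=list(self.labels), columns=list(self.genes))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="experiment")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DesignMatrix):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.labels == other.labels
            and np.array_equal(self.states, other.states)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DesignMatrix(genes={list(self.genes)}, experiments={list(self.labels)})"


def build_design_matrix(
    graph: SignalingGraph,
    experiments: Sequence[PerturbationExperiment | str | Iterable[str]],
) -> DesignMatrix:
    """Stack propagation outputs for a list of experiments into a matrix."""
    exps: list[PerturbationExperiment] = []
    for e in experiments:
        if isinstance(e, PerturbationExperiment):
            exps.append(e)
        elif isinstance(e, str):
            exps.append(PerturbationExperiment.from_label(e))
        else:
            exps.append(PerturbationExperiment(e))
    if not exps:
        return DesignMatrix(graph.nodes, (), np.zeros((0, len(graph.nodes)), dtype=np.uint8))
    rows = [propagate_perturbation(graph, e) for e in exps]
    return DesignMatrix(graph.nodes, exps, np.stack(rows))


def transitive_closure(graph: SignalingGraph) -> SignalingGraph:
    """Reachability closure of the edge set; gate annotations are kept as-is.

    The closure may raise a node's in-degree above two, so the returned
    graph skips the gate/in-degree validation; it is meant for equivalence
    reasoning and edge-accuracy scoring, not for propagation.
    """
    closed = nx.transitive_closure_dag(graph.to_networkx())
    return SignalingGraph(graph.nodes, closed.edges(), graph.gates, _check_gates=False)


# -- general synchronous Boolean dynamics -------------------------------


@dataclass(frozen=True)
class Attractor:
    """Outcome of synchronous iteration: a fixed point or a limit cycle."""

    nodes: tuple[str, ...]
    states: tuple[tuple[int, ...], ...]

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1

    @property
    def period(self) -> int:
        return len(self.states)

    def fixed_point(self) -> dict[str, int]:
        if not self.is_fixed_point:
            raise ValidationError(f"attractor is a limit cycle of period {self.period}")
        return dict(zip(self.nodes, self.states[0]))


class BooleanNetwork:
    """A synchronous Boolean network in activity space (1 = active).

    ``functions`` maps each node to ``(inputs, fn)``; a node with no entry
    keeps its state (a source holds its initial value).  Built from a
    ``SignalingGraph`` by negating the disruption-space gate logic, so that
    on acyclic graphs the steady state reproduces ``propagate_perturbation``.
    """

    def __init__(self, nodes: Sequence[str], functions: Mapping[str, tuple[Sequence[str], Callable]]):
        self.nodes = tuple(nodes)
        idx = {v: i for i, v in enumerate(self.nodes)}
        self._compiled = {}
        for node, (inputs, fn) in functions.items():
            if node not in idx:
                raise ValidationError(f"update rule for unknown node {node!r}")
            self._compiled[idx[node]] = ([idx[u] for u in inputs], fn)

    @classmethod
    def from_signaling_graph(cls, graph: SignalingGraph) -> "BooleanNetwork":
        functions = {}
        for node in graph.nodes:
            pars = graph._parents[node]
            if len(pars) == 1:
                functions[node] = (pars, lambda p: p)
            elif len(pars) == 2:
                gate = graph.gates[node]
                functions[node] = (
                    (gate.parent_a, gate.parent_b),
                    # activity = NOT gate(disruption_A, disruption_B)
                    lambda a, b, _g=gate: 1 - _g.evaluate(1 - a, 1 - b),
                )
        return cls(graph.nodes, functions)

    def step(self, state: tuple[int, ...], clamped_off: frozenset[int]) -> tuple[int, ...]:
        new = list(state)
        for i, (inputs, fn) in self._compiled.items():
            new[i] = int(fn(*(state[j] for j in inputs)))
        for i in clamped_off:
            new[i] = 0
        return tuple(new)


def steady_state_general(
    network: "BooleanNetwork | SignalingGraph",
    knockout: PerturbationExperiment | Iterable[str] = (),
    initial: Mapping[str, int] | None = None,
    max_steps: int = 4096,
) -> Attractor:
    """Synchronous attractor from the wild-type-active start with knockouts clamped.

    Iterates the synchronous update until a state repeats; returns the fixed
    point (period 1) or the limit cycle, rotated to start at its
    lexicographically smallest state for determinism.  Cyclic networks are
    allowed; for acyclic signaling graphs the fixed point's inactive set
    equals the ``propagate_perturbation`` disruption set.
    """
    if isinstance(network, SignalingGraph):
        network = BooleanNetwork.from_signaling_graph(network)
    if isinstance(knockout, PerturbationExperiment):
        ko = knockout.knocked_out
    else:
        ko = frozenset(knockout)
    idx = {v: i for i, v in enumerate(network.nodes)}
    unknown = ko - set(network.nodes)
    if unknown:
        raise ValidationError(f"knockout names unknown gene(s): {sorted(unknown)}")
    clamped = frozenset(idx[v] for v in ko)

    if initial is None:
        state = tuple(0 if i in clamped else 1 for i in range(len(network.nodes)))
    else:
        state = tuple(
            0 if i in clamped else int(initial[v]) for v, i in sorted(idx.items(), key=lambda kv: kv[1])
        )

    seen: dict[tuple[int, ...], int] = {}
    trajectory: list[tuple[int, ...]] = []
    for step in range(max_steps):
        if state in seen:
            cycle = trajectory[seen[state]:]
            pivot = min(range(len(cycle)), key=lambda k: cycle[k])
            cycle = tuple(cycle[pivot:] + cycle[:pivot])
            return Attractor(network.nodes, cycle)
        seen[state] = step
        trajectory.append(state)
        state = network.step(state, clamped)
    raise RuntimeError("no attractor within max_steps")  # pragma: no cover


def all_structure_patterns() -> dict[str, tuple[int, int, int]]:
    """The label -> (d_10, d_01, d_11) map for all 8 two-parent structures."""
    return {label: effect_pattern(label) for label in STRUCTURES}
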