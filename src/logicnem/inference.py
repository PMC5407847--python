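"""Structure search over logic-annotated signaling graphs.

The model space contains every labeled DAG over the S-genes with in-degree
at most two, each two-parent node expanded into one hypothesis per gate.
For up to five genes this space is enumerated exhaustively and every
hypothesis is scored with the marginal likelihood; for larger gene sets a
seeded greedy hill climber is provided.

Identifiability is limited: hypotheses with identical design matrices over
the measured experiments have identical scores.  Searches therefore report
equivalence classes (groups with byte-identical design matrices) and the
full top class, never a silently chosen single member; a canonical
representative (fewest edges, then lexicographic) is used only where a
single model is required.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import ValidationError
from .graph import (
    GATES,
    DesignMatrix,
    Gate,
    PerturbationExperiment,
    SignalingGraph,
    build_design_matrix,
    transitive_closure,
)
from .likelihood import EffectDataset, NoiseRates, attachment_log_likelihoods

__all__ = [
    "ModelHypothesis",
    "enumerate_models",
    "exhaustive_search",
    "greedy_search",
    "equivalence_partition",
    "top_equivalence_class",
    "EXHAUSTIVE_MAX_GENES",
]

EXHAUSTIVE_MAX_GENES = 5


@dataclass(frozen=True)
class ModelHypothesis:
    """A scored network hypothesis with its equivalence-class id."""

    graph: SignalingGraph
    score: float
    equivalence_class_id: int | None = None


def _canonical_key(graph: SignalingGraph) -> tuple:
    """Deterministic ordering key: fewest edges, then lexicographic."""
    gates = tuple(sorted((c, g.label, g.parent_a, g.parent_b) for c, g in graph.gates.items()))
    return (len(graph.edges), graph.edges, gates)


def _acyclic(n: int, edges: Sequence[tuple[int, int]]) -> bool:
    children: dict[int, list[int]] = {}
    in_deg = [0] * n
    for u, v in edges:
        children.setdefault(u, []).append(v)
        in_deg[v] += 1
    stack = [v for v in range(n) if in_deg[v] == 0]
    seen = 0
    while stack:
        u = stack.pop()
        seen += 1
        for w in children.get(u, ()):
            in_deg[w] -= 1
            if in_deg[w] == 0:
                stack.append(w)
    return seen == n


def enumerate_models(
    genes: Sequence[str],
    max_in_degree: int = 2,
    gates: Sequence[str] = GATES,
) -> Iterable[SignalingGraph]:
    """Yield every DAG over ``genes`` with bounded in-degree, gate-expanded.

    Each node that ends up with two parents is expanded into one hypothesis
    per gate label in ``gates`` (parents take the A/B roles in lexicographic
    order, which together with the NOT-A/NOT-B pair covers both
    orientations).  Restricting ``gates`` to ``("OR",)`` yields the classic
    no-logic nested-effects model space.
    """
    genes = tuple(genes)
    n = len(genes)
    if n < 2:
        raise ValidationError("need at least two genes to enumerate models")
    if n > EXHAUSTIVE_MAX_GENES:
        raise ValidationError(
            f"exhaustive enumeration supports at most {EXHAUSTIVE_MAX_GENES} genes "
            f"(got {n}); use greedy_search"
        )
    if max_in_degree not in (1, 2):
        raise ValidationError("max_in_degree must be 1 or 2")
    for g in gates:
        if g not in GATES:
            raise ValidationError(f"unknown gate label {g!r}")

    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    for mask in range(1 << len(pairs)):
        edges = [pairs[k] for k in range(len(pairs)) if mask >> k & 1]
        in_deg = [0] * n
        ok = True
        for _, v in edges:
            in_deg[v] += 1
            if in_deg[v] > max_in_degree:
                ok = False
                break
        if not ok or not _acyclic(n, edges):
            continue
        named_edges = [(genes[u], genes[v]) for u, v in edges]
        gated_children = [genes[v] for v in range(n) if in_deg[v] == 2]
        if not gated_children:
            yield SignalingGraph(genes, named_edges)
            continue
        parent_map: dict[str, list[str]] = {c: [] for c in gated_children}
        for p, c in named_edges:
            if c in parent_map:
                parent_map[c].append(p)
        for combo in itertools.product(gates, repeat=len(gated_children)):
            gate_map = {}
            for child, label in zip(gated_children, combo):
                pa, pb = sorted(parent_map[child])
                gate_map[child] = Gate(label, pa, pb)
            yield SignalingGraph(genes, named_edges, gate_map)


def _as_experiments(
    experiments: Sequence[PerturbationExperiment | str | Iterable[str]],
) -> tuple[PerturbationExperiment, ...]:
    out = []
    for e in experiments:
        if isinstance(e, PerturbationExperiment):
            out.append(e)
        elif isinstance(e, str):
            out.append(PerturbationExperiment.from_label(e))
        else:
            out.append(PerturbationExperiment(e))
    return tuple(out)


@lru_cache(maxsize=64)
def _model_space(genes: tuple[str, ...], gates: tuple[str, ...]) -> tuple[SignalingGraph, ...]:
    return tuple(enumerate_models(genes, gates=gates))


@lru_cache(maxsize=256)
def _design_tensor(
    genes: tuple[str, ...],
    gates: tuple[str, ...],
    labels: tuple[str, ...],
) -> tuple[tuple[SignalingGraph, ...], np.ndarray, np.ndarray]:
    """All hypotheses over ``genes`` with their stacked design matrices.

    Returns ``(models, F, class_ids)`` where F has shape
    (n_models, n_experiments, n_genes) and class_ids groups byte-identical
    design matrices (ids ordered by first occurrence).
    """
    models = _model_space(genes, gates)
    experiments = tuple(PerturbationExperiment.from_label(lbl) for lbl in labels)
    F = np.empty((len(models), len(experiments), len(genes)), dtype=np.uint8)
    for h, model in enumerate(models):
        F[h] = build_design_matrix(model, experiments).states
    class_ids = np.empty(len(models), dtype=np.intp)
    seen: dict[bytes, int] = {}
    for h in range(len(models)):
        key = F[h].tobytes()
        class_ids[h] = seen.setdefault(key, len(seen))
    return models, F, class_ids


def _score_design_tensor(
    data: EffectDataset,
    F: np.ndarray,
    rates: NoiseRates,
    chunk: int = 512,
) -> np.ndarray:
    """Marginal log-likelihood for a stack of design tensors at once.

    ``F`` has shape (H, n_experiments, n_genes); the dataset's experiment
    order must match axis 1.  Equivalent to calling
    ``marginal_log_likelihood`` per model, vectorized over models.
    """
    E = data.cells()  # (m, cells)
    m, n_cells = E.shape
    H, n_exp, n = F.shape
    Fx = np.repeat(F.astype(np.float64), data.replicates, axis=1)  # (H, cells, n)
    l00, l10, l01, l11 = rates.log_terms()
    finite = all(math.isfinite(t) for t in (l00, l10, l01, l11))
    scores = np.empty(H, dtype=np.float64)
    e_sum = E.sum(axis=1)  # ones per reporter
    logn = math.log(n)
    for start in range(0, H, chunk):
        Fb = Fx[start : start + chunk]  # (h, cells, n)
        n11 = np.einsum("mc,hcn->hmn", E, Fb, optimize=True)
        if finite:
            f_sum = Fb.sum(axis=1)  # (h, n)
            L = (
                n11 * (l11 - l10 - l01 + l00)
                + e_sum[None, :, None] * (l10 - l00)
                + f_sum[:, None, :] * (l01 - l00)
                + n_cells * l00
            )
        else:
            f_sum = Fb.sum(axis=1)
            n10 = e_sum[None, :, None] - n11
            n01 = f_sum[:, None, :] - n11
            n00 = n_cells - n11 - n10 - n01
            L = np.zeros_like(n11)
            for count, term in ((n00, l00), (n10, l10), (n01, l01), (n11, l11)):
                if math.isinf(term):
                    L = np.where(count > 0, -np.inf, L)
                else:
                    L = L + count * term
        per_reporter = logsumexp(L, axis=2) - logn  # (h, m)
        scores[start : start + chunk] = per_reporter.sum(axis=1)
    return scores


def _resolve_genes(
    data: EffectDataset,
    experiments: Sequence | None,
    genes: Sequence[str] | None,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Gene set and experiment labels for a search, defaulting from the data."""
    if experiments is None:
        labels = data.experiments
    else:
        labels = tuple(e.label for e in _as_experiments(experiments))
    if not labels:
        raise ValidationError("no experiments to score against")
    missing = [lbl for lbl in labels if lbl not in data.experiments]
    if missing:
        raise ValidationError(f"dataset lacks experiment column(s): {missing}")
    if genes is None:
        inferred: set[str] = set()
        for lbl in labels:
            inferred |= PerturbationExperiment.from_label(lbl).knocked_out
        genes = sorted(inferred)
    if not genes:
        raise ValidationError("could not determine the S-gene set")
    return tuple(genes), labels


def exhaustive_search(
    data: EffectDataset,
    experiments: Sequence | None = None,
    rates: NoiseRates = NoiseRates(),
    genes: Sequence[str] | None = None,
    gates: Sequence[str] = GATES,
) -> list[ModelHypothesis]:
    """Score every hypothesis in the model space; return them ranked.

    The gene set defaults to the union of knocked-out genes in the
    experiment labels.  Models are sorted by score descending; ties are
    broken by the canonical key so the ordering is deterministic, and each
    hypothesis carries the id of its design-matrix equivalence class.
    """
    gene_tuple, labels = _resolve_genes(data, experiments, genes)
    models, F, class_ids = _design_tensor(gene_tuple, tuple(gates), labels)
    sub = data.restrict(experiments=labels)
    scores = _score_design_tensor(sub, F, rates)
    order = sorted(range(len(models)), key=lambda h: (-scores[h], _canonical_key(models[h])))
    return [
        ModelHypothesis(models[h], float(scores[h]), int(class_ids[h])) for h in order
    ]


def top_equivalence_class(results: Sequence[ModelHypothesis]) -> list[ModelHypothesis]:
    """All members of the best-scoring equivalence class."""
    if not results:
        return []
    top_id = results[0].equivalence_class_id
    return [r for r in results if r.equivalence_class_id == top_id]


# -- greedy hill climbing ----------------------------------------------


def _neighbors(graph: SignalingGraph, gates: Sequence[str]) -> Iterable[SignalingGraph]:
    """Single-move neighborhood: edge insert/delete/reverse and gate swap."""
    nodes = graph.nodes
    edge_set = set(graph.edges)

    def try_build(edges, gate_map):
        try:
            return SignalingGraph(nodes, edges, gate_map)
        except ValidationError:
            return None

    # gate swaps
    for child, gate in graph.gates.items():
        for label in gates:
            if label != gate.label:
                gm = dict(graph.gates)
                gm[child] = Gate(label, gate.parent_a, gate.parent_b)
                g = try_build(graph.edges, gm)
                if g is not None:
                    yield g

    def gates_for(edges, changed_children):
        """Gate maps consistent with the new parent sets of changed nodes."""
        parent_map: dict[str, list[str]] = {v: [] for v in nodes}
        for p, c in edges:
            parent_map[c].append(p)
        base = {
            c: g for c, g in graph.gates.items() if len(parent_map[c]) == 2 and c not in changed_children
        }
        options: list[list[tuple[str, Gate]]] = []
        for child in changed_children:
            if len(parent_map[child]) == 2:
                pa, pb = sorted(parent_map[child])
                options.append([(child, Gate(label, pa, pb)) for label in gates])
        if not options:
            yield base
            return
        for combo in itertools.product(*options):
            gm = dict(base)
            gm.update(dict(combo))
            yield gm

    # deletions
    for edge in graph.edges:
        edges = [e for e in graph.edges if e != edge]
        for gm in gates_for(edges, {edge[1]}):
            g = try_build(edges, gm)
            if g is not None:
                yield g

    # insertions
    for u in nodes:
        for v in nodes:
            if u == v or (u, v) in edge_set:
                continue
            edges = list(graph.edges) + [(u, v)]
            for gm in gates_for(edges, {v}):
                g = try_build(edges, gm)
                if g is not None:
                    yield g

    # reversals
    for u, v in graph.edges:
        if (v, u) in edge_set:
            continue
        edges = [e for e in graph.edges if e != (u, v)] + [(v, u)]
        for gm in gates_for(edges, {u, v}):
            g = try_build(edges, gm)
            if g is not None:
                yield g


def _random_start(
    genes: tuple[str, ...], rng: np.random.Generator, gates: Sequence[str]
) -> SignalingGraph:
    """Random DAG with in-degree <= 2 and random gates, edge prob 0.3."""
    n = len(genes)
    order = rng.permutation(n)
    edges: list[tuple[str, str]] = []
    in_deg = [0] * n
    for a in range(n):
        for b in range(a + 1, n):
            u, v = int(order[a]), int(order[b])
            if in_deg[v] < 2 and rng.random() < 0.3:
                edges.append((genes[u], genes[v]))
                in_deg[v] += 1
    parent_map: dict[str, list[str]] = {g: [] for g in genes}
    for p, c in edges:
        parent_map[c].append(p)
    gate_map = {}
    for child, pars in parent_map.items():
        if len(pars) == 2:
            pa, pb = sorted(pars)
            gate_map[child] = Gate(str(rng.choice(gates)), pa, pb)
    return SignalingGraph(genes, edges, gate_map)


def greedy_search(
    data: EffectDataset,
    experiments: Sequence | None = None,
    rates: NoiseRates = NoiseRates(),
    restarts: int = 1,
    seed: int | None = None,
    genes: Sequence[str] | None = None,
    gates: Sequence[str] = GATES,
) -> ModelHypothesis:
    """Greedy hill climbing over the restricted DAG space.

    From a seeded random start, repeatedly scores the single-move
    neighborhood (edge insertion, deletion, reversal and gate swap, all
    keeping acyclicity and in-degree <= 2) and accepts the best strictly
    improving move until none exists.  The best model over ``restarts``
    independent starts is returned; identical seeds give identical output.
    """
    if restarts < 1:
        raise ValidationError("restarts must be >= 1")
    gene_tuple, labels = _resolve_genes(data, experiments, genes)
    sub = data.restrict(experiments=labels)
    experiments_resolved = tuple(PerturbationExperiment.from_label(lbl) for lbl in labels)
    rng = np.random.default_rng(seed)

    def score(graph: SignalingGraph) -> float:
        phi = build_design_matrix(graph, experiments_resolved)
        L = attachment_log_likelihoods(sub, phi, rates)
        per_reporter = logsumexp(L, axis=1) - math.log(len(gene_tuple))
        return float(per_reporter.sum())

    best: tuple[float, tuple, SignalingGraph] | None = None
    for _ in range(restarts):
        current = _random_start(gene_tuple, rng, gates)
        current_score = score(current)
        improved = True
        while improved:
            improved = False
            step_best: tuple[float, tuple, SignalingGraph] | None = None
            for cand in _neighbors(current, gates):
                s = score(cand)
                key = (-s, _canonical_key(cand))
                if step_best is None or key < (-step_best[0], step_best[1]):
                    step_best = (s, _canonical_key(cand), cand)
            if step_best is not None and step_best[0] > current_score:
                current, current_score = step_best[2], step_best[0]
                improved = True
        key = (-current_score, _canonical_key(current))
        if best is None or key < (-best[0], best[1]):
            best = (current_score, _canonical_key(current), current)
    assert best is not None
    return ModelHypothesis(best[2], best[0], None)


# -- equivalence analysis ----------------------------------------------


@dataclass(frozen=True)
class EquivalenceClass:
    """Models indistinguishable on the scored experiments."""

    members: tuple[SignalingGraph, ...]
    design: DesignMatrix
    same_transitive_closure: bool
    parent_chain_collapse: bool

    @property
    def representative(self) -> SignalingGraph:
        return min(self.members, key=_canonical_key)


def equivalence_partition(
    models: Sequence[SignalingGraph],
    experiments: Sequence,
) -> list[EquivalenceClass]:
    """Partition models by byte-identical design matrices.

    Each class is annotated with the two documented structural causes of
    indistinguishability: all members sharing one transitive closure, and
    the parent-regulates-parent collapse (some member has an edge between
    the two parents of a gated child, which makes the upstream parent's
    single knockout act like the double knockout).
    """
    exps = _as_experiments(experiments)
    groups: dict[bytes, list[SignalingGraph]] = {}
    designs: dict[bytes, DesignMatrix] = {}
    for model in models:
        phi = build_design_matrix(model, exps)
        key = phi.states.tobytes()
        groups.setdefault(key, []).append(model)
        designs.setdefault(key, phi)
    out = []
    for key, members in groups.items():
        closures = {transitive_closure(m).edges for m in members}
        chain = any(
            (g.parent_a, g.parent_b) in m.edges or (g.parent_b, g.parent_a) in m.edges
            for m in members
            for g in m.gates.values()
        )
        out.append(
            EquivalenceClass(
                members=tuple(sorted(members, key=_canonical_key)),
                design=designs[key],
                same_transitive_closure=len(closures) == 1,
                parent_chain_collapse=chain,
            )
        )
    out.sort(key=lambda c: _canonical_key(c.representative))
    return out
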