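"""Ground-truth simulation and the inference-accuracy benchmark.

Random 4-node networks are drawn with exactly one two-parent logic gate:
a child node and two parents are chosen uniformly, the gate uniformly from
the five labels, and the remaining possible edges are added independently
with a small probability subject to acyclicity and a single gated node.
Reporters are attached to the S-genes uniformly at random, binary data are
simulated for all single knockouts plus the double knockout of the gated
parent pair, and noise flips each cell independently (0 -> 1 with rate
alpha, 1 -> 0 with rate beta).

The benchmark sweeps beta at fixed alpha, runs exhaustive inference on
every simulated dataset and records three per-network accuracies:

* ``edge``  -- agreement of the transitively closed adjacency matrices,
* ``logic`` -- exact recovery of the gated triples (parents and label;
  masking orientation matters),
* ``expected_data`` -- agreement of the reporter-level expected effect
  matrices under each model's attachments,

plus wall time.  Medians per beta are the headline summary.  Per-network
seeds derive from the master seed by the counter scheme
``SeedSequence([seed, beta_index, network_index])``, so any single network
is re-runnable in isolation.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .graph import (
    GATES,
    Gate,
    PerturbationExperiment,
    SignalingGraph,
    build_design_matrix,
    transitive_closure,
)
from .inference import exhaustive_search
from .likelihood import AttachmentMap, EffectDataset, NoiseRates, map_attachments

__all__ = [
    "SimulationConfig",
    "random_network",
    "simulate_data",
    "edge_accuracy",
    "logic_accuracy",
    "expected_data_accuracy",
    "run_benchmark",
    "summarize_benchmark",
]

DEFAULT_BETA_GRID = (0.01, 0.025, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the benchmark.

    Defaults are the benchmark conditions: 4-gene networks, 100 reporters,
    alpha fixed at 0.1, beta swept over a wide grid, 100 networks per beta,
    one replicate.  ``extra_edge_prob`` is the probability of each optional
    non-gate edge (0.25 keeps the networks sparse while exercising chains
    and parent-parent dependencies).
    """

    seed: int
    n_genes: int = 4
    n_reporters: int = 100
    alpha: float = 0.1
    beta_grid: tuple[float, ...] = DEFAULT_BETA_GRID
    n_networks: int = 100
    replicates: int = 1
    extra_edge_prob: float = 0.25

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("a seed is mandatory for reproducibility")
        if self.n_reporters < 1:
            raise ValidationError("n_reporters must be >= 1")
        if not (0.0 <= self.alpha < 1.0) or any(
            not (0.0 <= b < 1.0) for b in self.beta_grid
        ):
            raise ValidationError("all noise rates must lie in [0, 1)")
        if self.n_genes < 3:
            raise ValidationError("need at least 3 genes to plant a two-parent gate")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1}" for i in range(self.n_genes))


def random_network(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[SignalingGraph, AttachmentMap]:
    """Draw a ground-truth network with one planted gate plus attachments.

    One node gets two uniformly chosen parents joined by a uniformly chosen
    gate; every other ordered pair that keeps the graph acyclic and leaves
    all remaining in-degrees at most one is added independently with
    ``extra_edge_prob``.  No edge is ever placed between the two gated
    parents: one parent regulating the other makes the upstream parent's
    single knockout equivalent to the double knockout, so the planted gate
    would be unidentifiable in principle and the benchmark would measure
    that identifiability gap instead of inference accuracy.  Reporters
    attach uniformly at random.
    """
    genes = config.genes
    n = len(genes)
    child_i = int(rng.integers(n))
    others = [i for i in range(n) if i != child_i]
    parent_is = sorted(int(i) for i in rng.choice(others, size=2, replace=False))
    gate_label = str(rng.choice(GATES))
    child = genes[child_i]
    pa, pb = genes[parent_is[0]], genes[parent_is[1]]
    edges = [(pa, child), (pb, child)]
    in_deg = {g: 0 for g in genes}
    in_deg[child] = 2

    def creates_cycle(u: str, v: str) -> bool:
        # reachability v -> u over current edges
        stack, seen = [v], set()
        while stack:
            w = stack.pop()
            if w == u:
                return True
            for p, c in edges:
                if p == w and c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False

    for u in genes:
        for v in genes:
            if u == v or v == child or (u, v) in edges:
                continue
            if {u, v} == {pa, pb}:
                continue  # keep the gated parents independent
            if in_deg[v] >= 1:
                continue  # keep a single gated node in the truth
            if rng.random() < config.extra_edge_prob and not creates_cycle(u, v):
                edges.append((u, v))
                in_deg[v] += 1
    graph = SignalingGraph(genes, edges, {child: Gate(gate_label, pa, pb)})
    assignment = rng.integers(0, n, size=config.n_reporters)
    reporters = tuple(f"E{i + 1}" for i in range(config.n_reporters))
    return graph, AttachmentMap(genes, assignment, reporters)


def simulate_data(
    truth: SignalingGraph,
    theta: AttachmentMap,
    experiments: Sequence,
    rates: NoiseRates,
    replicates: int = 1,
    rng: np.random.Generator | None = None,
) -> EffectDataset:
    """Noisy binary effects from a ground-truth model.

    Expected cell = design-matrix entry at (experiment, attached gene);
    each observed cell independently flips 0 -> 1 with probability alpha
    and 1 -> 0 with probability beta.
    """
    if rng is None:
        rng = np.random.default_rng()
    phi = build_design_matrix(truth, experiments)
    expected = phi.states[:, theta.assignment].T  # (m, n_exp)
    m, n_exp = expected.shape
    exp3 = np.repeat(expected[:, :, None], replicates, axis=2)
    u = rng.random((m, n_exp, replicates))
    observed = np.where(exp3 == 1, u >= rates.beta, u < rates.alpha).astype(np.uint8)
    reporters = theta.reporters or tuple(f"E{i + 1}" for i in range(m))
    return EffectDataset(reporters, phi.labels, observed)


def _check_same_genes(inferred: SignalingGraph, truth: SignalingGraph) -> None:
    if set(inferred.nodes) != set(truth.nodes):
        raise ValidationError(
            f"gene sets differ: {sorted(inferred.nodes)} vs {sorted(truth.nodes)}"
        )


def edge_accuracy(inferred: SignalingGraph, truth: SignalingGraph) -> float:
    """Agreement of transitively closed adjacencies over ordered gene pairs.

    (matching present + matching absent) / (n * (n - 1)); the closure makes
    the score insensitive to shortcut-edge differences within an
    equivalence class.
    """
    _check_same_genes(inferred, truth)
    order = truth.nodes
    a = _closed_adjacency(inferred, order)
    b = _closed_adjacency(truth, order)
    n = len(order)
    off = ~np.eye(n, dtype=bool)
    return float((a[off] == b[off]).mean())


def _closed_adjacency(graph: SignalingGraph, order: Sequence[str]) -> np.ndarray:
    closed = transitive_closure(graph)
    idx = {g: i for i, g in enumerate(order)}
    a = np.zeros((len(order), len(order)), dtype=np.uint8)
    for p, c in closed.edges:
        a[idx[p], idx[c]] = 1
    return a


def logic_accuracy(inferred: SignalingGraph, truth: SignalingGraph) -> float:
    """Fraction of the truth's gated triples recovered exactly.

    A triple counts only when the inferred network gates the same child
    with the same parent pair and the same orientation-normalized label
    (NOT-A vs NOT-B confusion counts as wrong).
    """
    _check_same_genes(inferred, truth)
    true_triples = truth.gated_triples()
    if not true_triples:
        raise ValidationError("truth network has no gated node to score")
    inf_triples = inferred.gated_triples()
    hits = sum(
        1
        for child, spec in true_triples.items()
        if inf_triples.get(child) == spec
    )
    return hits / len(true_triples)


def expected_data_accuracy(
    inferred: SignalingGraph,
    theta_inferred: AttachmentMap,
    truth: SignalingGraph,
    theta_truth: AttachmentMap,
    experiments: Sequence,
) -> float:
    """Cellwise agreement of the reporter-level expected effect matrices."""
    _check_same_genes(inferred, truth)
    phi_inf = build_design_matrix(inferred, experiments)
    phi_true = build_design_matrix(truth, experiments)
    e_inf = phi_inf.states[:, theta_inferred.assignment]
    e_true = phi_true.states[:, theta_truth.assignment]
    if e_inf.shape != e_true.shape:
        raise ValidationError("attachment maps cover different reporter counts")
    return float((e_inf == e_true).mean())


def run_benchmark(
    config: SimulationConfig,
    gates: Sequence[str] = GATES,
    betas: Sequence[float] | None = None,
):
    """Simulate, infer and score accuracy across the beta grid.

    Returns a long-format DataFrame with columns (beta, network_id, metric,
    value); metrics are ``edge``, ``logic``, ``expected_data`` and
    ``seconds``.  Fully reproducible from the config seed.  ``gates``
    restricts the *search* space (the truth always uses all five gates);
    ``("OR",)`` gives the classic no-logic baseline.
    """
    import pandas as pd

    rows = []
    beta_list = tuple(betas) if betas is not None else config.beta_grid
    for bi, beta in enumerate(beta_list):
        rates = NoiseRates(config.alpha, beta)
        for net in range(config.n_networks):
            ss = np.random.SeedSequence([config.seed, bi, net])
            rng = np.random.default_rng(ss)
            truth, theta = random_network(config, rng)
            (pa, pb), _ = next(iter(truth.gated_triples().values()))
            experiments = [PerturbationExperiment([g]) for g in truth.nodes]
            experiments.append(PerturbationExperiment([pa, pb]))
            data = simulate_data(
                truth, theta, experiments, rates, config.replicates, rng
            )
            t0 = time.perf_counter()
            results = exhaustive_search(
                data, rates=rates, genes=truth.nodes, gates=gates
            )
            seconds = time.perf_counter() - t0
            best = results[0].graph
            phi_best = build_design_matrix(best, experiments)
            theta_hat, _, _ = map_attachments(data, phi_best, rates)
            try:
                logic = logic_accuracy(best, truth)
            except ValidationError:  # pragma: no cover - truth always gated
                logic = float("nan")
            record = {
                "edge": edge_accuracy(best, truth),
                "logic": logic,
                "expected_data": expected_data_accuracy(
                    best, theta_hat, truth, theta, experiments
                ),
                "seconds": seconds,
            }
            for metric, value in record.items():
                rows.append(
                    {"beta": beta, "network_id": net, "metric": metric, "value": value}
                )
    return pd.DataFrame(rows, columns=["beta", "network_id", "metric", "value"])


def summarize_benchmark(results):
    """Median of each metric per beta (wide table, metrics as columns)."""
    return (
        results.pivot_table(index="beta", columns="metric", values="value", aggfunc="median")
        .sort_index()
    )
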