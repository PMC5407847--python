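"""Screening a genetic-interaction pair for third-gene modulators.

A pair of genes (X, Y) with single knockouts and the X:Y double knockout
measured is screened against candidate modulators Z: for each Z the data is
restricted to the reporters showing an effect in any of the four relevant
experiments, every 3-gene hypothesis (with and without logic gates) is
scored exhaustively, and the best-scoring equivalence class determines the
category:

* a gate label (AND / OR / XOR / NOT-A / NOT-B, oriented so that NOT-A
  means "X masks the effect of Y") when the top class contains a model in
  which X and Y are the two gated parents of Z;
* ``no-epistasis`` when the top class has no such gated triple even though
  Z shares effect reporters with the pair;
* ``no-information`` when Z shares no effect reporters with the pair --
  decided from reporter overlap alone, before any likelihood is computed.

A pair whose significant modulators span two or more gate categories shows
mixed epistasis: different downstream gene sets follow different epistatic
logics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .graph import GATES, canonical_label
from .inference import (
    ModelHypothesis,
    exhaustive_search,
    top_equivalence_class,
)
from .likelihood import EffectDataset, NoiseRates

__all__ = [
    "ScreenResult",
    "CATEGORIES",
    "candidate_modulators",
    "common_effect_set",
    "screen_pair",
    "classify_result",
    "gate_distribution",
    "significance_filter",
    "permutation_pvalue",
    "pair_epistasis_label",
]

CATEGORIES: tuple[str, ...] = GATES + ("no-epistasis", "no-information")


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of scoring one (pair, modulator) triple."""

    pair: tuple[str, str]
    modulator: str
    category: str
    labels: tuple[str, ...]  # all gate labels present in the top class
    ambiguous: bool
    score: float | None  # best marginal log-likelihood over all hypotheses
    gate_score: float | None  # best among models with the pair gating Z
    no_epistasis_score: float | None  # best among all remaining models
    n_common_reporters: int
    best_class: tuple[ModelHypothesis, ...] = ()

    @property
    def margin(self) -> float | None:
        """Log-likelihood lead of the best gated model over the best non-gated one."""
        if self.gate_score is None or self.no_epistasis_score is None:
            return None
        return self.gate_score - self.no_epistasis_score


def _single_labels(data: EffectDataset) -> dict[str, str]:
    """Map gene -> its single-knockout column label."""
    singles = {}
    for lbl in data.experiments:
        genes = [g for g in lbl.split(":") if g] if lbl != "WT" else []
        if len(genes) == 1:
            singles[genes[0]] = lbl
    return singles


def candidate_modulators(data: EffectDataset, pair: Sequence[str]) -> list[str]:
    """Genes whose single knockout shows at least one effect, minus the pair."""
    x, y = pair
    singles = _single_labels(data)
    missing = [g for g in (x, y) if g not in singles]
    if missing:
        raise ValidationError(f"pair gene(s) without a single-knockout column: {missing}")
    out = []
    for gene, lbl in singles.items():
        if gene in (x, y):
            continue
        if data.effect_mask(lbl).any():
            out.append(gene)
    return out


def common_effect_set(
    data: EffectDataset, pair: Sequence[str], modulator: str
) -> np.ndarray:
    """Boolean reporter mask: effect in any of the X, Y, Z singles or X:Y double.

    This is the common reporter set on which all hypotheses for the triple
    are scored, so that their marginal likelihoods are comparable.
    """
    x, y = pair
    double = canonical_label((x, y))
    if double not in data.experiments:
        raise ValidationError(
            f"dataset lacks the double-knockout column {double!r} for pair ({x}, {y})"
        )
    mask = data.effect_mask(double)
    for gene in (x, y, modulator):
        singles = _single_labels(data)
        if gene not in singles:
            raise ValidationError(f"no single-knockout column for gene {gene!r}")
        mask = mask | data.effect_mask(singles[gene])
    return mask


def classify_result(
    top_class: Sequence[ModelHypothesis],
    pair: Sequence[str],
    modulator: str,
    has_shared_reporters: bool,
) -> tuple[str, tuple[str, ...], bool]:
    """Category of a triple from its best-scoring equivalence class.

    Returns ``(category, labels, ambiguous)``.  ``labels`` collects the
    gate labels (in pair orientation) of every top-class model in which the
    pair are the two parents of the modulator; when several labels are
    present the first in canonical gate order is the category and the
    result is flagged ambiguous.
    """
    if not has_shared_reporters:
        return "no-information", (), False
    x, y = pair
    labels: set[str] = set()
    for hyp in top_class:
        gate = hyp.graph.gates.get(modulator)
        if gate is None:
            continue
        if {gate.parent_a, gate.parent_b} != {x, y}:
            continue
        # orient NOT-A/NOT-B so that A is the first pair gene
        if gate.label in ("NOT-A", "NOT-B"):
            masker = gate.parent_a if gate.label == "NOT-A" else gate.parent_b
            labels.add("NOT-A" if masker == x else "NOT-B")
        else:
            labels.add(gate.label)
    if not labels:
        return "no-epistasis", (), False
    ordered = tuple(g for g in GATES if g in labels)
    return ordered[0], ordered, len(ordered) > 1


def _screen_one(
    data: EffectDataset,
    pair: tuple[str, str],
    modulator: str,
    rates: NoiseRates,
) -> ScreenResult:
    x, y = pair
    singles = _single_labels(data)
    double = canonical_label((x, y))
    pair_mask = (
        data.effect_mask(singles[x])
        | data.effect_mask(singles[y])
        | data.effect_mask(double)
    )
    mod_mask = data.effect_mask(singles[modulator])
    shared = bool((pair_mask & mod_mask).any())
    common = common_effect_set(data, pair, modulator)
    n_common = int(common.sum())
    if not shared:
        return ScreenResult(
            pair=pair,
            modulator=modulator,
            category="no-information",
            labels=(),
            ambiguous=False,
            score=None,
            gate_score=None,
            no_epistasis_score=None,
            n_common_reporters=n_common,
        )
    labels = [singles[x], singles[y], singles[modulator], double]
    sub = data.restrict(reporters=common, experiments=labels)
    results = exhaustive_search(sub, rates=rates, genes=sorted((x, y, modulator)))
    top = top_equivalence_class(results)
    category, gate_labels, ambiguous = classify_result(top, pair, modulator, shared)

    gate_score = None
    noep_score = None
    for hyp in results:
        gate = hyp.graph.gates.get(modulator)
        is_gated_triple = gate is not None and {gate.parent_a, gate.parent_b} == {x, y}
        if is_gated_triple:
            if gate_score is None or hyp.score > gate_score:
                gate_score = hyp.score
        else:
            if noep_score is None or hyp.score > noep_score:
                noep_score = hyp.score
    return ScreenResult(
        pair=pair,
        modulator=modulator,
        category=category,
        labels=gate_labels,
        ambiguous=ambiguous,
        score=results[0].score,
        gate_score=gate_score,
        no_epistasis_score=noep_score,
        n_common_reporters=n_common,
        best_class=tuple(top),
    )


def screen_pair(
    data: EffectDataset,
    pair: Sequence[str],
    candidates: Sequence[str] | None = None,
    rates: NoiseRates = NoiseRates(),
) -> list[ScreenResult]:
    """Score every candidate modulator for one genetic-interaction pair.

    Candidates default to every gene whose single knockout shows an effect.
    Results are ranked by best score descending, ``no-information``
    triples (which have no score) last; each candidate's result depends
    only on its own triple, never on the other candidates.
    """
    x, y = tuple(pair)
    if candidates is None:
        candidates = candidate_modulators(data, (x, y))
    results = [_screen_one(data, (x, y), z, rates) for z in candidates]
    results.sort(
        key=lambda r: (r.score is None, -(r.score if r.score is not None else 0.0), r.modulator)
    )
    return results


def significance_filter(
    results: Sequence[ScreenResult],
    margin: float = 0.0,
    permutations: int = 0,
    seed: int | None = None,
    data: EffectDataset | None = None,
    rates: NoiseRates = NoiseRates(),
    p_threshold: float = 0.05,
) -> list[ScreenResult]:
    """Keep modulators whose gate hypothesis clearly beats the alternatives.

    Default rule: keep a gated result when its best gated model leads the
    best non-gated model by more than ``margin`` log-units.  With
    ``permutations > 0`` (requires ``data``), an empirical null for that
    score lead is built by permuting the modulator's single-knockout column
    across reporters: this destroys exactly the modulator-pair coherence a
    gated triple needs while preserving the pair's own structure and every
    column's effect frequency.  (Permuting whole reporter rows would leave
    the marginal likelihood invariant, and permuting all columns inflates
    the null because gated models generically fit incoherent reporters
    better than gateless ones.)  A result is kept when its empirical
    p-value is at most ``p_threshold``.  Seeded and deterministic.
    """
    if margin < 0:
        raise ValidationError("margin must be >= 0")
    kept = []
    base = [
        r
        for r in results
        if r.category in GATES and r.margin is not None and r.margin > margin
    ]
    if permutations <= 0:
        return base
    if data is None:
        raise ValidationError("permutation mode needs the effect dataset")
    rng = np.random.default_rng(seed)
    for r in base:
        p_emp = permutation_pvalue(
            data, r.pair, r.modulator, rates, permutations, rng, observed=r.margin
        )
        if p_emp <= p_threshold:
            kept.append(r)
    return kept


def permutation_pvalue(
    data: EffectDataset,
    pair: Sequence[str],
    modulator: str,
    rates: NoiseRates = NoiseRates(),
    permutations: int = 99,
    rng: "np.random.Generator | int | None" = None,
    observed: float | None = None,
) -> float:
    """Empirical p-value for one triple's gated-versus-gateless score lead.

    The null permutes the modulator's single-knockout column across
    reporters (see ``significance_filter``); the p-value uses the standard
    add-one estimator (1 + #null >= observed) / (1 + permutations).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if observed is None:
        obs_result = _screen_one(data, tuple(pair), modulator, rates)
        observed = obs_result.margin
        if observed is None:
            return 1.0
    singles = _single_labels(data)
    mod_col = data.experiments.index(singles[modulator])
    null = np.empty(permutations)
    for p in range(permutations):
        perm_vals = data.values.copy()
        perm_vals[:, mod_col, :] = perm_vals[
            rng.permutation(perm_vals.shape[0]), mod_col, :
        ]
        perm_data = EffectDataset(data.reporters, data.experiments, perm_vals)
        pr = _screen_one(perm_data, tuple(pair), modulator, rates)
        null[p] = pr.margin if pr.margin is not None else -np.inf
    return (1.0 + float((null >= observed).sum())) / (1.0 + permutations)


def gate_distribution(
    results: "Sequence[ScreenResult] | Mapping[tuple[str, str], Sequence[ScreenResult]]",
):
    """Per-pair category counts, the table behind a stacked-bar summary."""
    import pandas as pd

    if isinstance(results, Mapping):
        flat: list[ScreenResult] = [r for rs in results.values() for r in rs]
    else:
        flat = list(results)
    rows: dict[str, dict[str, int]] = {}
    for r in flat:
        pair_lbl = canonical_label(r.pair)
        row = rows.setdefault(pair_lbl, {c: 0 for c in CATEGORIES})
        row[r.category] += 1
    table = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    if table.empty:
        return pd.DataFrame(columns=list(CATEGORIES), dtype=int)
    return table[list(CATEGORIES)].sort_index()


def pair_epistasis_label(significant: Sequence[ScreenResult]) -> str:
    """Summarize one pair's significant modulators.

    ``mixed`` when the gate categories span two or more labels (different
    reporter sets follow different epistatic logics), the single gate label
    when they agree, and ``none`` without significant gated modulators.
    """
    gates = {r.category for r in significant if r.category in GATES}
    if not gates:
        return "none"
    if len(gates) == 1:
        return next(iter(gates))
    return "mixed"


def plot_gate_distribution(table, ax=None):
    """Stacked-bar rendering of a ``gate_distribution`` table."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.5 * len(table)), 4))
    bottom = np.zeros(len(table))
    for cat in table.columns:
        ax.bar(table.index, table[cat].to_numpy(), bottom=bottom, label=cat)
        bottom += table[cat].to_numpy()
    ax.set_ylabel("modulators")
    ax.set_xlabel("gene pair")
    ax.legend(fontsize="small")
    ax.tick_params(axis="x", rotation=90)
    return ax
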