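"""Marginal likelihood of binary effect data given a signaling model.

Observed effects are binary: reporter i shows an effect (1) or not (0) in
each experiment and replicate.  Each reporter is attached to exactly one
S-gene; the attachment is hidden and is marginalized with a uniform prior.
Given a design matrix F (expected disruption f of every S-gene under every
experiment) and noise rates alpha (false positive) and beta (false
negative), a single cell contributes

    P(e | f) = 1-alpha  if e=0, f=0      alpha  if e=1, f=0
               beta     if e=0, f=1      1-beta if e=1, f=1

The full-data likelihood is the product over reporters, experiments and
replicates; the marginal likelihood averages, independently per reporter,
over the n possible attachments:

    P(D | F) = (1/n^m) * prod_i sum_j prod_cells P(e_icell | f = F[cell, j])

Everything is computed in log space with log-sum-exp; products over
hundreds of reporters would underflow otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import ValidationError
from .graph import DesignMatrix

__all__ = [
    "NoiseRates",
    "EffectDataset",
    "AttachmentMap",
    "cell_log_likelihood",
    "full_log_likelihood",
    "attachment_log_likelihoods",
    "marginal_log_likelihood",
    "map_attachments",
]


@dataclass(frozen=True)
class NoiseRates:
    """False-positive rate alpha and false-negative rate beta.

    Both are treated as known properties of the experiment, not estimated.
    The constraint alpha + beta < 1 keeps signal above noise.
    """

    alpha: float = 0.1
    beta: float = 0.1

    def __post_init__(self):
        if not (0.0 <= self.alpha < 1.0 and 0.0 <= self.beta < 1.0):
            raise ValidationError(f"rates must lie in [0, 1): alpha={self.alpha}, beta={self.beta}")
        if self.alpha + self.beta >= 1.0:
            raise ValidationError(
                f"alpha + beta must be < 1 (got {self.alpha} + {self.beta})"
            )

    def log_terms(self) -> tuple[float, float, float, float]:
        """(log P(0|0), log P(1|0), log P(0|1), log P(1|1)); -inf at rate 0."""
        with np.errstate(divide="ignore"):
            return (
                float(np.log(1.0 - self.alpha)),
                float(np.log(self.alpha)),
                float(np.log(self.beta)),
                float(np.log(1.0 - self.beta)),
            )


def cell_log_likelihood(e: int, f: int, rates: NoiseRates) -> float:
    """Log-probability of one observed cell given its expected effect."""
    l00, l10, l01, l11 = rates.log_terms()
    if f:
        return l11 if e else l01
    return l10 if e else l00


class EffectDataset:
    """Binary effects of m reporters across experiments with l replicates.

    ``values`` has shape (m, n_experiments, l).  Experiment labels use the
    canonical form (sorted gene names joined by ':').
    """

    __slots__ = ("reporters", "experiments", "values", "_col_index")

    def __init__(
        self,
        reporters: Sequence[str],
        experiments: Sequence[str],
        values: np.ndarray,
    ):
        self.reporters = tuple(reporters)
        self.experiments = tuple(experiments)
        values = np.asarray(values)
        if values.ndim == 2:
            values = values[:, :, None]
        if values.shape[:2] != (len(self.reporters), len(self.experiments)):
            raise ValidationError(
                f"value tensor shape {values.shape} does not match "
                f"{len(self.reporters)} reporters x {len(self.experiments)} experiments"
            )
        if values.shape[0] < 1 or values.shape[2] < 1:
            raise ValidationError("need at least one reporter and one replicate")
        if not np.isin(values, (0, 1)).all():
            raise ValidationError("effect values must be binary 0/1")
        if len(set(self.reporters)) != len(self.reporters):
            raise ValidationError("duplicate reporter identifiers")
        if len(set(self.experiments)) != len(self.experiments):
            raise ValidationError("duplicate experiment labels")
        self.values = values.astype(np.uint8)
        self._col_index = {lbl: i for i, lbl in enumerate(self.experiments)}

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n_experiments(self) -> int:
        return self.values.shape[1]

    @property
    def replicates(self) -> int:
        return self.values.shape[2]

    def column(self, label: str) -> np.ndarray:
        """Values (m, l) for one experiment label."""
        try:
            return self.values[:, self._col_index[label], :]
        except KeyError:
            raise ValidationError(f"no experiment {label!r} in dataset") from None

    def effect_mask(self, label: str) -> np.ndarray:
        """Boolean mask over reporters: effect observed in any replicate."""
        return self.column(label).any(axis=1)

    def restrict(
        self,
        reporters: Sequence[str] | np.ndarray | None = None,
        experiments: Sequence[str] | None = None,
    ) -> "EffectDataset":
        vals = self.values
        reps = self.reporters
        if reporters is not None:
            if isinstance(reporters, np.ndarray) and reporters.dtype == bool:
                idx = np.flatnonzero(reporters)
            else:
                rix = {r: i for i, r in enumerate(self.reporters)}
                idx = np.array([rix[r] for r in reporters], dtype=int)
            vals = vals[idx]
            reps = tuple(self.reporters[i] for i in idx)
        exps = self.experiments
        if experiments is not None:
            cols = []
            for lbl in experiments:
                if lbl not in self._col_index:
                    raise ValidationError(f"no experiment {lbl!r} in dataset")
                cols.append(self._col_index[lbl])
            vals = vals[:, cols, :]
            exps = tuple(experiments)
        return EffectDataset(reps, exps, vals)

    def cells(self) -> np.ndarray:
        """Flattened (m, n_experiments * l) float view, replicate-major per experiment."""
        m, n_exp, l = self.values.shape
        return self.values.reshape(m, n_exp * l).astype(np.float64)

    def to_frame(self):
        import pandas as pd

        if self.replicates == 1:
            cols = list(self.experiments)
        else:
            cols = [f"{lbl}#{k + 1}" for lbl in self.experiments for k in range(self.replicates)]
        return pd.DataFrame(
            self.values.reshape(self.m, -1), index=list(self.reporters), columns=cols
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EffectDataset):
            return NotImplemented
        return (
            self.reporters == other.reporters
            and self.experiments == other.experiments
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"EffectDataset(m={self.m}, experiments={list(self.experiments)}, "
            f"replicates={self.replicates})"
        )


@dataclass(frozen=True)
class AttachmentMap:
    """Assignment of each reporter to one S-gene (by gene index)."""

    genes: tuple[str, ...]
    assignment: np.ndarray  # shape (m,), int indices into genes
    reporters: tuple[str, ...] | None = None

    def __post_init__(self):
        a = np.asarray(self.assignment, dtype=np.intp)
        if a.ndim != 1:
            raise ValidationError("attachment assignment must be a 1-D index array")
        if a.size and (a.min() < 0 or a.max() >= len(self.genes)):
            raise ValidationError("attachment index out of range")
        object.__setattr__(self, "assignment", a)

    def gene_of(self, i: int) -> str:
        return self.genes[self.assignment[i]]


def _expected_cells(phi: DesignMatrix, data: EffectDataset) -> np.ndarray:
    """Design rows aligned to the dataset's experiments, replicate-expanded.

    Returns (n_cells, n_genes) float matrix where n_cells = n_exp * l.
    """
    rows = np.stack([phi.row(lbl) for lbl in data.experiments]).astype(np.float64)
    return np.repeat(rows, data.replicates, axis=0)


def _safe_mul(count: np.ndarray, logterm: float) -> np.ndarray:
    """count * logterm with the convention 0 * (-inf) = 0."""
    if math.isinf(logterm):
        return np.where(count > 0, logterm, 0.0)
    return count * logterm


def full_log_likelihood(
    data: EffectDataset,
    phi: DesignMatrix,
    theta: AttachmentMap | Sequence[int],
    rates: NoiseRates,
) -> float:
    """Log-likelihood of the data at a fixed, known attachment."""
    if isinstance(theta, AttachmentMap):
        if theta.genes != phi.genes:
            raise ValidationError("attachment map genes do not match the design matrix")
        assignment = theta.assignment
    else:
        assignment = np.asarray(theta, dtype=np.intp)
    if assignment.shape != (data.m,):
        raise ValidationError(
            f"attachment length {assignment.shape} does not match m={data.m}"
        )
    F = _expected_cells(phi, data)  # (cells, n)
    E = data.cells()  # (m, cells)
    expected = F[:, assignment].T  # (m, cells)
    l00, l10, l01, l11 = rates.log_terms()
    n11 = float((E * expected).sum())
    n10 = float((E * (1 - expected)).sum())
    n01 = float(((1 - E) * expected).sum())
    n00 = float(((1 - E) * (1 - expected)).sum())
    total = 0.0
    for count, term in ((n00, l00), (n10, l10), (n01, l01), (n11, l11)):
        if count > 0:
            total += count * term
    if any(
        count > 0 and math.isinf(term)
        for count, term in ((n00, l00), (n10, l10), (n01, l01), (n11, l11))
    ):
        return float("-inf")
    return total


def attachment_log_likelihoods(
    data: EffectDataset, phi: DesignMatrix, rates: NoiseRates
) -> np.ndarray:
    """Per-reporter, per-gene log-likelihood matrix L[i, j].

    L[i, j] = sum over the reporter's cells of the cell log-probability
    under attachment theta_i = j.  This is the building block shared by the
    marginal likelihood and the MAP attachment report.
    """
    if len(phi.genes) == 0:
        raise ValidationError("design matrix has no S-genes")
    F = _expected_cells(phi, data)  # (cells, n)
    E = data.cells()  # (m, cells)
    l00, l10, l01, l11 = rates.log_terms()
    n11 = E @ F
    n10 = E @ (1.0 - F)
    n01 = (1.0 - E) @ F
    n00 = (1.0 - E) @ (1.0 - F)
    L = (
        _safe_mul(n00, l00)
        + _safe_mul(n10, l10)
        + _safe_mul(n01, l01)
        + _safe_mul(n11, l11)
    )
    return L


def marginal_log_likelihood(
    data: EffectDataset,
    phi: DesignMatrix,
    rates: NoiseRates,
    include_null: bool = False,
) -> float:
    """Log marginal likelihood, attachments averaged with a uniform prior.

    ``include_null`` adds one extra attachment target whose expected effects
    are all zero (a reporter explained by noise alone); it is off by
    default, matching the plain 1/n^m uniform average over the S-genes.
    """
    L = attachment_log_likelihoods(data, phi, rates)
    if include_null:
        E = data.cells()
        l00, l10, _, _ = rates.log_terms()
        ones = E.sum(axis=1)
        zeros = E.shape[1] - ones
        null_col = _safe_mul(zeros, l00) + _safe_mul(ones, l10)
        L = np.column_stack([L, null_col])
    n = L.shape[1]
    per_reporter = logsumexp(L, axis=1) - math.log(n)
    return float(per_reporter.sum())


def map_attachments(
    data: EffectDataset,
    phi: DesignMatrix,
    rates: NoiseRates,
) -> tuple[AttachmentMap, np.ndarray, list[tuple[str, tuple[str, ...]]]]:
    """MAP attachment per reporter plus the normalized posterior.

    Returns ``(attachment, posterior, ties)``: posterior is an (m, n)
    row-stochastic matrix; ties lists reporters whose maximum is attained by
    several genes (within 1e-9 log-units), the lowest gene index winning.
    """
    L = attachment_log_likelihoods(data, phi, rates)
    norm = logsumexp(L, axis=1, keepdims=True)
    posterior = np.exp(L - norm)
    best = np.argmax(L, axis=1)
    ties: list[tuple[str, tuple[str, ...]]] = []
    for i in range(L.shape[0]):
        tied = np.flatnonzero(L[i] >= L[i, best[i]] - 1e-9)
        if tied.size > 1:
            ties.append((data.reporters[i], tuple(phi.genes[j] for j in tied)))
    attachment = AttachmentMap(phi.genes, best, data.reporters)
    return attachment, posterior, ties
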