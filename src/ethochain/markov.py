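"""Generative Markov-chain machinery over a fitted transition matrix.

Simulation, multi-step transition probabilities, stationary distribution,
sequence log-likelihood, a likelihood-ratio (G) test of first-order
dependence against an independent-draws null, and sequence-level bootstrap
confidence intervals for the transition probabilities.

Randomness: every stochastic entry point takes an explicit seed and builds
one :class:`numpy.random.Generator` from it; child streams (bootstrap
replicates, synthetic sessions) are derived with ``SeedSequence.spawn`` so
results are reproducible regardless of execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats

from .ethogram import Ethogram, EventSequence
from .transitions import (
    TransitionCounts,
    TransitionMatrix,
    count_transitions,
    estimate_matrix,
)

__all__ = [
    "MarkovChain",
    "StationaryDistribution",
    "OrderTestResult",
    "BootstrapResult",
    "simulate",
    "k_step",
    "stationary",
    "sequence_log_likelihood",
    "test_first_order",
    "bootstrap_cis",
]


@dataclass(frozen=True)
class MarkovChain:
    """A transition matrix with an initial distribution: the generative model."""

    matrix: TransitionMatrix
    initial: np.ndarray

    def __post_init__(self) -> None:
        if not self.matrix.all_defined:
            bad = [s for s, d in zip(self.matrix.states, self.matrix.defined) if not d]
            raise ValueError(f"chain has undefined rows: {bad}")
        init = np.asarray(self.initial, dtype=float)
        if init.shape != (self.matrix.n_states,):
            raise ValueError("initial distribution length must equal N")
        if init.min() < 0 or abs(init.sum() - 1.0) > 1e-9:
            raise ValueError("initial must be a probability vector (sum 1 within 1e-9)")
        object.__setattr__(self, "initial", init)

    @classmethod
    def uniform_start(cls, matrix: TransitionMatrix) -> "MarkovChain":
        n = matrix.n_states
        return cls(matrix, np.full(n, 1.0 / n))


@dataclass(frozen=True)
class StationaryDistribution:
    """Fixed point of πP = π with its max-norm residual."""

    pi: np.ndarray
    residual: float


@dataclass(frozen=True)
class OrderTestResult:
    """G-test of first-order dependence vs an independent-draws null."""

    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile bootstrap bounds for each transition probability."""

    point: TransitionMatrix
    lower: np.ndarray
    upper: np.ndarray
    B: int
    level: float


def simulate(chain: MarkovChain, n_steps: int, seed) -> EventSequence:
    """Simulate a behavior sequence of ``n_steps`` states.

    X_0 is drawn from the chain's initial distribution and each X_{n+1}
    from row X_n of the transition matrix, giving ``n_steps − 1``
    transitions.  The same (chain, n_steps, seed) always yields the same
    sequence.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    n = chain.matrix.n_states
    cum = np.cumsum(chain.matrix.probs, axis=1)
    cum[:, -1] = 1.0  # guard against float drift in searchsorted
    u = rng.random(n_steps)
    states = np.empty(n_steps, dtype=np.int64)
    states[0] = np.searchsorted(np.cumsum(chain.initial), u[0], side="right")
    for t in range(1, n_steps):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t], side="right")
    np.clip(states, 0, n - 1, out=states)
    return EventSequence("simulated", states.tolist())


def k_step(matrix: TransitionMatrix, k: int) -> TransitionMatrix:
    """The k-step transition matrix P^k (rows remain stochastic)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not matrix.all_defined:
        raise ValueError("k_step requires all rows defined")
    power = np.linalg.matrix_power(matrix.probs, k)
    # renormalize away accumulated float drift before the row-sum check
    power = power / power.sum(axis=1, keepdims=True)
    return TransitionMatrix(power, matrix.states)


def _strong_components(probs: np.ndarray) -> np.ndarray:
    graph = sparse.csr_matrix((probs > 0).astype(np.int8))
    _, labels = sparse.csgraph.connected_components(graph, connection="strong")
    return labels


def stationary(matrix: TransitionMatrix) -> StationaryDistribution:
    """Solve πP = π, Σπ = 1 for an irreducible chain.

    Uses a direct linear solve of the balance equations with the
    normalization constraint.  Periodic chains are accepted: π is the
    stationary (long-run occupancy) distribution even when the limiting
    distribution does not exist.

    Raises
    ------
    ValueError
        If the chain is reducible, naming the states outside the first
        communicating class.
    """
    if not matrix.all_defined:
        raise ValueError("stationary requires all rows defined")
    p = matrix.probs
    labels = _strong_components(p)
    if labels.max() > 0:
        outside = [s for s, lab in zip(matrix.states, labels) if lab != labels[0]]
        raise ValueError(
            f"chain is reducible: states {outside} form a separate communicating class"
        )
    n = p.shape[0]
    a = np.vstack([p.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    residual = float(np.max(np.abs(pi @ p - pi)))
    return StationaryDistribution(pi, residual)


def sequence_log_likelihood(
    matrix: TransitionMatrix, seq: EventSequence, initial: np.ndarray | None = None
) -> float:
    """Log-likelihood Σ_n log p(X_{n+1}|X_n), plus log initial(X_0) if given.

    A transition (or start state) with probability zero yields −inf.
    Undefined source rows encountered along the sequence are an error.
    """
    if len(seq) < 1:
        raise ValueError("sequence must have length >= 1")
    ix = np.asarray(seq.states, dtype=np.int64)
    total = 0.0
    if initial is not None:
        p0 = float(np.asarray(initial, dtype=float)[ix[0]])
        total += np.log(p0) if p0 > 0 else -np.inf
    if len(ix) >= 2:
        src, dst = ix[:-1], ix[1:]
        if not matrix.defined[src].all():
            bad = sorted({matrix.states[i] for i in src[~matrix.defined[src]]})
            raise ValueError(f"sequence visits undefined rows: {bad}")
        steps = matrix.probs[src, dst]
        with np.errstate(divide="ignore"):
            total += float(np.where(steps > 0, np.log(np.where(steps > 0, steps, 1.0)), -np.inf).sum())
    return total


def test_first_order(
    sequences: list[EventSequence],
    ethogram: Ethogram,
    self_transitions: bool | None = None,
) -> OrderTestResult:
    """Likelihood-ratio (G) test of sequential dependence.

    Compares the first-order Markov model against the zero-order null in
    which each next state is an independent draw from the pooled
    next-state frequencies: expected counts are row-margin × column
    frequency, G = 2·Σ O·log(O/E), and the p-value comes from the
    chi-square upper tail.

    Degrees of freedom follow the likelihood-ratio accounting: the full
    model spends (allowed, supported columns − 1) parameters per supported
    row, the null spends (supported columns − 1), and structurally
    forbidden cells (the empty diagonal of run-collapsed data) are never
    counted.  On a complete table this is the classical (r−1)(c−1).  With
    structural zeros the chi-square reference is approximate.

    ``self_transitions`` defaults to auto: the diagonal is treated as
    structurally forbidden only when no self-transition was observed.
    """
    counts = count_transitions(sequences, ethogram).counts
    n_total = counts.sum()
    if n_total == 0:
        raise ValueError("no transitions observed")
    if n_total < 2:
        raise ValueError("need at least 2 transitions")
    n = counts.shape[0]
    if self_transitions is None:
        self_transitions = bool(np.diag(counts).any())
    allowed = np.ones((n, n), dtype=bool)
    if not self_transitions:
        np.fill_diagonal(allowed, False)
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    expected = np.outer(row_tot, col_tot / n_total)
    obs = counts[allowed & (counts > 0)]
    exp = expected[allowed & (counts > 0)]
    g = float(2.0 * np.sum(obs * np.log(obs / exp)))
    g = max(g, 0.0)
    supported_rows = row_tot > 0
    supported_cols = col_tot > 0
    full_params = int(
        sum(
            (allowed[i] & supported_cols).sum() - 1
            for i in np.flatnonzero(supported_rows)
        )
    )
    null_params = int(supported_cols.sum()) - 1
    df = max(full_params - null_params, 1)
    p = float(stats.chi2.sf(g, df))
    return OrderTestResult(g, df, p)


def bootstrap_cis(
    sequences: list[EventSequence],
    ethogram: Ethogram,
    B: int,
    level: float = 0.95,
    seed=0,
) -> BootstrapResult:
    """Percentile bootstrap for transition probabilities.

    Whole sequences (sessions) are resampled with replacement — the
    resampling unit respects within-session dependence.  For each cell,
    bounds are percentiles over the replicates in which the cell's source
    row was observed; cells whose row is undefined in every replicate get
    NaN bounds.
    """
    if not sequences:
        raise ValueError("bootstrap requires at least one sequence")
    if B < 1:
        raise ValueError("B must be >= 1")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    n = ethogram.n_states
    per_seq = np.stack(
        [count_transitions([s], ethogram).counts for s in sequences]
    )  # (n_seq, N, N)
    pooled = per_seq.sum(axis=0)
    point = estimate_matrix(TransitionCounts(pooled, ethogram.state_names))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(sequences), size=(B, len(sequences)))
    reps = np.full((B, n, n), np.nan)
    allow_self = bool(np.diag(pooled).any())
    for b in range(B):
        c = per_seq[idx[b]].sum(axis=0)
        rep = estimate_matrix(
            TransitionCounts(c, ethogram.state_names), allow_self=allow_self
        )
        reps[b] = rep.probs
    alpha = 1.0 - level
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells stay NaN
        lower = np.nanpercentile(reps, 100 * alpha / 2, axis=0)
        upper = np.nanpercentile(reps, 100 * (1 - alpha / 2), axis=0)
    return BootstrapResult(point, lower, upper, B, level)
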