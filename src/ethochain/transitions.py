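"""Transition-count and transition-probability estimation, with stage
aggregation.

The model is a time-homogeneous first-order Markov chain over the ethogram
states: p_ij = P(X_{n+1} = E_j | X_n = E_i).  The maximum-likelihood
estimate is the row-normalized table of observed adjacent-pair counts,
pooled over sessions (transitions never span session boundaries).  Summing
a row's probabilities over the stage membership of the *target* states
yields the probability that the next behavior falls in each fighting stage.

Internally all probabilities are proportions in [0, 1]; rendering helpers
multiply by 100 and round half-even to 2 decimals so printed tables can be
compared cell-by-cell.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ethogram import Ethogram, EventSequence, normalize_name

__all__ = [
    "TransitionCounts",
    "TransitionMatrix",
    "StageMatrix",
    "count_transitions",
    "estimate_matrix",
    "vannamei_transition_matrix",
    "aggregate_stages",
    "next_behavior_range",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "to_percent",
]

ROW_SUM_TOL = 1e-9


def to_percent(p: float) -> float:
    """Render a proportion as a percent rounded half-even to 2 decimals."""
    return float(np.round(p * 100.0, 2))


@dataclass(frozen=True)
class TransitionCounts:
    """N×N observed transition counts in canonical state order."""

    counts: np.ndarray
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (len(self.states), len(self.states)):
            raise ValueError("counts must be N×N matching the state list")
        if (c < 0).any():
            raise ValueError("transition counts must be nonnegative")
        object.__setattr__(self, "counts", c)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition probabilities.

    Rows whose source behavior was never observed (zero support, no
    smoothing) are *undefined* and stored as NaN rather than silently
    uniform.  ``row_support`` carries per-row transition counts when the
    matrix came from data; it is ``None`` for externally supplied matrices.
    """

    probs: np.ndarray
    states: tuple[str, ...]
    row_support: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        n = len(self.states)
        if p.shape != (n, n):
            raise ValueError("probs must be N×N matching the state list")
        defined = ~np.isnan(p).any(axis=1)
        if defined.any():
            if p[defined].min() < -ROW_SUM_TOL:
                raise ValueError("probabilities must be nonnegative")
            sums = p[defined].sum(axis=1)
            if np.max(np.abs(sums - 1.0)) > ROW_SUM_TOL:
                raise ValueError("defined rows must sum to 1 within 1e-9")
        object.__setattr__(self, "probs", p)
        if self.row_support is not None:
            object.__setattr__(
                self, "row_support", np.asarray(self.row_support, dtype=np.int64)
            )

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of rows with a defined probability distribution."""
        return ~np.isnan(self.probs).any(axis=1)

    @property
    def all_defined(self) -> bool:
        return bool(self.defined.all())

    def index_of(self, name: str) -> int:
        return self.states.index(normalize_name(name))

    def prob(self, source: str, target: str) -> float:
        return float(self.probs[self.index_of(source), self.index_of(target)])


@dataclass(frozen=True)
class StageMatrix:
    """N×S probabilities that the next behavior falls in each stage."""

    probs: np.ndarray
    states: tuple[str, ...]
    stages: tuple[str, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (len(self.states), len(self.stages)):
            raise ValueError("stage probs must be N×S")
        defined = ~np.isnan(p).any(axis=1)
        sums = p[defined].sum(axis=1)
        if defined.any() and np.max(np.abs(sums - 1.0)) > ROW_SUM_TOL:
            raise ValueError("defined rows must sum to 1 within 1e-9")
        object.__setattr__(self, "probs", p)

    def prob(self, source: str, stage: str) -> float:
        i = self.states.index(normalize_name(source))
        s = self.stages.index(normalize_name(stage))
        return float(self.probs[i, s])


def count_transitions(
    sequences: Sequence[EventSequence], ethogram: Ethogram
) -> TransitionCounts:
    """Tally adjacent state pairs (X_n → X_{n+1}) pooled over sequences.

    An empty sequence list yields an all-zero matrix; single-state
    sequences contribute nothing.
    """
    n = ethogram.n_states
    counts = np.zeros((n, n), dtype=np.int64)
    for seq in sequences:
        ix = np.asarray(seq.states, dtype=np.int64)
        if (ix < 0).any() or (ix >= n).any():
            raise ValueError(f"sequence {seq.session_id!r} has out-of-range state index")
        if len(ix) >= 2:
            np.add.at(counts, (ix[:-1], ix[1:]), 1)
    return TransitionCounts(counts, ethogram.state_names)


def estimate_matrix(
    counts: TransitionCounts,
    pseudocount: float = 0.0,
    allow_self: bool | None = None,
) -> TransitionMatrix:
    """Row-normalize transition counts into the MLE transition matrix.

    ``pseudocount`` (a ≥ 0) is added only to structurally allowed cells
    before normalizing: p_ij = (c_ij + a) / Σ_k (c_ik + a).  By default
    self-transitions are treated as structurally forbidden when the
    diagonal of ``counts`` is all zero (run-collapsed data) and allowed
    otherwise; pass ``allow_self`` to override.  Rows with zero support and
    no smoothing are left undefined (NaN).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    c = counts.counts.astype(float)
    n = c.shape[0]
    if allow_self is None:
        allow_self = bool(np.diag(counts.counts).any())
    allowed = np.ones((n, n), dtype=bool)
    if not allow_self:
        np.fill_diagonal(allowed, False)
    # forbidden cells contribute nothing and stay exact zeros
    smoothed = np.where(allowed, c + pseudocount, 0.0)
    totals = smoothed.sum(axis=1)
    probs = np.full((n, n), np.nan)
    ok = totals > 0
    probs[ok] = smoothed[ok] / totals[ok, None]
    return TransitionMatrix(probs, counts.states, row_support=counts.row_totals)


def vannamei_transition_matrix() -> TransitionMatrix:
    """The packaged next-behavior probability matrix for *L. vannamei*
    agonistic behavior, stored as printed percents and returned as
    proportions.  Empty cells are exact zeros; all nine rows are defined."""
    text = resources.files("ethochain.data").joinpath("vannamei_matrix.tsv").read_text()
    return read_matrix_tsv(io.StringIO(text), percent=True, delimiter="\t")


def aggregate_stages(matrix: TransitionMatrix, ethogram: Ethogram) -> StageMatrix:
    """Sum each row's next-state probabilities over the stage membership of
    the target states, giving P(next behavior in stage s | current = E_i)."""
    if tuple(matrix.states) != ethogram.state_names:
        raise ValueError("matrix states do not match the ethogram")
    stage_map = ethogram.stage_map
    n, stages = ethogram.n_states, ethogram.stage_names
    member = np.zeros((n, len(stages)), dtype=float)
    for j, state in enumerate(ethogram.state_names):
        if state not in stage_map:
            raise ValueError(f"state {state!r} missing from stage map")
        member[j, stages.index(stage_map[state])] = 1.0
    return StageMatrix(matrix.probs @ member, matrix.states, stages)


def next_behavior_range(
    matrix: TransitionMatrix, target_state: str, source_states: Sequence[str]
) -> tuple[float, float]:
    """Min and max of P(next = target | current = source) over sources."""
    if not source_states:
        raise ValueError("source_states must be nonempty")
    j = matrix.index_of(target_state)
    vals = []
    for src in source_states:
        i = matrix.index_of(src)
        if not matrix.defined[i]:
            raise ValueError(f"source row {src!r} is undefined")
        vals.append(float(matrix.probs[i, j]))
    return (min(vals), max(vals))


# ---------------------------------------------------------------------------
# Matrix I/O (TSV with header row/column of state names)
# ---------------------------------------------------------------------------


def read_matrix_tsv(
    source, percent: bool = False, delimiter: str | None = None
) -> TransitionMatrix:
    """Read a transition matrix from delimited text.

    First column holds source-state names, header row target-state names.
    Empty cells are zeros.  With ``percent``, values are divided by 100.
    """
    sep = delimiter
    if sep is None and isinstance(source, (str, Path)):
        sep = "\t" if Path(source).suffix.lower() == ".tsv" else ","
    df = pd.read_csv(source, sep=sep or "\t", index_col=0)
    states = tuple(normalize_name(s) for s in df.index)
    cols = tuple(normalize_name(s) for s in df.columns)
    if set(cols) - set(states):
        raise ValueError("matrix header names do not match row names")
    full = pd.DataFrame(0.0, index=list(states), columns=list(states))
    df.index, df.columns = list(states), list(cols)
    full.loc[:, list(cols)] = df.fillna(0.0).astype(float).values
    probs = full.values
    if percent:
        probs = probs / 100.0
    # repair printed-precision row sums (e.g. percents totalling 100.00)
    sums = probs.sum(axis=1)
    close = np.abs(sums - 1.0) < 1e-3
    probs[close] = probs[close] / sums[close, None]
    return TransitionMatrix(probs, states)


def write_matrix_tsv(
    matrix: TransitionMatrix,
    target,
    percent: bool = False,
    table_style: bool = False,
    delimiter: str = "\t",
) -> None:
    """Write a transition matrix as delimited text.

    ``percent`` renders values ×100 rounded half-even to 2 decimals;
    ``table_style`` additionally leaves structural zeros as empty cells
    (implies ``percent``).
    """
    vals = matrix.probs.copy()
    if percent or table_style:
        vals = np.round(vals * 100.0, 2)
    df = pd.DataFrame(vals, index=list(matrix.states), columns=list(matrix.states))
    df.index.name = "behavior"
    if table_style:
        df = df.map(lambda v: "" if v == 0 else f"{v:.2f}")
    df.to_csv(target, sep=delimiter)


def write_stage_tsv(
    stage_matrix: StageMatrix, target, percent: bool = False, delimiter: str = "\t"
) -> None:
    """Write a stage matrix (rows = behaviors, columns = stages)."""
    vals = stage_matrix.probs.copy()
    if percent:
        vals = np.round(vals * 100.0, 2)
    df = pd.DataFrame(
        vals, index=list(stage_matrix.states), columns=list(stage_matrix.stages)
    )
    df.index.name = "behavior"
    df.to_csv(target, sep=delimiter)
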