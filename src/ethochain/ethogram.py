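"""Ethogram definitions and event-log ingestion.

An ethogram is an ordered catalogue of discrete, mutually exclusive behavior
patterns defined for a species, here augmented with a total mapping of each
behavior onto a fighting stage (e.g. encounter / contact / withdrawal for
*Litopenaeus vannamei* agonistic bouts).  This module turns raw timestamped
behavior records — one row per scored event — into per-session state
sequences suitable for first-order Markov chain estimation.

Behavior names are matched case-insensitively after whitespace normalization,
so ``"Temporary Retreat"`` and ``"temporary  retreat"`` resolve to the same
state.  Consecutive repeats of the same behavior are collapsed by default:
the transition model has no self-transitions, only changes of behavior count.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "BehaviorState",
    "Stage",
    "Ethogram",
    "EventRecord",
    "EventSequence",
    "UnknownBehaviorError",
    "normalize_name",
    "vannamei_ethogram",
    "read_ethogram",
    "parse_event_log",
    "write_event_log",
    "build_sequences",
]

_WS = re.compile(r"[\s_]+")


def normalize_name(raw: str) -> str:
    """Canonicalize a behavior/stage name: lowercase, trim, collapse
    internal whitespace (and underscores) to single spaces."""
    return _WS.sub(" ", str(raw).strip()).lower()


class UnknownBehaviorError(ValueError):
    """A behavior name does not resolve against the ethogram."""


@dataclass(frozen=True)
class BehaviorState:
    """One discrete behavior pattern.

    Parameters
    ----------
    name
        Short lowercase identifier (canonical form, see :func:`normalize_name`).
    label
        Display name used in tables and diagrams.
    index
        0-based position in the ethogram's canonical order.
    """

    name: str
    label: str
    index: int


@dataclass(frozen=True)
class Stage:
    """A fighting stage: a named, nonempty group of behavior states."""

    name: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError(f"stage {self.name!r} contains no states")


@dataclass(frozen=True)
class Ethogram:
    """Ordered behavior states plus a total state→stage mapping."""

    states: tuple[BehaviorState, ...]
    stages: tuple[Stage, ...]
    name: str = ""
    _lookup: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError("an ethogram needs at least 2 states")
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise ValueError("state names must be unique")
        for i, s in enumerate(self.states):
            if s.index != i:
                raise ValueError(f"state {s.name!r} has index {s.index}, expected {i}")
        stage_names = [st.name for st in self.stages]
        if len(set(stage_names)) != len(stage_names):
            raise ValueError("stage names must be unique")
        seen: dict[str, str] = {}
        for st in self.stages:
            for nm in st.states:
                if nm not in set(names):
                    raise ValueError(f"stage {st.name!r} references unknown state {nm!r}")
                if nm in seen:
                    raise ValueError(f"state {nm!r} assigned to both {seen[nm]!r} and {st.name!r}")
                seen[nm] = st.name
        missing = set(names) - set(seen)
        if missing:
            raise ValueError(f"states missing from stage map: {sorted(missing)}")
        lookup = {s.name: s for s in self.states}
        for s in self.states:  # labels resolve too
            lookup.setdefault(normalize_name(s.label), s)
        object.__setattr__(self, "_lookup", lookup)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states)

    @property
    def stage_names(self) -> tuple[str, ...]:
        return tuple(st.name for st in self.stages)

    @property
    def stage_map(self) -> dict[str, str]:
        """Total mapping state name → stage name."""
        return {nm: st.name for st in self.stages for nm in st.states}

    def index_of(self, name: str) -> int:
        return self.resolve(name).index

    def stage_of(self, name: str) -> str:
        return self.stage_map[self.resolve(name).name]

    def resolve(self, raw: str) -> BehaviorState:
        """Resolve a (possibly messy) behavior name to its state."""
        state = self._lookup.get(normalize_name(raw))
        if state is None:
            valid = ", ".join(self.state_names)
            raise UnknownBehaviorError(
                f"unknown behavior {raw!r}; valid states: {valid}"
            )
        return state

    # -- construction ------------------------------------------------------

    @classmethod
    def from_mapping(cls, mapping: dict) -> "Ethogram":
        """Build from a plain dict with ``states`` (ordered list of names or
        ``{name, label}`` entries) and ``stages`` (mapping stage → state list)."""
        states = []
        for i, entry in enumerate(mapping["states"]):
            if isinstance(entry, str):
                nm = normalize_name(entry)
                label = entry.strip()
            else:
                nm = normalize_name(entry["name"])
                label = entry.get("label", entry["name"])
            states.append(BehaviorState(nm, label, i))
        stages = tuple(
            Stage(normalize_name(k), tuple(normalize_name(v) for v in vals))
            for k, vals in mapping["stages"].items()
        )
        return cls(tuple(states), stages, name=mapping.get("name", ""))


def read_ethogram(source) -> Ethogram:
    """Read an ethogram definition from a YAML (or JSON) file or stream."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            mapping = yaml.safe_load(fh)
    else:
        mapping = yaml.safe_load(source)
    return Ethogram.from_mapping(mapping)


def vannamei_ethogram() -> Ethogram:
    """The packaged nine-state agonistic ethogram of *L. vannamei*.

    Nine behavior patterns — parade, demonstration, attack, fight, chase,
    impact, feint, temporary retreat, retreat — grouped into the encounter,
    contact, and withdrawal stages of a fight.
    """
    text = resources.files("ethochain.data").joinpath("vannamei_ethogram.yaml").read_text()
    return read_ethogram(io.StringIO(text))


# ---------------------------------------------------------------------------
# Event records and sequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventRecord:
    """One scored behavior event within an observation session."""

    session_id: str
    time: float
    state: str
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative event time {self.time}")


@dataclass
class EventSequence:
    """Ordered behavior states of one session, as ethogram indices."""

    session_id: str
    states: list[int]

    def __len__(self) -> int:
        return len(self.states)

    @property
    def n_transitions(self) -> int:
        return max(len(self.states) - 1, 0)


_REQUIRED_COLUMNS = ("session_id", "time_s", "behavior")


def _infer_sep(source, delimiter: str | None) -> str | None:
    if delimiter is not None:
        return delimiter
    if isinstance(source, (str, Path)):
        suffix = Path(source).suffix.lower()
        if suffix == ".tsv":
            return "\t"
        if suffix == ".csv":
            return ","
    return None  # sniff


def parse_event_log(source, ethogram: Ethogram, delimiter: str | None = None) -> list[EventRecord]:
    """Parse a delimited event log into records, in file order.

    The log must have header columns ``session_id``, ``time_s`` and
    ``behavior``; ``subject_id`` is optional.  The delimiter is taken from
    the file extension (.csv/.tsv) unless given explicitly; otherwise it is
    sniffed.

    Raises
    ------
    ValueError
        On a missing required column or a non-numeric/negative time.
    UnknownBehaviorError
        When a behavior name does not resolve, naming the offending row.
    """
    sep = _infer_sep(source, delimiter)
    df = pd.read_csv(
        source,
        sep=sep,
        engine="python" if sep is None else "c",
        dtype=str,
        keep_default_na=False,
    )
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event log missing required column(s): {missing}")
    has_subject = "subject_id" in df.columns
    records: list[EventRecord] = []
    for row in df.itertuples(index=True):
        rownum = row.Index + 2  # 1-based, counting the header line
        raw_time = getattr(row, "time_s")
        try:
            t = float(raw_time)
        except ValueError:
            raise ValueError(f"row {rownum}: non-numeric time {raw_time!r}") from None
        if t < 0:
            raise ValueError(f"row {rownum}: negative time {t}")
        try:
            state = ethogram.resolve(getattr(row, "behavior"))
        except UnknownBehaviorError as exc:
            raise UnknownBehaviorError(f"row {rownum}: {exc}") from None
        subject = getattr(row, "subject_id") if has_subject else None
        records.append(
            EventRecord(str(row.session_id), t, state.name, subject or None)
        )
    return records


def write_event_log(records: Iterable[EventRecord], target, delimiter: str | None = None) -> None:
    """Write records back to a delimited event log (inverse of parsing)."""
    rows = list(records)
    sep = _infer_sep(target, delimiter) or ","
    df = pd.DataFrame(
        {
            "session_id": [r.session_id for r in rows],
            "subject_id": [r.subject_id or "" for r in rows],
            "time_s": [r.time for r in rows],
            "behavior": [r.state for r in rows],
        }
    )
    df.to_csv(target, sep=sep, index=False)


def build_sequences(
    records: Sequence[EventRecord],
    ethogram: Ethogram,
    collapse_runs: bool = True,
) -> list[EventSequence]:
    """Assemble per-session state sequences from event records.

    Records are sorted by time within each session, so the result does not
    depend on input row order.  With ``collapse_runs`` (the default),
    consecutive identical states are merged so that only behavior *changes*
    count as transitions.  Sessions with a single remaining event are kept;
    they simply contribute no transitions.  Sequences are returned sorted by
    session id.

    Raises
    ------
    ValueError
        If two records in the same session share a timestamp (ordering
        would be ambiguous).
    """
    by_session: dict[str, list[EventRecord]] = {}
    for rec in records:
        by_session.setdefault(rec.session_id, []).append(rec)
    sequences: list[EventSequence] = []
    for session_id in sorted(by_session):
        rows = sorted(by_session[session_id], key=lambda r: r.time)
        times = [r.time for r in rows]
        for a, b in zip(times, times[1:]):
            if a == b:
                raise ValueError(
                    f"session {session_id!r}: duplicate event time {a}"
                )
        indices = [ethogram.index_of(r.state) for r in rows]
        if collapse_runs:
            collapsed = [indices[0]]
            for ix in indices[1:]:
                if ix != collapsed[-1]:
                    collapsed.append(ix)
            indices = collapsed
        sequences.append(EventSequence(session_id, indices))
    return sequences
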