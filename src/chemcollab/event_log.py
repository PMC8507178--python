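"""Experiment event-log data model: parsing, validation, sessions, provenance.

An experiment log is an ordered sequence of molecule-creation events.  Each
event records who drew the molecule, when, its SMILES, its score, and the
event it was derived from (``parent_event_id``; null for a scratch start).
Two experiment modes exist: in *individual* mode each participant can only
branch from their own molecules, in *collective* mode from anyone's.

A *design session* is a contiguous editing episode by one participant that
starts from scratch or from a previously saved molecule.  Operationally, an
event opens a new session iff its parent is null, or its parent was created
by someone else, or its parent is not the most recent event of the same
participant at that moment (i.e. the participant re-opened an older
molecule); otherwise it continues its parent's session.

Native CSV schema: ``event_id,timestamp,participant_id,smiles,
parent_event_id,score``.  A flat mapping config renames external columns
onto this schema so foreign dialects parse without code changes.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Sequence

from .chem_core import MoleculeRecord, canonicalize

NATIVE_COLUMNS = (
    "event_id",
    "timestamp",
    "participant_id",
    "smiles",
    "parent_event_id",
    "score",
)


@dataclass(frozen=True)
class DesignEvent:
    event_id: str
    timestamp: datetime
    participant_id: str
    smiles: str
    parent_event_id: str | None
    score: int

    def sort_key(self) -> tuple[datetime, str]:
        # ties in timestamp are broken by event_id so downstream metrics
        # are deterministic
        return (self.timestamp, self.event_id)


@dataclass
class ValidationReport:
    """Structural findings from parsing: what was repaired or dropped."""

    n_events: int = 0
    warnings: list[str] = field(default_factory=list)
    dangling_parents: list[str] = field(default_factory=list)
    invalid_smiles_events: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_events": self.n_events,
                "warnings": self.warnings,
                "dangling_parents": self.dangling_parents,
                "invalid_smiles_events": self.invalid_smiles_events,
            },
            indent=2,
        )


@dataclass
class ExperimentLog:
    experiment_id: str
    mode: str  # "individual" | "collective"
    target: MoleculeRecord | None
    events: list[DesignEvent]
    validation: ValidationReport = field(default_factory=ValidationReport)

    def __post_init__(self) -> None:
        if self.mode not in ("individual", "collective"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        self.events.sort(key=DesignEvent.sort_key)
        self._by_id = {e.event_id: e for e in self.events}
        if len(self._by_id) != len(self.events):
            raise ValueError("duplicate event_id in log")

    @property
    def participants(self) -> set[str]:
        """Engaged participants: creators of at least one event."""
        return {e.participant_id for e in self.events}

    def event(self, event_id: str) -> DesignEvent:
        try:
            return self._by_id[event_id]
        except KeyError:
            raise KeyError(f"no such event: {event_id!r}") from None


@dataclass(frozen=True)
class ProvenancePath:
    """Parent-pointer chain from a scratch root down to a focal event."""

    events: tuple[DesignEvent, ...]  # root first
    creators: frozenset[str]
    session_sequence: tuple[int, ...]  # session of each event along the path

    @property
    def distinct_sessions(self) -> int:
        return len(set(self.session_sequence))


# ---------------------------------------------------------------------------
# Parsing / serialization


def _parse_timestamp(raw: str) -> datetime:
    ts = datetime.fromisoformat(str(raw).strip())
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts


def parse_log(
    path_or_stream,
    mapping_config: dict[str, str] | None = None,
    *,
    experiment_id: str = "experiment",
    mode: str = "collective",
    target_smiles: str | None = None,
    fmt: str | None = None,
) -> ExperimentLog:
    """Parse a CSV or JSONL event log into a validated :class:`ExperimentLog`.

    ``mapping_config`` maps native field names to source column names, e.g.
    ``{"participant_id": "user"}``.  Rows referencing a parent that is not in
    the file are kept with the parent nulled and a warning recorded.
    """
    if hasattr(path_or_stream, "read"):
        text = path_or_stream.read()
        name = getattr(path_or_stream, "name", "")
    else:
        with open(path_or_stream) as fh:
            text = fh.read()
        name = str(path_or_stream)
    if fmt is None:
        fmt = "jsonl" if name.endswith((".jsonl", ".ndjson")) else "csv"

    if fmt == "jsonl":
        rows = [json.loads(line) for line in text.splitlines() if line.strip()]
    elif fmt == "csv":
        rows = list(csv.DictReader(text.splitlines()))
    else:
        raise ValueError(f"unknown log format: {fmt!r}")

    mapping = {k: k for k in NATIVE_COLUMNS}
    if mapping_config:
        mapping.update(mapping_config)

    if rows:
        missing = [
            native
            for native, src in mapping.items()
            if native != "parent_event_id" and src not in rows[0]
        ]
        if missing:
            raise ValueError(f"missing mandatory column(s): {missing}")

    report = ValidationReport()
    events: list[DesignEvent] = []
    for row in rows:
        parent = row.get(mapping["parent_event_id"])
        if parent in ("", None, "null", "None", "NA"):
            parent = None
        events.append(
            DesignEvent(
                event_id=str(row[mapping["event_id"]]),
                timestamp=_parse_timestamp(row[mapping["timestamp"]]),
                participant_id=str(row[mapping["participant_id"]]),
                smiles=str(row[mapping["smiles"]]),
                parent_event_id=str(parent) if parent is not None else None,
                score=int(row[mapping["score"]]),
            )
        )

    ids = {e.event_id for e in events}
    resolved: list[DesignEvent] = []
    for e in events:
        if e.parent_event_id is not None and e.parent_event_id not in ids:
            report.dangling_parents.append(e.event_id)
            report.warnings.append(
                f"event {e.event_id}: parent {e.parent_event_id!r} not in log;"
                " treated as scratch start"
            )
            e = DesignEvent(
                e.event_id, e.timestamp, e.participant_id, e.smiles, None, e.score
            )
        resolved.append(e)

    for e in resolved:
        if not canonicalize(e.smiles).valid:
            report.invalid_smiles_events.append(e.event_id)
    report.n_events = len(resolved)

    target = canonicalize(target_smiles) if target_smiles else None
    log = ExperimentLog(
        experiment_id=experiment_id,
        mode=mode,
        target=target,
        events=resolved,
        validation=report,
    )
    _check_parent_order(log)
    return log


def _check_parent_order(log: ExperimentLog) -> None:
    for e in log.events:
        if e.parent_event_id is not None:
            p = log.event(e.parent_event_id)
            if p.timestamp > e.timestamp:
                log.validation.warnings.append(
                    f"event {e.event_id}: parent {p.event_id} has a later"
                    " timestamp"
                )


def write_log(log: ExperimentLog, path_or_stream, fmt: str = "csv") -> None:
    """Serialize a log back to the native CSV (or JSONL) schema."""
    rows = [
        {
            "event_id": e.event_id,
            "timestamp": e.timestamp.isoformat(),
            "participant_id": e.participant_id,
            "smiles": e.smiles,
            "parent_event_id": e.parent_event_id or "",
            "score": e.score,
        }
        for e in log.events
    ]
    own = not hasattr(path_or_stream, "write")
    fh = open(path_or_stream, "w", newline="") if own else path_or_stream
    try:
        if fmt == "csv":
            writer = csv.DictWriter(fh, fieldnames=NATIVE_COLUMNS)
            writer.writeheader()
            writer.writerows(rows)
        elif fmt == "jsonl":
            for row in rows:
                fh.write(json.dumps(row) + "\n")
        else:
            raise ValueError(f"unknown log format: {fmt!r}")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# Sessions and provenance


def assign_sessions(log: ExperimentLog) -> dict[str, int]:
    """Assign every event to a design session (event_id -> session number).

    Sessions are numbered in order of opening, starting at 1.
    """
    session_of: dict[str, int] = {}
    last_event_of: dict[str, str] = {}  # participant -> their latest event_id
    n_sessions = 0
    for e in log.events:
        new_session = True
        if e.parent_event_id is not None:
            parent = log.event(e.parent_event_id)
            if (
                parent.participant_id == e.participant_id
                and last_event_of.get(e.participant_id) == parent.event_id
            ):
                new_session = False
        if new_session:
            n_sessions += 1
            session_of[e.event_id] = n_sessions
        else:
            session_of[e.event_id] = session_of[e.parent_event_id]
        last_event_of[e.participant_id] = e.event_id
    return session_of


def provenance_path(log: ExperimentLog, event_id: str) -> ProvenancePath:
    """The unique parent-pointer chain from a scratch root to ``event_id``."""
    sessions = assign_sessions(log)
    chain: list[DesignEvent] = []
    seen: set[str] = set()
    cur: str | None = event_id
    while cur is not None:
        if cur in seen:
            raise ValueError(f"provenance cycle detected at event {cur!r}")
        seen.add(cur)
        e = log.event(cur)
        chain.append(e)
        cur = e.parent_event_id
    chain.reverse()
    return ProvenancePath(
        events=tuple(chain),
        creators=frozenset(e.participant_id for e in chain),
        session_sequence=tuple(sessions[e.event_id] for e in chain),
    )
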