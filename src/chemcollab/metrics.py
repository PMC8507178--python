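"""Experiment-level metric suite for design logs.

For each experiment the suite computes: the maximum score reached, the
number of unique molecules generated (InChIKey-distinct), the number of
scoring-function calls (all events, repetitions included), the time played
(idle gaps above a threshold omitted), the scaffold/molecule diversity
ratio, the number of leader changes, the forefront-participation percentage,
and — when the target molecule was found — the number of evolution steps
(distinct design sessions on its provenance path) and the collaboration
degree (share of the experiment's participants on that path).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

from . import chem_core
from .chem_core import canonicalize, murcko_scaffold, unique_inchikeys
from .event_log import ExperimentLog, DesignEvent, assign_sessions, provenance_path

#: Gaps between a participant's consecutive events strictly greater than
#: this many seconds are treated as idle time and omitted from time played.
IDLE_THRESHOLD_SECONDS = 60.0


@dataclass
class MetricsReport:
    """One experiment's row of the results table."""

    experiment_id: str
    mode: str
    max_score: int
    unique_molecules: int
    scoring_calls: int
    time_played_seconds: int
    scaffold_molecule_ratio: float
    leader_changes: int
    forefront_participation_pct: float
    n_participants: int
    target_found: bool
    target_evolution_steps: int | None
    target_collaboration_pct: float | None
    n_invalid_events: int
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_markdown(self) -> str:
        """Single-row markdown table in the results-table layout."""
        hours, rem = divmod(self.time_played_seconds, 3600)
        cols = [
            ("Experiment", self.experiment_id),
            ("Mode", self.mode),
            ("Time played", f"{hours}H {rem // 60} m"),
            ("Generated unique molecules", f"{self.unique_molecules:,}"),
            ("Scaffold/molecule ratio", f"{self.scaffold_molecule_ratio:.3f}"),
            ("Leader changes", str(self.leader_changes)),
            ("Max score", str(self.max_score)),
            ("Scoring calls", str(self.scoring_calls)),
            (
                "Target mol. evolution steps",
                "-" if self.target_evolution_steps is None
                else str(self.target_evolution_steps),
            ),
            (
                "Target mol. collaboration degree (%)",
                "-" if self.target_collaboration_pct is None
                else f"{self.target_collaboration_pct:g}",
            ),
        ]
        head = "| " + " | ".join(c for c, _ in cols) + " |"
        sep = "|" + "|".join(" --- " for _ in cols) + "|"
        row = "| " + " | ".join(v for _, v in cols) + " |"
        return "\n".join([head, sep, row])


def max_score(log: ExperimentLog) -> int:
    if not log.events:
        raise ValueError("empty log has no maximum score")
    return max(e.score for e in log.events)


def scoring_calls(log: ExperimentLog) -> int:
    """Every event is one scoring-function call; repetitions count."""
    return len(log.events)


def time_played(
    log: ExperimentLog, idle_threshold: float = IDLE_THRESHOLD_SECONDS
) -> tuple[dict[str, float], float]:
    """Seconds of active design time per participant, plus the total.

    A participant's time is the sum of gaps between their consecutive
    events; gaps strictly greater than ``idle_threshold`` are idle and
    contribute nothing, as does each participant's first event.
    """
    per: dict[str, float] = {}
    last_ts: dict[str, object] = {}
    for e in log.events:
        prev = last_ts.get(e.participant_id)
        if prev is not None:
            gap = (e.timestamp - prev).total_seconds()
            if gap <= idle_threshold:
                per[e.participant_id] = per.get(e.participant_id, 0.0) + gap
        per.setdefault(e.participant_id, 0.0)
        last_ts[e.participant_id] = e.timestamp
    return per, sum(per.values())


def scaffold_molecule_ratio(log: ExperimentLog) -> float:
    """Unique Murcko scaffolds divided by unique molecules (<= 1).

    All acyclic molecules share one sentinel scaffold class.
    """
    seen_keys: set[str] = set()
    scaffolds: set[str] = set()
    for e in log.events:
        rec = canonicalize(e.smiles)
        if not rec.valid or rec.inchikey in seen_keys:
            continue
        seen_keys.add(rec.inchikey)
        scaffolds.add(murcko_scaffold(rec))
    if not seen_keys:
        raise ValueError("no valid molecules in log")
    return len(scaffolds) / len(seen_keys)


def leader_changes(log: ExperimentLog) -> tuple[int, set[str]]:
    """Number of leader changes and the forefront creator set.

    Scanning events in order with a running (leader, best-score) state: an
    event strictly above the best score by a different creator is a leader
    change; strict self-improvement only raises the bar.  The first event
    installs the initial leader without counting.  Forefront creators are
    the creators of every strict running-max improvement (first included).
    """
    if not log.events:
        raise ValueError("empty log has no leader")
    changes = 0
    leader: str | None = None
    best = -1
    forefront: set[str] = set()
    for e in log.events:
        if e.score > best:
            if leader is not None and e.participant_id != leader:
                changes += 1
            leader = e.participant_id
            best = e.score
            forefront.add(e.participant_id)
    return changes, forefront


def evolution_steps(log: ExperimentLog, target_event_id: str) -> int:
    """Distinct design sessions along the event's provenance path."""
    return provenance_path(log, target_event_id).distinct_sessions


def collaboration_degree(log: ExperimentLog, target_event_id: str) -> float:
    """Percentage of engaged participants appearing on the provenance path."""
    path = provenance_path(log, target_event_id)
    return 100.0 * len(path.creators) / len(log.participants)


def find_target_event(log: ExperimentLog) -> DesignEvent | None:
    """Earliest event whose InChIKey equals the target's, if any.

    InChIKey equality — not score 1000 — defines target discovery, because
    1024-bucket fingerprint hashing can in principle give a non-target
    molecule similarity 1.
    """
    if log.target is None or not log.target.valid:
        return None
    for e in log.events:
        rec = canonicalize(e.smiles)
        if rec.valid and rec.inchikey == log.target.inchikey:
            return e
    return None


def metrics_report(
    log: ExperimentLog,
    idle_threshold: float = IDLE_THRESHOLD_SECONDS,
    tanimoto_variant: str = "minmax",
) -> MetricsReport:
    """Assemble the full metric row for one experiment."""
    if not log.events:
        raise ValueError("cannot report on an empty log")
    keys, n_invalid = unique_inchikeys([e.smiles for e in log.events])
    changes, forefront = leader_changes(log)
    _, total_seconds = time_played(log, idle_threshold)
    target_event = find_target_event(log)
    return MetricsReport(
        experiment_id=log.experiment_id,
        mode=log.mode,
        max_score=max_score(log),
        unique_molecules=len(keys),
        scoring_calls=scoring_calls(log),
        time_played_seconds=int(round(total_seconds)),
        scaffold_molecule_ratio=scaffold_molecule_ratio(log),
        leader_changes=changes,
        forefront_participation_pct=100.0 * len(forefront) / len(log.participants),
        n_participants=len(log.participants),
        target_found=target_event is not None,
        target_evolution_steps=(
            None if target_event is None else evolution_steps(log, target_event.event_id)
        ),
        target_collaboration_pct=(
            None
            if target_event is None
            else collaboration_degree(log, target_event.event_id)
        ),
        n_invalid_events=n_invalid,
        config={
            "fingerprint": f"ECFC{chem_core.FP_RADIUS * 2}_{chem_core.FP_BUCKETS}",
            "tanimoto_variant": tanimoto_variant,
            "idle_threshold_seconds": idle_threshold,
            "session_rule": "parent-null|cross-creator|reopened-older-molecule",
        },
    )
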