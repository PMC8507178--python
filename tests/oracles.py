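"""Independent brute-force re-implementations of the experiment metrics.

These deliberately avoid the package's incremental scan logic: everything
is recomputed from the raw event list with whole-list lookups (and networkx
for provenance), so agreement with the pipeline is a genuine cross-check
rather than the same code twice.
"""

from __future__ import annotations

import networkx as nx
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold


def _events(log):
    return sorted(log.events, key=lambda e: (e.timestamp, e.event_id))


def bf_max_score(log) -> int:
    return max(e.score for e in _events(log))


def bf_scoring_calls(log) -> int:
    return len(log.events)


def bf_unique_inchikeys(log) -> set[str]:
    keys = []
    for e in _events(log):
        mol = Chem.MolFromSmiles(e.smiles)
        if mol is not None:
            keys.append(Chem.MolToInchiKey(mol))
    # quadratic pairwise partition instead of set()
    classes: list[str] = []
    for k in keys:
        if not any(k == c for c in classes):
            classes.append(k)
    return set(classes)


def bf_time_played(log, idle_threshold: float = 60.0) -> float:
    total = 0.0
    for p in {e.participant_id for e in log.events}:
        ts = sorted(e.timestamp for e in log.events if e.participant_id == p)
        for a, b in zip(ts, ts[1:]):
            gap = (b - a).total_seconds()
            if gap <= idle_threshold:
                total += gap
    return total


def bf_scaffold_ratio(log) -> float:
    mols: dict[str, Chem.Mol] = {}
    for e in _events(log):
        m = Chem.MolFromSmiles(e.smiles)
        if m is not None:
            mols.setdefault(Chem.MolToInchiKey(m), m)
    scaffolds = set()
    for m in mols.values():
        smi = Chem.MolToSmiles(MurckoScaffold.GetScaffoldForMol(m))
        scaffolds.add(smi if smi else "<acyclic>")
    return len(scaffolds) / len(mols)


def bf_leader_changes(log) -> tuple[int, set[str]]:
    ev = _events(log)
    scores = [e.score for e in ev]
    improvements = [
        i for i in range(len(ev)) if scores[i] > max(scores[:i], default=-1)
    ]
    leaders = [ev[i].participant_id for i in improvements]
    changes = sum(1 for a, b in zip(leaders, leaders[1:]) if a != b)
    return changes, set(leaders)


def bf_session_of(log) -> dict[str, int]:
    """Non-incremental session assignment from the new-session predicate."""
    ev = _events(log)
    by_id = {e.event_id: e for e in ev}

    def opens_new_session(i: int) -> bool:
        e = ev[i]
        if e.parent_event_id is None:
            return True
        parent = by_id[e.parent_event_id]
        if parent.participant_id != e.participant_id:
            return True
        before = [x for x in ev[:i] if x.participant_id == e.participant_id]
        return before[-1].event_id != parent.event_id

    session: dict[str, int] = {}
    n = 0
    for i, e in enumerate(ev):
        if opens_new_session(i):
            n += 1
            session[e.event_id] = n
        else:
            session[e.event_id] = session[e.parent_event_id]
    return session


def _provenance_chain(log, event_id: str) -> list:
    g = nx.DiGraph()
    for e in log.events:
        g.add_node(e.event_id)
        if e.parent_event_id is not None:
            g.add_edge(e.parent_event_id, e.event_id)
    chain = [event_id]
    while True:
        preds = list(g.predecessors(chain[0]))
        if not preds:
            break
        chain.insert(0, preds[0])
    by_id = {e.event_id: e for e in log.events}
    return [by_id[i] for i in chain]


def bf_evolution_steps(log, event_id: str) -> int:
    sessions = bf_session_of(log)
    return len({sessions[e.event_id] for e in _provenance_chain(log, event_id)})


def bf_collaboration_pct(log, event_id: str) -> float:
    creators = {e.participant_id for e in _provenance_chain(log, event_id)}
    participants = {e.participant_id for e in log.events}
    return 100.0 * len(creators) / len(participants)
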