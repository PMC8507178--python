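"""Agent-based generator of experiment logs for the analysis pipeline.

The generator emulates the *structure* of human design experiments — score-
guided incremental editing with occasional scratch restarts, provenance
pointers, per-event scores, and the individual/collective visibility rule —
not human cognition.  Agents act in round-robin; each move either restarts
from a single carbon atom or picks a parent from the visible pool (own
molecules in individual mode, everyone's in collective mode) by a softmax
over normalized scores, then applies a few random valence-valid graph edits.

Randomness comes from one master seed that spawns per-agent substreams, so
adding an agent does not perturb the trajectories of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from importlib import resources

import numpy as np
from rdkit import Chem

from .chem_core import MoleculeRecord, canonicalize
from .event_log import DesignEvent, ExperimentLog, parse_log
from .scoring import normalized_score

EDIT_KINDS = (
    "add_atom",
    "remove_terminal_atom",
    "change_bond_order",
    "form_ring_bond",
    "break_ring_bond",
    "substitute_element",
)

#: Sampling weights of the edit kinds: growth and element swaps dominate,
#: ring surgery is rare — roughly the move mix of a human sketching editor.
EDIT_KIND_WEIGHTS = (0.35, 0.15, 0.10, 0.05, 0.05, 0.30)

_BOND_ORDERS = (Chem.BondType.SINGLE, Chem.BondType.DOUBLE, Chem.BondType.TRIPLE)

#: The packaged easy target (1-heptanol, 8 heavy atoms) used for seed-pooled
#: individual-vs-collective comparisons: a near-monotone similarity landscape
#: that desk-scale simulations can actually solve.
EASY_TARGET_SMILES = "CCCCCCCO"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one simulated experiment.

    Defaults describe a desk-scale experiment: a handful of agents editing
    small organic molecules, mostly extending their latest good candidate,
    occasionally restarting from scratch, with mostly short (in-session)
    inter-event gaps and occasional long idle pauses so that idle-time
    filtering has something to filter.
    """

    target_smiles: str
    n_agents: int = 5
    mode: str = "collective"  # "individual" | "collective"
    max_events: int = 500
    seed: int = 0
    restart_probability: float = 0.05
    selection_greediness: float = 30.0  # softmax inverse temperature
    edits_per_move: tuple[int, int] = (1, 1)
    element_alphabet: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl")
    max_heavy_atoms: int = 60
    # inter-event gap mixture: short in-session gaps, rare long idle gaps
    short_gap_range: tuple[float, float] = (1.0, 12.0)
    long_gap_range: tuple[float, float] = (61.0, 300.0)
    long_gap_probability: float = 0.1
    start_time: str = "2021-03-01T10:00:00+00:00"

    def __post_init__(self) -> None:
        if self.mode not in ("individual", "collective"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        if self.n_agents < 1:
            raise ValueError("need at least one agent")
        if self.max_events < self.n_agents:
            raise ValueError("max_events must be >= n_agents")
        if not (0.0 <= self.restart_probability <= 1.0):
            raise ValueError("restart_probability must be in [0,1]")


# ---------------------------------------------------------------------------
# Random valence-valid molecule edits


def _sanitized(mol: Chem.RWMol) -> Chem.Mol | None:
    try:
        out = mol.GetMol()
        Chem.SanitizeMol(out)
        if out.GetNumHeavyAtoms() == 0:
            return None
        frags = Chem.GetMolFrags(out)
        if len(frags) > 1:
            return None  # edits must keep a single covalent structure
        return out
    except Exception:
        return None


def _free_valence(atom: Chem.Atom) -> int:
    return atom.GetTotalNumHs()


def _apply_edit(
    mol: Chem.Mol, kind: str, rng: np.random.Generator, config: SimulationConfig
) -> Chem.Mol | None:
    """Apply one edit of the given kind; None when inapplicable/invalid."""
    rw = Chem.RWMol(mol)
    n = rw.GetNumAtoms()
    if kind == "add_atom":
        if n >= config.max_heavy_atoms:
            return None
        sites = [a.GetIdx() for a in rw.GetAtoms() if _free_valence(a) >= 1]
        if not sites:
            return None
        site = int(rng.choice(sites))
        elem = str(rng.choice(config.element_alphabet))
        new = rw.AddAtom(Chem.Atom(elem))
        rw.AddBond(site, new, Chem.BondType.SINGLE)
    elif kind == "remove_terminal_atom":
        if n <= 1:
            return None
        terminals = [a.GetIdx() for a in rw.GetAtoms() if a.GetDegree() == 1]
        if not terminals:
            return None
        rw.RemoveAtom(int(rng.choice(terminals)))
    elif kind == "change_bond_order":
        if rw.GetNumBonds() == 0:
            return None
        bond = rw.GetBondWithIdx(int(rng.integers(rw.GetNumBonds())))
        order = _BOND_ORDERS[int(rng.integers(len(_BOND_ORDERS)))]
        if bond.GetBondType() == order:
            return None
        bond.SetBondType(order)
    elif kind == "form_ring_bond":
        sites = [a.GetIdx() for a in rw.GetAtoms() if _free_valence(a) >= 1]
        if len(sites) < 2:
            return None
        i, j = (int(x) for x in rng.choice(sites, size=2, replace=False))
        if rw.GetBondBetweenAtoms(i, j) is not None:
            return None
        rw.AddBond(i, j, Chem.BondType.SINGLE)
    elif kind == "break_ring_bond":
        ring_bonds = [b.GetIdx() for b in rw.GetBonds() if b.IsInRing()]
        if not ring_bonds:
            return None
        b = rw.GetBondWithIdx(int(rng.choice(ring_bonds)))
        rw.RemoveBond(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    elif kind == "substitute_element":
        idx = int(rng.integers(n))
        elem = str(rng.choice(config.element_alphabet))
        if rw.GetAtomWithIdx(idx).GetSymbol() == elem:
            return None
        rw.GetAtomWithIdx(idx).SetAtomicNum(Chem.Atom(elem).GetAtomicNum())
    else:
        raise ValueError(f"unknown edit kind: {kind!r}")
    out = _sanitized(rw)
    if out is not None and out.GetNumHeavyAtoms() > config.max_heavy_atoms:
        return None
    return out


def mutate(
    mol: MoleculeRecord,
    rng: np.random.Generator,
    config: SimulationConfig,
    max_retries: int = 20,
) -> tuple[MoleculeRecord, bool]:
    """One random valence-valid edit of a molecule.

    Rejected edits (invalid valence, fragmentation, size cap) are resampled
    up to ``max_retries`` times; on exhaustion the input is returned
    unchanged with ``mutated=False``.
    """
    base = mol.mol
    # at the size cap only shrinking/substituting edits remain applicable
    at_cap = base.GetNumHeavyAtoms() >= config.max_heavy_atoms
    if at_cap:
        kinds = ("remove_terminal_atom", "substitute_element", "break_ring_bond")
        weights = None
    else:
        kinds = EDIT_KINDS
        weights = EDIT_KIND_WEIGHTS
    for _ in range(max_retries):
        kind = str(rng.choice(kinds, p=weights))
        out = _apply_edit(base, kind, rng, config)
        if out is not None:
            return canonicalize(Chem.MolToSmiles(out)), True
    return mol, False


# ---------------------------------------------------------------------------
# The experiment simulator


def _softmax_pick(
    scores: list[int], rng: np.random.Generator, greediness: float
) -> int:
    z = np.asarray(scores, dtype=float) / 1000.0 * greediness
    z -= z.max()  # numerical stability
    p = np.exp(z)
    p /= p.sum()
    return int(rng.choice(len(scores), p=p))


def simulate_experiment(config: SimulationConfig) -> ExperimentLog:
    """Run one simulated experiment and return its event log.

    Stops when some agent draws the target molecule (InChIKey match) or
    after ``max_events`` events.  Identical config (seed included) yields a
    byte-identical log.
    """
    target = canonicalize(config.target_smiles)
    if not target.valid:
        raise ValueError(f"unparsable target: {config.target_smiles!r}")

    agent_rngs = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(config.seed).spawn(config.n_agents)
    ]
    clock = datetime.fromisoformat(config.start_time)
    events: list[DesignEvent] = []
    # visible pool per agent: indices into events with a valid molecule
    own_pool: list[list[int]] = [[] for _ in range(config.n_agents)]
    shared_pool: list[int] = []
    carbon = canonicalize("C")
    found = False

    while len(events) < config.max_events and not found:
        for a in range(config.n_agents):
            if len(events) >= config.max_events or found:
                break
            rng = agent_rngs[a]
            pool = shared_pool if config.mode == "collective" else own_pool[a]
            restart = not pool or rng.random() < config.restart_probability
            if restart:
                parent_idx = None
                base = carbon
            else:
                pick = _softmax_pick(
                    [events[i].score for i in pool], rng, config.selection_greediness
                )
                parent_idx = pool[pick]
                base = canonicalize(events[parent_idx].smiles)

            n_edits = int(rng.integers(config.edits_per_move[0],
                                       config.edits_per_move[1] + 1))
            mol = base
            for _ in range(n_edits):
                mol, _changed = mutate(mol, rng, config)

            if rng.random() < config.long_gap_probability:
                gap = rng.uniform(*config.long_gap_range)
            else:
                gap = rng.uniform(*config.short_gap_range)
            clock = clock + timedelta(seconds=float(gap))

            score = normalized_score(mol, target)
            idx = len(events)
            events.append(
                DesignEvent(
                    event_id=f"e{idx + 1:05d}",
                    timestamp=clock,
                    participant_id=f"agent{a + 1}",
                    smiles=mol.smiles_canonical,
                    parent_event_id=(
                        None if parent_idx is None else events[parent_idx].event_id
                    ),
                    score=score.normalized,
                )
            )
            own_pool[a].append(idx)
            shared_pool.append(idx)
            if mol.inchikey == target.inchikey:
                found = True

    return ExperimentLog(
        experiment_id=f"sim-{config.mode}-seed{config.seed}",
        mode=config.mode,
        target=target,
        events=events,
    )


def fixture_log() -> ExperimentLog:
    """The packaged hand-authored 28-event log (3 participants).

    Every metric of this log is documented in the adjacent expectations
    file ``data/fixture_expectations.json``; tests hold the pipeline to it
    field-for-field.
    """
    data = resources.files("chemcollab.data")
    expectations = fixture_expectations()
    with (data / "fixture_log.csv").open() as fh:
        return parse_log(
            fh,
            experiment_id="fixture",
            mode="collective",
            target_smiles=expectations["target_smiles"],
            fmt="csv",
        )


def fixture_expectations() -> dict:
    """The authored expected metric values of the fixture log."""
    import json

    text = resources.files("chemcollab.data").joinpath(
        "fixture_expectations.json"
    ).read_text()
    return json.loads(text)
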