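"""Molecule normalization, uniqueness, scaffolds and complexity profiling.

Every structure entering the pipeline passes through :func:`canonicalize`,
which yields a :class:`MoleculeRecord` carrying the canonical SMILES and the
standard InChIKey.  Uniqueness anywhere downstream is defined as InChIKey
equality (the full 27-character key, never a truncation).

The fingerprint used throughout is a count-based extended-connectivity
fingerprint of diameter 4 (atom environments of radius 0, 1 and 2) hashed
into 1024 buckets — ECFC4_1024 in the common shorthand — computed with
RDKit's Morgan generator.  Environments covering an already-seen bond set
are deduplicated by the generator, so the total count of a molecule is in
general smaller than 3 x (number of heavy atoms).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

# RDKit is chatty about unparsable SMILES; invalid input is an expected,
# handled condition here (dirty experiment logs), so silence the C++ logger.
RDLogger.DisableLog("rdApp.error")

FP_RADIUS = 2  # diameter 4
FP_BUCKETS = 1024

#: Scaffold class assigned to acyclic molecules.  They have no Murcko
#: framework; all of them share this one sentinel class in ratio metrics.
ACYCLIC_SCAFFOLD = "<acyclic>"

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(
    radius=FP_RADIUS, fpSize=FP_BUCKETS
)


@dataclass(frozen=True)
class MoleculeRecord:
    """A validated molecule.

    ``valid`` is False when the input SMILES did not parse/sanitize; all
    derived fields are then ``None`` and structure-based operations refuse
    the record.
    """

    smiles_input: str
    valid: bool
    smiles_canonical: str | None = None
    inchikey: str | None = None
    heavy_atom_count: int | None = None
    _mol: Chem.Mol | None = field(default=None, compare=False, repr=False)

    @property
    def mol(self) -> Chem.Mol:
        if not self.valid or self._mol is None:
            raise ValueError(f"invalid molecule: {self.smiles_input!r}")
        return self._mol


@dataclass(frozen=True)
class CountFingerprint:
    """Sparse count fingerprint: bucket index (0..1023) -> count >= 1."""

    buckets: dict[int, int]

    @property
    def cardinality(self) -> int:
        """Number of buckets with nonzero count."""
        return len(self.buckets)

    @property
    def total_count(self) -> int:
        """Sum of all individual counts."""
        return sum(self.buckets.values())

    def __eq__(self, other: object) -> bool:  # dict equality; order-free
        return isinstance(other, CountFingerprint) and self.buckets == other.buckets

    def __hash__(self) -> int:
        return hash(frozenset(self.buckets.items()))


@dataclass(frozen=True)
class ComplexityProfile:
    """The five size/complexity features used for target equivalence."""

    heavy_atoms: int
    aliphatic_rings: int
    aromatic_rings: int
    cardinality: int
    total_fingerprints: int

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (
            self.heavy_atoms,
            self.aliphatic_rings,
            self.aromatic_rings,
            self.cardinality,
            self.total_fingerprints,
        )


def canonicalize(smiles: str) -> MoleculeRecord:
    """Parse and normalize a SMILES string into a :class:`MoleculeRecord`.

    Unparsable or unsanitizable input yields a record with ``valid=False``
    rather than raising, so log ingestion can continue over dirty rows.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        return MoleculeRecord(smiles_input=str(smiles), valid=False)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumHeavyAtoms() == 0:
        return MoleculeRecord(smiles_input=smiles, valid=False)
    return MoleculeRecord(
        smiles_input=smiles,
        valid=True,
        smiles_canonical=Chem.MolToSmiles(mol),
        inchikey=Chem.MolToInchiKey(mol),
        heavy_atom_count=mol.GetNumHeavyAtoms(),
        _mol=mol,
    )


def count_fingerprint(mol: MoleculeRecord) -> CountFingerprint:
    """ECFC4_1024 count fingerprint of a valid molecule."""
    fp = _MORGAN.GetCountFingerprint(mol.mol)
    return CountFingerprint(buckets=dict(fp.GetNonzeroElements()))


def complexity_profile(mol: MoleculeRecord) -> ComplexityProfile:
    """Heavy atoms, ring counts (SSSR after aromaticity perception) and
    fingerprint cardinality/total for a valid molecule."""
    m = mol.mol
    fp = count_fingerprint(mol)
    return ComplexityProfile(
        heavy_atoms=m.GetNumHeavyAtoms(),
        aliphatic_rings=rdMolDescriptors.CalcNumAliphaticRings(m),
        aromatic_rings=rdMolDescriptors.CalcNumAromaticRings(m),
        cardinality=fp.cardinality,
        total_fingerprints=fp.total_count,
    )


def murcko_scaffold(mol: MoleculeRecord) -> str:
    """Canonical SMILES of the Murcko framework (ring systems + linkers).

    Acyclic molecules have no framework and map to :data:`ACYCLIC_SCAFFOLD`,
    a single shared scaffold class.
    """
    core = MurckoScaffold.GetScaffoldForMol(mol.mol)
    smi = Chem.MolToSmiles(core)
    return smi if smi else ACYCLIC_SCAFFOLD


def unique_molecule_count(smiles_list: Sequence[str]) -> int:
    """Number of distinct InChIKeys among the valid entries."""
    keys, _ = unique_inchikeys(smiles_list)
    return len(keys)


def unique_inchikeys(smiles_list: Sequence[str]) -> tuple[set[str], int]:
    """Distinct InChIKeys of the valid entries plus the invalid-entry count."""
    keys: set[str] = set()
    n_invalid = 0
    for smi in smiles_list:
        rec = canonicalize(smi)
        if rec.valid:
            keys.add(rec.inchikey)
        else:
            n_invalid += 1
    return keys, n_invalid


def complexity_equivalent(a: ComplexityProfile, b: ComplexityProfile) -> bool:
    """True iff all five complexity features are pairwise equal."""
    return a.as_tuple() == b.as_tuple()


def select_equivalent_targets(
    reference: MoleculeRecord, candidates: Sequence[MoleculeRecord]
) -> list[MoleculeRecord]:
    """Candidates whose complexity profile equals the reference's, in order."""
    ref = complexity_profile(reference)
    return [
        c
        for c in candidates
        if c.valid and complexity_equivalent(complexity_profile(c), ref)
    ]


# ---------------------------------------------------------------------------
# The five goal-directed benchmark drugs with their published complexity
# features (heavy atoms, aliphatic rings, aromatic rings, fingerprint
# cardinality, total fingerprint count) as computed with the original
# CDK ECFC4_1024 engine.  Heavy-atom/ring counts are toolkit-independent;
# cardinality can shift by a bucket or two across engines because 1024-bucket
# folding collides differently, so table1_fidelity() reports any per-molecule
# deviation explicitly.

BENCHMARK_DRUGS: dict[str, str] = {
    "Albuterol": "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",
    "Celecoxib": "Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1",
    "Thiothixene": "CN1CCN(CC/C=C2\\c3ccccc3Sc3ccc(S(=O)(=O)N(C)C)cc32)CC1",
    "Aripiprazole": "O=C1CCc2ccc(OCCCCN3CCN(c4cccc(Cl)c4Cl)CC3)cc2N1",
    "Troglitazone": "Cc1c(C)c2c(c(C)c1O)CCC(C)(COc1ccc(CC3SC(=O)NC3=O)cc1)O2",
}

REFERENCE_PROFILES: dict[str, ComplexityProfile] = {
    "Albuterol": ComplexityProfile(17, 0, 1, 33, 45),
    "Celecoxib": ComplexityProfile(26, 0, 3, 41, 71),
    "Thiothixene": ComplexityProfile(30, 2, 2, 51, 85),
    "Aripiprazole": ComplexityProfile(30, 2, 2, 53, 87),
    "Troglitazone": ComplexityProfile(31, 2, 2, 54, 86),
}

#: Complexity level of each benchmark drug (L1 easiest .. L5 hardest).
DRUG_COMPLEXITY_LEVEL: dict[str, str] = {
    "Albuterol": "L1",
    "Celecoxib": "L2",
    "Thiothixene": "L3",
    "Aripiprazole": "L4",
    "Troglitazone": "L5",
}


def table1_fidelity() -> dict[str, dict[str, tuple[int, int]]]:
    """Per-drug comparison of computed vs reference complexity features.

    Returns ``{drug: {feature: (computed, reference)}}`` containing only the
    features that deviate; an empty inner dict means exact agreement.  This
    is the audit trail for cross-toolkit fingerprint-hashing differences.
    """
    fields = (
        "heavy_atoms",
        "aliphatic_rings",
        "aromatic_rings",
        "cardinality",
        "total_fingerprints",
    )
    out: dict[str, dict[str, tuple[int, int]]] = {}
    for name, smi in BENCHMARK_DRUGS.items():
        prof = complexity_profile(canonicalize(smi))
        ref = REFERENCE_PROFILES[name]
        out[name] = {
            f: (getattr(prof, f), getattr(ref, f))
            for f in fields
            if getattr(prof, f) != getattr(ref, f)
        }
    return out


# ---------------------------------------------------------------------------
# File ingestion


def read_smiles_file(path_or_stream) -> list[tuple[str, str]]:
    """Read a SMILES file: one molecule per line, optional tab-separated id,
    '#' comment lines and blank lines ignored.  Returns (smiles, id) pairs."""
    if hasattr(path_or_stream, "read"):
        lines = path_or_stream.read().splitlines()
    else:
        with open(path_or_stream) as fh:
            lines = fh.read().splitlines()
    out: list[tuple[str, str]] = []
    for i, line in enumerate(lines):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smi = parts[0].strip()
        ident = parts[1].strip() if len(parts) > 1 else f"mol{i + 1}"
        out.append((smi, ident))
    return out


def read_target_manifest(path_or_stream) -> list[dict[str, str]]:
    """Read a target manifest CSV with columns id,smiles,complexity_level."""
    if hasattr(path_or_stream, "read"):
        fh = path_or_stream
        rows = list(csv.DictReader(fh))
    else:
        with open(path_or_stream, newline="") as fh:
            rows = list(csv.DictReader(fh))
    required = {"id", "smiles", "complexity_level"}
    if rows and not required.issubset(rows[0].keys()):
        missing = required - set(rows[0].keys())
        raise ValueError(f"target manifest missing columns: {sorted(missing)}")
    return rows
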