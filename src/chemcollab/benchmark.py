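"""Goal-directed benchmark scoring of molecule streams.

Two benchmark types are supported, mirroring the goal-directed suite used
to compare human and automatic de novo design:

* *rediscovery* — score is the single best (top-1) raw count-Tanimoto
  similarity to a fixed target molecule;
* *similarity* — each molecule's raw similarity is passed through the
  0.75-threshold modifier, and the benchmark score is the average of the
  top-1, top-10 and top-100 mean scores.

Molecule streams are deduplicated by InChIKey before ranking, so a
structure drawn repeatedly cannot fill several top-k slots.  The published
scores of the automatic baseline generators (smiles_lstm, graph_ga,
smiles_ga, graph_mcts, best_of_chembl) ship as quoted constants for
comparison tables; they are never recomputed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from statistics import mean
from typing import Sequence

from .chem_core import MoleculeRecord, canonicalize, count_fingerprint
from .event_log import ExperimentLog
from .scoring import ThresholdSpec, tanimoto_count, thresholded_modifier

REDISCOVERY_TOP_KS = (1,)
SIMILARITY_TOP_KS = (1, 10, 100)


@dataclass(frozen=True)
class BenchmarkSpec:
    name: str
    type: str  # "rediscovery" | "similarity"
    target: MoleculeRecord
    threshold: float | None = None
    top_ks: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.type not in ("rediscovery", "similarity"):
            raise ValueError(f"unknown benchmark type: {self.type!r}")
        if self.type == "similarity" and self.threshold is None:
            raise ValueError("similarity benchmarks require a threshold")
        if not self.top_ks:
            ks = REDISCOVERY_TOP_KS if self.type == "rediscovery" else SIMILARITY_TOP_KS
            object.__setattr__(self, "top_ks", ks)

    @classmethod
    def rediscovery(cls, name: str, target_smiles: str) -> "BenchmarkSpec":
        return cls(name=name, type="rediscovery", target=canonicalize(target_smiles))

    @classmethod
    def similarity(
        cls,
        name: str,
        target_smiles: str,
        threshold: float = 0.75,
        top_ks: tuple[int, ...] = (),
    ) -> "BenchmarkSpec":
        return cls(
            name=name,
            type="similarity",
            target=canonicalize(target_smiles),
            threshold=threshold,
            top_ks=top_ks,
        )

    @classmethod
    def from_json(cls, path_or_stream) -> "BenchmarkSpec":
        if hasattr(path_or_stream, "read"):
            cfg = json.load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                cfg = json.load(fh)
        return cls(
            name=cfg["name"],
            type=cfg["type"],
            target=canonicalize(cfg["target"]),
            threshold=cfg.get("threshold"),
            top_ks=tuple(cfg.get("top_ks", ())),
        )


@dataclass(frozen=True)
class BenchmarkResult:
    name: str
    per_k_means: dict[int, float]
    final_score: float
    n_molecules_considered: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "per_k_means": {str(k): v for k, v in self.per_k_means.items()},
                "final_score": self.final_score,
                "n_molecules_considered": self.n_molecules_considered,
            },
            indent=2,
        )


def benchmark_score(
    molecules: Sequence[MoleculeRecord],
    spec: BenchmarkSpec,
    *,
    permissive: bool = False,
    tanimoto_variant: str = "minmax",
) -> BenchmarkResult:
    """Score a molecule stream against one goal-directed benchmark.

    With fewer unique molecules than the largest requested k this raises,
    unless ``permissive`` is set, in which case each top-k mean is taken
    over the molecules available (with a warning).
    """
    target_fp = count_fingerprint(spec.target)
    seen: set[str] = set()
    scores: list[float] = []
    for rec in molecules:
        if not rec.valid or rec.inchikey in seen:
            continue
        seen.add(rec.inchikey)
        sim = tanimoto_count(count_fingerprint(rec), target_fp, tanimoto_variant)
        if spec.type == "similarity":
            sim = thresholded_modifier(sim, ThresholdSpec(spec.threshold))
        scores.append(sim)

    max_k = max(spec.top_ks)
    if len(scores) < max_k:
        if not permissive:
            raise ValueError(
                f"benchmark {spec.name!r} needs at least {max_k} unique"
                f" molecules, got {len(scores)}"
            )
        warnings.warn(
            f"benchmark {spec.name!r}: only {len(scores)} unique molecules"
            f" for top-{max_k}; means taken over available molecules",
            stacklevel=2,
        )
    if not scores:
        raise ValueError(f"benchmark {spec.name!r}: no valid molecules to score")

    scores.sort(reverse=True)
    per_k = {k: mean(scores[: min(k, len(scores))]) for k in spec.top_ks}
    if spec.type == "rediscovery":
        final = per_k[1]
    else:
        final = mean(per_k.values())
    return BenchmarkResult(
        name=spec.name,
        per_k_means=per_k,
        final_score=final,
        n_molecules_considered=len(scores),
    )


def log_to_benchmark(
    log: ExperimentLog, spec: BenchmarkSpec, **kwargs
) -> BenchmarkResult:
    """Score the unique valid molecules of an experiment log."""
    records = [canonicalize(e.smiles) for e in log.events]
    return benchmark_score([r for r in records if r.valid], spec, **kwargs)


# ---------------------------------------------------------------------------
# Printed baseline constants and comparison tables


def load_baselines() -> dict:
    """Quoted published scores of the automatic baseline generators."""
    text = resources.files("chemcollab.data").joinpath(
        "guacamol_baselines.json"
    ).read_text()
    return json.loads(text)


def comparison_table(
    results: dict[str, BenchmarkResult], benchmark_name: str
) -> list[dict]:
    """Merge computed results with the quoted baselines for one benchmark.

    Returns one row per method with a ``source`` flag distinguishing values
    computed by this package from constants quoted from the literature.
    """
    data = load_baselines()["benchmarks"]
    if benchmark_name not in data:
        raise KeyError(f"no quoted baselines for benchmark {benchmark_name!r}")
    rows: list[dict] = []
    for method, res in results.items():
        rows.append(
            {
                "method": method,
                "final": round(res.final_score, 2),
                **{f"top{k}": round(v, 2) for k, v in res.per_k_means.items()},
                "source": "computed",
            }
        )
    for method, cells in data[benchmark_name]["baselines"].items():
        rows.append(
            {
                "method": method,
                **{k: v for k, v in cells.items()},
                "source": "quoted",
            }
        )
    return rows


def comparison_markdown(rows: list[dict]) -> str:
    cols = ["method", "final", "top1", "top10", "top100", "source"]
    present = [c for c in cols if any(c in r for r in rows)]
    head = "| " + " | ".join(present) + " |"
    sep = "|" + "|".join(" --- " for _ in present) + "|"
    body = [
        "| " + " | ".join(str(r.get(c, "-")) for c in present) + " |" for r in rows
    ]
    return "\n".join([head, sep] + body)
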