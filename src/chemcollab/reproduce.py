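"""Recompute the published per-experiment results from deposited raw logs.

The study deposited the raw event data of its ten experiments (five
individual, five collective, complexity levels L1-L5) as supplementary
material.  When that export is available locally this module replays it
through the metric suite, one :class:`~chemcollab.metrics.MetricsReport`
per experiment, so every printed per-experiment value (unique molecules,
scoring calls, leader changes, evolution steps, collaboration degree, ...)
can be recomputed rather than quoted.

Expected layout (CSV):

* event file — the native event schema plus ``experiment_id`` and ``mode``
  columns, experiment ids of the form ``L4-collective``; a column-mapping
  config can adapt other dialects;
* optional target manifest next to it (``targets.csv``, columns
  ``id,smiles,complexity_level``) giving each experiment's target structure
  (deposited separately from the event data).  Without it, target-dependent
  fields are computed from score-1000 events' structures.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .chem_core import canonicalize, read_target_manifest
from .event_log import NATIVE_COLUMNS, parse_log
from .metrics import MetricsReport, metrics_report


def _split_experiments(path: Path, mapping: dict[str, str] | None):
    mapping = {**{k: k for k in NATIVE_COLUMNS}, **(mapping or {}),
               "experiment_id": (mapping or {}).get("experiment_id", "experiment_id"),
               "mode": (mapping or {}).get("mode", "mode")}
    groups: dict[str, list[dict]] = {}
    modes: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            exp = row[mapping["experiment_id"]]
            groups.setdefault(exp, []).append(row)
            modes[exp] = row.get(mapping["mode"], exp.split("-")[-1])
    return groups, modes, mapping


def reproduce_published_rows(
    path, mapping_config: dict[str, str] | None = None
) -> dict[str, dict]:
    """Metric rows for every experiment in a deposited raw-data export.

    Returns ``{experiment_id: metric dict}`` with the fields of
    :class:`MetricsReport`.
    """
    path = Path(path)
    groups, modes, mapping = _split_experiments(path, mapping_config)

    targets: dict[str, str] = {}
    manifest = path.with_name("targets.csv")
    if manifest.exists():
        for row in read_target_manifest(manifest):
            targets[row["id"]] = row["smiles"]

    out: dict[str, dict] = {}
    for exp, rows in groups.items():
        target_smiles = targets.get(exp)
        if target_smiles is None:
            # fall back to the found target's own structure, if any
            hits = [r for r in rows if int(r[mapping["score"]]) == 1000]
            if hits:
                target_smiles = hits[0][mapping["smiles"]]
        header = ",".join(NATIVE_COLUMNS)
        body = "\n".join(
            ",".join(str(r[mapping[c]] or "") for c in NATIVE_COLUMNS)
            for r in rows
        )
        import io

        log = parse_log(
            io.StringIO(header + "\n" + body),
            experiment_id=exp,
            mode=modes[exp] if modes[exp] in ("individual", "collective")
            else "collective",
            target_smiles=target_smiles,
            fmt="csv",
        )
        rep = metrics_report(log)
        out[exp] = {
            "max_score": rep.max_score,
            "unique_molecules": rep.unique_molecules,
            "scoring_calls": rep.scoring_calls,
            "time_played_seconds": rep.time_played_seconds,
            "scaffold_molecule_ratio": rep.scaffold_molecule_ratio,
            "leader_changes": rep.leader_changes,
            "target_found": rep.target_found,
            "target_evolution_steps": rep.target_evolution_steps,
            "target_collaboration_pct": rep.target_collaboration_pct,
        }
    return out
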