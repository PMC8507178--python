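#!/usr/bin/env python
"""Chemical-space maps of one individual and one collective simulated run.

Projects each run's unique molecules (ECFC4_1024 count fingerprints) to 2D
with t-SNE at a fixed seed and writes the coordinates, annotated with the
creating participant and the creation order — the two colorings used to
compare how spread each participant's exploration is in the two modes.
"""

from pathlib import Path

from chemcollab import parse_log
from chemcollab.embedding import embed_log
from chemcollab.synthetic import EASY_TARGET_SMILES

ROOT = Path(__file__).resolve().parent.parent
LOGS = ROOT / "scratch" / "logs"
OUT = ROOT / "results"
OUT.mkdir(exist_ok=True)

if not LOGS.exists():
    raise SystemExit("run 02_simulate_experiments.py first")

for mode in ("individual", "collective"):
    log = parse_log(
        LOGS / f"sim-{mode}-seed0.csv", experiment_id=f"sim-{mode}",
        mode=mode, target_smiles=EASY_TARGET_SMILES,
    )
    coords = embed_log(log, seed=0)
    out = OUT / f"embedding_{mode}.csv"
    coords.to_csv(out, index=False)
    spread = coords.groupby("participant_id")[["x", "y"]].std().mean(axis=1)
    print(
        f"{mode}: {len(coords)} unique molecules embedded; mean per-participant "
        f"coordinate spread {spread.mean():.1f} (per participant: "
        f"{spread.round(1).to_dict()}); wrote {out}"
    )
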