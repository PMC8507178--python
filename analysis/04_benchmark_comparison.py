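#!/usr/bin/env python
"""Goal-directed benchmark scores of simulated search vs published baselines.

Scores the unique-molecule streams of one collective and one individual
simulated run on rediscovery and 0.75-thresholded similarity benchmarks
against the simulation target, then renders the five published benchmark
comparison tables in which the automatic de novo baselines (smiles_lstm,
graph_ga, smiles_ga, graph_mcts, best_of_chembl) appear as quoted
constants.  Simulated agents are not humans: their scores are shown beside
the baselines to demonstrate the comparison machinery, not to re-estimate
the human results.
"""

from pathlib import Path

from chemcollab import BenchmarkSpec, log_to_benchmark, parse_log
from chemcollab.benchmark import comparison_markdown, comparison_table, load_baselines
from chemcollab.synthetic import EASY_TARGET_SMILES

ROOT = Path(__file__).resolve().parent.parent
LOGS = ROOT / "scratch" / "logs"
OUT = ROOT / "results"
OUT.mkdir(exist_ok=True)

if not LOGS.exists():
    raise SystemExit("run 02_simulate_experiments.py first")

sections = []

redisc = BenchmarkSpec.rediscovery("heptanol rediscovery", EASY_TARGET_SMILES)
simil = BenchmarkSpec.similarity("heptanol similarity", EASY_TARGET_SMILES)
sections.append("## Simulated agents on the simulation target\n")
for mode in ("collective", "individual"):
    log = parse_log(
        LOGS / f"sim-{mode}-seed0.csv", experiment_id=f"sim-{mode}",
        mode=mode, target_smiles=EASY_TARGET_SMILES,
    )
    r1 = log_to_benchmark(log, redisc)
    r2 = log_to_benchmark(log, simil, permissive=True)
    sections.append(
        f"- {mode}: rediscovery final {r1.final_score:.2f}; thresholded "
        f"similarity final {r2.final_score:.2f} over "
        f"{r2.n_molecules_considered} unique molecules"
    )

sections.append("\n## Published baseline tables (quoted constants)\n")
for name in load_baselines()["benchmarks"]:
    sections.append(f"### {name}\n")
    sections.append(comparison_markdown(comparison_table({}, name)))
    sections.append("")

text = "\n".join(sections)
(OUT / "benchmark_comparison.md").write_text(text + "\n")
print(text)
print(f"\nWrote {OUT/'benchmark_comparison.md'}")
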