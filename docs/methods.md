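# Methods

## The score

Molecules are represented by count-based extended-connectivity
fingerprints of diameter 4 (atom environments of radius 0, 1, 2), hashed
into 1024 buckets (ECFC4_1024), computed with RDKit's Morgan generator.
Environments covering an already-seen bond set are deduplicated by the
generator, which is why a 17-heavy-atom molecule such as albuterol has a
total count of 45 rather than 3 × 17 = 51.

Similarity between two count fingerprints defaults to the min/max
generalization of Tanimoto, `Σ min(a_k,b_k) / Σ max(a_k,b_k)`; the
dot-product generalization `a·b / (|a|² + |b|² − a·b)` is selectable with
`variant="dot"`. Which of the two the original scoring engine (CDK) used
is not documented, so the choice is recorded in every report. The in-app
score is the similarity times 1000, rounded half away from zero; 1000 is
reached only at similarity exactly 1. Benchmark scoring uses the same
engine; the application that produced the human data used a slightly
different internal score for display, which this package deliberately does
not attempt to reproduce separately.

### Fingerprint-engine fidelity

Heavy-atom and ring counts, and the *total* fingerprint count, are
engine-independent and reproduce the published complexity features of all
five benchmark drugs exactly. Fingerprint *cardinality* (nonzero buckets)
depends on how a toolkit folds environment identifiers into 1024 buckets:
albuterol agrees exactly (33/45), while the other four drugs' cardinalities
differ by 1–2 buckets from the values computed with the original CDK
engine (celecoxib 39 vs 41, thiothixene 49 vs 51, aripiprazole 54 vs 53,
troglitazone 55 vs 54). These deviations are hash-collision artifacts, not
structural disagreements; `chem_core.table1_fidelity()` reports them per
molecule and per feature, and the test suite asserts that any deviation is
confined to cardinality and surfaced there.

## Experiment logs and derived metrics

A log is a time-ordered sequence of events `(event_id, timestamp, creator,
SMILES, parent, score)`; timestamp ties are broken by `event_id` so every
downstream metric is deterministic. Scratch starts have a null parent; the
single-carbon seed molecule is treated as scratch, not as a shared parent.
Dangling parent references are nulled with a warning rather than dropped,
and events with unparsable SMILES are kept for call counting but excluded
from all structure-based metrics (molecule uniqueness, scaffolds,
benchmark streams).

*Sessions.* An event opens a new design session iff its parent is null,
its parent was created by someone else, or its parent is not the most
recent event of the same participant at that moment (re-opening an older
molecule). Otherwise it continues its parent's session. This is the
operational reading of "a design session includes all molecules generated
starting from scratch or from a certain molecule already in the system";
the rule lives in one function (`event_log.assign_sessions`) so alternative
readings can be swapped in.

*Metrics.* Uniqueness is full 27-character standard InChIKey equality.
Time played sums, per participant, gaps between consecutive events that
are ≤ 60 s (strictly longer gaps count as idle; both the threshold and the
strictness are parameters). The scaffold/molecule ratio is unique Murcko
scaffolds ÷ unique molecules; acyclic molecules have no Murcko framework
and share one sentinel scaffold class. Leader changes come from a running
maximum scan: a strict improvement by a different creator is a change, the
first event installs the initial leader without counting, and forefront
creators are the creators of all strict improvements. Target discovery is
decided by InChIKey equality with the target — not by score 1000, since
1024-bucket hashing can in principle give a non-target molecule similarity
1. Evolution steps are the distinct sessions along the target's
parent-pointer path; collaboration degree is the percentage of *engaged*
participants (≥ 1 event, not invited participants) on that path.

*Benchmarks.* Streams are deduplicated by InChIKey before ranking, so a
redrawn molecule cannot fill several top-k slots. Rediscovery scores the
top-1 raw similarity; similarity benchmarks apply the 0.75-threshold
modifier and average the top-1/10/100 means. Fewer unique molecules than
the largest k is an error by default; a permissive mode averages over what
is available and warns. The published baseline scores ship in
`data/guacamol_baselines.json` and every comparison row is flagged
`computed` or `quoted`.

## The simulator

The generator's purpose is *structural* realism — logs with provenance,
sessions, leaders, restarts, and the individual/collective visibility
difference — not cognitive fidelity; no claim is made that the agents
model human design. Agents act in round-robin. Each move restarts from a
single carbon with probability 0.05 (or when nothing is visible), else
selects a parent from the visible pool by softmax over normalized scores
with inverse temperature 30 (score differences of 0.1 weigh e³ ≈ 20:1),
then applies one random valence-valid graph edit drawn from {add atom
(0.35), remove terminal atom (0.15), change bond order (0.10), form ring
bond (0.05), break ring bond (0.05), substitute element (0.30)} over the
alphabet C, N, O, S, F, Cl, with rejected edits resampled up to 20 times.
Molecules are capped at 60 heavy atoms; at the cap only shrinking and
substituting edits apply. Inter-event gaps are a mixture of short
in-session gaps (1–12 s, 90%) and long idle gaps (61–300 s, 10%) so the
idle-time filter is exercised in both directions. One master seed spawns
per-agent substreams, so identical configs give byte-identical logs and
adding an agent does not perturb the others' randomness.

The packaged easy target for seed-pooled mode comparisons is 1-heptanol
(`CCCCCCCO`, 8 heavy atoms). Its near-monotone similarity landscape is
what makes a desk-scale random-edit hill climb solvable: across 20 seeds
with 5 agents and at most 2000 events, both modes find it in every run,
collective in a median of ~360 events versus ~1060 individually. Branched
or aromatic targets of the same size are deceptive for this edit set
(reaching them requires chains of score-decreasing edits) and desk-scale
runs then stall below score 500 — a limitation of the simple agent policy,
not of the metric pipeline. Simulated logs therefore exercise the
analysis machinery and the qualitative collective-vs-individual direction;
they do not reproduce, and are not meant to reproduce, the human
experiments' quantitative results.

## The fixture log

`data/fixture_log.csv` is a hand-authored 28-event collective experiment
(3 participants, 8 sessions) whose every metric is documented in
`data/fixture_expectations.json`: 24 unique molecules (two deliberate
duplicates), 385 s played (idle gaps straddle the 60 s threshold on both
sides), 5 leader changes, and a target reached through a 5-event
provenance path crossing 3 sessions and all 3 participants. Sessions,
leader scan, time sums and the provenance path were derived by hand at
authoring time; the stored per-event scores were computed with the scoring
engine so that score-recomputation validation holds exactly.

## Verification strategy and problem sizes

Every metric is checked against an independent brute-force
re-implementation (whole-list scans, networkx provenance; no shared code
with the pipeline) on the fixture and on 100 simulated logs of up to 200
events spanning both modes — problem sizes chosen so the full suite runs
in well under a minute of metric checking. The seed-pooled mode comparison
uses 20 seeds per mode at 5 agents / 2000 events. Reproducing the published
human per-experiment numbers requires the study's deposited raw logs; the
replay machinery (`chemcollab.reproduce`) is tested on a synthetic export
of the same layout, and the corresponding end-to-end check fails with an
explicit message when the deposited data is not present locally.

## Known limitations

- Cross-toolkit fingerprint cardinalities can differ by a few buckets
  (reported, see above); similarity values involving affected molecules
  can therefore differ in the third decimal from the original engine's.
- Aromaticity perception is RDKit's default model; ring classification
  (aromatic vs aliphatic) is pinned to it and recorded in reports.
- The session rule is one operational reading of an informally stated
  definition; deposited logs with explicit session identifiers would take
  precedence over the inferred rule.
- The agent policy is a deliberately simple stochastic hill climb; see
  above for what that does and does not license.
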