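{
  "_comment": "Hand-authored expectations for the packaged fixture log. Sessions, leader scan, time-played sums, provenance path and scaffold classes were derived manually at authoring time; scores were computed with the package's scoring engine (minmax count-Tanimoto, ECFC4_1024).",
  "target_smiles": "CCc1ccc(O)c(N)c1",
  "n_events": 28,
  "n_participants": 3,
  "max_score": 1000,
  "unique_molecules": 24,
  "scoring_calls": 28,
  "time_played_seconds": 385,
  "time_played_per_participant": {
    "alice": 145,
    "bob": 135,
    "carol": 105
  },
  "unique_scaffolds": 2,
  "scaffold_molecule_ratio": 0.08333333333333333,
  "leader_changes": 5,
  "forefront_creators": [
    "alice",
    "bob",
    "carol"
  ],
  "forefront_participation_pct": 100.0,
  "target_found": true,
  "target_event_id": "e28",
  "target_evolution_steps": 3,
  "target_collaboration_pct": 100.0,
  "n_sessions": 8,
  "session_of": {
    "e01": 1,
    "e02": 1,
    "e03": 1,
    "e09": 1,
    "e10": 1,
    "e04": 2,
    "e05": 2,
    "e06": 2,
    "e07": 3,
    "e08": 3,
    "e12": 3,
    "e17": 3,
    "e18": 3,
    "e11": 4,
    "e15": 4,
    "e13": 5,
    "e14": 5,
    "e19": 5,
    "e20": 5,
    "e26": 5,
    "e16": 6,
    "e21": 6,
    "e22": 6,
    "e27": 6,
    "e23": 7,
    "e24": 7,
    "e25": 7,
    "e28": 8
  },
  "target_provenance": {
    "event_ids": [
      "e07",
      "e08",
      "e12",
      "e16",
      "e28"
    ],
    "creators": [
      "alice",
      "bob",
      "carol"
    ],
    "distinct_sessions": 3
  },
  "duplicate_events": {
    "e14": "e12",
    "e22": "e16"
  },
  "n_invalid_events": 0
}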