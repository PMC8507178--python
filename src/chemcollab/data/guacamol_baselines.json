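{
  "description": "Published goal-directed benchmark scores of the automatic de novo baseline generators, quoted cell-by-cell from the printed comparison table. All values are quoted constants, never computed here.",
  "benchmarks": {
    "Celecoxib rediscovery": {
      "complexity_level": "L2",
      "type": "rediscovery",
      "baselines": {
        "smiles_lstm": {"final": 1.0, "top1": 1.0},
        "graph_ga": {"final": 1.0, "top1": 1.0},
        "smiles_ga": {"final": 0.732, "top1": 0.732},
        "graph_mcts": {"final": 0.355, "top1": 0.355},
        "best_of_chembl": {"final": 0.505, "top1": 0.505}
      }
    },
    "Thiothixene rediscovery": {
      "complexity_level": "L3",
      "type": "rediscovery",
      "baselines": {
        "smiles_lstm": {"final": 1.0, "top1": 1.0},
        "graph_ga": {"final": 1.0, "top1": 1.0},
        "smiles_ga": {"final": 0.598, "top1": 0.598},
        "graph_mcts": {"final": 0.311, "top1": 0.311},
        "best_of_chembl": {"final": 0.456, "top1": 0.456}
      }
    },
    "Troglitazone rediscovery": {
      "complexity_level": "L5",
      "type": "rediscovery",
      "baselines": {
        "smiles_lstm": {"final": 1.0, "top1": 1.0},
        "graph_ga": {"final": 1.0, "top1": 1.0},
        "smiles_ga": {"final": 0.515, "top1": 0.515},
        "graph_mcts": {"final": 0.311, "top1": 0.311},
        "best_of_chembl": {"final": 0.419, "top1": 0.419}
      }
    },
    "Albuterol similarity": {
      "complexity_level": "L1",
      "type": "similarity",
      "baselines": {
        "smiles_lstm": {"final": 1.0, "top1": 1.0, "top10": 1.0, "top100": 1.0},
        "graph_ga": {"final": 1.0, "top1": 1.0, "top10": 1.0, "top100": 1.0},
        "smiles_ga": {"final": 0.907, "top1": 1.0, "top10": 1.0, "top100": 1.0},
        "graph_mcts": {"final": 0.749, "top1": 0.80, "top10": 0.758, "top100": 0.72},
        "best_of_chembl": {"final": 0.719, "top1": 0.765, "top10": 0.726, "top100": 0.689}
      }
    },
    "Aripiprazole similarity": {
      "complexity_level": "L4",
      "type": "similarity",
      "baselines": {
        "smiles_lstm": {"final": 1.0, "top1": 1.0, "top10": 1.0, "top100": 1.0},
        "graph_ga": {"final": 1.0, "top1": 1.0, "top10": 1.0, "top100": 1.0},
        "smiles_ga": {"final": 0.834, "top1": 0.856, "top10": 0.838, "top100": 0.807},
        "graph_mcts": {"final": 0.380, "top1": 0.428, "top10": 0.376, "top100": 0.335},
        "best_of_chembl": {"final": 0.595, "top1": 0.609, "top10": 0.601, "top100": 0.576}
      }
    }
  },
  "scoring_calls_to_target": {
    "description": "Published scoring-function-call counts needed to reach each target (null = target not reached).",
    "smiles_lstm": {"L1": 132838, "L2": 132846, "L3": 138209, "L4": 139221, "L5": 140339},
    "human_individual": {"L1": 3614, "L2": null, "L3": null, "L4": null, "L5": null},
    "human_collective": {"L1": 1956, "L2": 4271, "L3": 5404, "L4": 4591, "L5": 12118}
  }
}
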