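"""t-SNE projection of the chemical space explored during an experiment.

Unique molecules are described by their ECFC4_1024 count fingerprints and
embedded in 2D with t-distributed stochastic neighbor embedding at a fixed
seed.  The output carries, per molecule, the participant who first drew it
and its creation order, the two colorings used to inspect individual vs
collective exploration patterns.  The layout is a qualitative visualization
aid only; no quantitative claim rests on it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .chem_core import FP_BUCKETS, canonicalize, count_fingerprint
from .event_log import ExperimentLog

MIN_MOLECULES = 10


def embed_log(log: ExperimentLog, seed: int = 0, perplexity: float = 30.0) -> pd.DataFrame:
    """2D t-SNE coordinates of an experiment's unique molecules.

    Returns a DataFrame with columns ``inchikey, smiles, participant_id,
    creation_order, x, y``.  Raises when fewer than 10 unique molecules are
    present (a degenerate embedding).
    """
    seen: dict[str, tuple[str, str, int]] = {}
    fps = []
    for order, e in enumerate(log.events):
        rec = canonicalize(e.smiles)
        if not rec.valid or rec.inchikey in seen:
            continue
        seen[rec.inchikey] = (rec.smiles_canonical, e.participant_id, order)
        fps.append(count_fingerprint(rec))
    n = len(seen)
    if n < MIN_MOLECULES:
        raise ValueError(
            f"embedding needs at least {MIN_MOLECULES} unique molecules, got {n}"
        )
    X = np.zeros((n, FP_BUCKETS))
    for i, fp in enumerate(fps):
        for k, c in fp.buckets.items():
            X[i, k] = c
    tsne = TSNE(
        n_components=2,
        random_state=seed,
        perplexity=min(perplexity, (n - 1) / 3),
        init="pca",
    )
    coords = tsne.fit_transform(X)
    return pd.DataFrame(
        {
            "inchikey": list(seen.keys()),
            "smiles": [v[0] for v in seen.values()],
            "participant_id": [v[1] for v in seen.values()],
            "creation_order": [v[2] for v in seen.values()],
            "x": coords[:, 0],
            "y": coords[:, 1],
        }
    )
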