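"""The molecular score and the goal-directed benchmark scoring primitives.

The in-app score shown to participants is the count-fingerprint Tanimoto
similarity to the target, linearly normalized to the 0-1000 integer range.
Benchmarks use the same raw similarity, for similarity-type benchmarks
adjusted by a threshold modifier that saturates at 1.0 above the threshold
and decreases linearly to zero below it.

For count vectors two Tanimoto generalizations are in circulation:

``minmax``   sum_k min(a_k, b_k) / sum_k max(a_k, b_k)        (default)
``dot``      a.b / (|a|^2 + |b|^2 - a.b)

Which one the original scoring engine used is not documented, so both are
implemented; every report records the variant in effect.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem_core import CountFingerprint, MoleculeRecord, count_fingerprint

SCORE_MAX = 1000


@dataclass(frozen=True)
class ScoreValue:
    """Raw similarity in [0,1] and its 0-1000 normalized integer form."""

    similarity: float
    normalized: int


@dataclass(frozen=True)
class ThresholdSpec:
    """Threshold of the similarity-benchmark modifier (default 0.75)."""

    threshold: float = 0.75

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError(f"threshold must be in (0,1]: {self.threshold}")


def tanimoto_count(
    a: CountFingerprint, b: CountFingerprint, variant: str = "minmax"
) -> float:
    """Tanimoto similarity of two count fingerprints."""
    if not a.buckets and not b.buckets:
        raise ValueError("similarity of two empty fingerprints is undefined")
    if variant == "minmax":
        num = 0
        den = 0
        for k in a.buckets.keys() | b.buckets.keys():
            ak = a.buckets.get(k, 0)
            bk = b.buckets.get(k, 0)
            num += min(ak, bk)
            den += max(ak, bk)
        return num / den
    if variant == "dot":
        dot = sum(c * b.buckets.get(k, 0) for k, c in a.buckets.items())
        na = sum(c * c for c in a.buckets.values())
        nb = sum(c * c for c in b.buckets.values())
        return dot / (na + nb - dot)
    raise ValueError(f"unknown tanimoto variant: {variant!r}")


def normalize_similarity(similarity: float) -> int:
    """Linear 0-1000 normalization, rounding half away from zero."""
    if not (0.0 <= similarity <= 1.0):
        raise ValueError(f"similarity out of [0,1]: {similarity}")
    # int(x + 0.5) rounds half away from zero for nonnegative x; avoids
    # banker's rounding so that e.g. 0.7215 -> 722 is stable at the boundary
    return int(SCORE_MAX * similarity + 0.5)


def normalized_score(
    mol: MoleculeRecord, target: MoleculeRecord, variant: str = "minmax"
) -> ScoreValue:
    """In-app score of ``mol`` against ``target``."""
    sim = tanimoto_count(count_fingerprint(mol), count_fingerprint(target), variant)
    return ScoreValue(similarity=sim, normalized=normalize_similarity(sim))


def thresholded_modifier(
    similarity: float, spec: ThresholdSpec = ThresholdSpec()
) -> float:
    """Full score (1.0) at or above the threshold, linear decrease below."""
    if not (0.0 <= similarity <= 1.0):
        raise ValueError(f"similarity out of [0,1]: {similarity}")
    return min(similarity, spec.threshold) / spec.threshold
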