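"""Probe-vs-gallery identity scoring and ranked candidate lists.

The identity score between two vector maps is the average, over probe
descriptors, of the squared Euclidean distance to each descriptor's nearest
neighbor in the gallery entry.  Small scores mean strong matches.  The score
is asymmetric (the probe side is averaged); matching direction is probe ->
gallery throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .errors import UnmatchableError
from .features import DescriptorSet
from .preprocess import PipelineConfig

__all__ = [
    "distance_score",
    "brute_force_distance_score",
    "apply_gender_filter",
    "rank_matches",
    "RankedMatchList",
    "MatchOutcome",
    "Outcome",
    "classify_outcome",
]


def distance_score(probe: DescriptorSet, entry: DescriptorSet) -> float:
    """Average nearest-neighbor squared Euclidean distance, probe -> entry.

    Vectorized (BLAS-backed) evaluation of
    ``(1/n_probe) * sum_i min_j ||p_i - e_j||^2``.  Agrees with the brute
    force double loop to floating-point accuracy; zero when probe and entry
    are identical sets.
    """
    if probe.unmatchable or entry.unmatchable:
        raise UnmatchableError("cannot score an empty descriptor set")
    d2 = cdist(probe.descriptors, entry.descriptors, metric="sqeuclidean")
    return float(d2.min(axis=1).mean())


def brute_force_distance_score(probe: DescriptorSet, entry: DescriptorSet) -> float:
    """Reference semantics: explicit double loop over descriptor pairs.

    Kept as the independent oracle for the accelerated implementation; never
    used on the identification path.
    """
    if probe.unmatchable or entry.unmatchable:
        raise UnmatchableError("cannot score an empty descriptor set")
    p = probe.descriptors.astype(np.float64)
    e = entry.descriptors.astype(np.float64)
    total = 0.0
    for i in range(p.shape[0]):
        best = np.inf
        for j in range(e.shape[0]):
            diff = p[i] - e[j]
            d2 = float(diff @ diff)
            if d2 < best:
                best = d2
        total += best
    return total / p.shape[0]


def apply_gender_filter(gallery: Sequence, label: Optional[str]) -> list:
    """Narrow the gallery to records whose gender label matches exactly.

    An unknown probe label (``None`` or empty string) disables the filter
    for this query — identification degrades gracefully to the unfiltered
    search rather than erroring.
    """
    if not label:
        return list(gallery)
    return [rec for rec in gallery if rec.gender == label]


@dataclass(frozen=True)
class RankedMatchList:
    """Ascending-score candidate list of at most ``top_k`` subjects.

    Scores are non-decreasing; subject IDs are unique; ties are broken
    lexicographically by subject ID for cross-platform determinism.
    """

    entries: Tuple[Tuple[str, float], ...]

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(b < a for a, b in zip(scores, scores[1:])):
            raise ValueError("ranked list scores must be non-decreasing")
        ids = [i for i, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("ranked list subject IDs must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def rank_of(self, subject_id: str) -> Optional[int]:
        """1-based rank of ``subject_id`` in this list, or None if absent."""
        for rank, (sid, _) in enumerate(self.entries, start=1):
            if sid == subject_id:
                return rank
        return None


def rank_matches(
    probe: DescriptorSet,
    gallery: Sequence,
    config: PipelineConfig,
    probe_gender: Optional[str] = None,
) -> RankedMatchList:
    """Score the probe against every (optionally gender-filtered) record.

    Returns the ``config.top_k`` smallest-score candidates in ascending
    order.  A gallery that is empty after filtering yields an empty list;
    fewer than ``top_k`` survivors yield a shorter list (no padding).
    """
    if probe.unmatchable:
        raise UnmatchableError("probe has no descriptors")
    records = list(gallery)
    if config.use_gender_filter:
        records = apply_gender_filter(records, probe_gender)
    scored = [
        (rec.subject_id, distance_score(probe, rec.composite))
        for rec in records
        if not rec.composite.unmatchable
    ]
    scored.sort(key=lambda t: (t[1], t[0]))
    return RankedMatchList(tuple(scored[: config.top_k]))


class Outcome(str, Enum):
    TOP1 = "top1"
    TOP10 = "top10"
    NONE = "none"


@dataclass(frozen=True)
class MatchOutcome:
    """Identification outcome for one probe against the ranked list.

    Rank 1 counts as both a top-1 and a top-10 match; rank 2..k as top-10
    only; a true subject absent from the list is "no match".
    """

    outcome: Outcome
    rank: Optional[int]

    @property
    def is_top1(self) -> bool:
        return self.outcome is Outcome.TOP1

    @property
    def is_top10(self) -> bool:
        return self.outcome in (Outcome.TOP1, Outcome.TOP10)


def classify_outcome(ranked: RankedMatchList, true_id: str) -> MatchOutcome:
    rank = ranked.rank_of(true_id)
    if rank is None:
        return MatchOutcome(Outcome.NONE, None)
    if rank == 1:
        return MatchOutcome(Outcome.TOP1, 1)
    return MatchOutcome(Outcome.TOP10, rank)
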