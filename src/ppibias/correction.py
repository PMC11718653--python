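"""Study-bias corrections of node degree.

AP-MS and Y2H studies are asymmetric: a few actively chosen baits are tested
against many preys, so a bait's degree partly reflects how often it was
tested, not how promiscuous it is.  Three corrections are provided:

* per-study bait/prey recomputation — count only interactions in which a
  protein played the *larger* role set's counterpart (prey-degree for
  bait-poor studies, bait-degree for prey-poor studies);
* bait-normalized degree — divide a protein's aggregated degree by the number
  of times it served as bait;
* hub extraction — the top-k proteins by any of these scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

from .analytic import BaitUsage

__all__ = [
    "RoleAnnotatedStudy",
    "size_balance",
    "corrected_degrees",
    "normalized_degrees",
    "top_hubs",
]


@dataclass
class RoleAnnotatedStudy:
    """One study's (bait, prey) interaction records.

    Self-interactions are dropped with a warning and duplicate (bait, prey)
    records de-duplicated, preserving first-occurrence order.  ``unoriented``
    holds records whose bait/prey roles were not annotated; they take part in
    aggregation but not in role-based corrections.
    """

    study_id: str
    interactions: list = field(default_factory=list)
    method: str = "unspecified"
    unoriented: list = field(default_factory=list)

    def __post_init__(self):
        cleaned, seen = [], set()
        n_self = 0
        for bait, prey in self.interactions:
            if bait == prey:
                n_self += 1
                continue
            if (bait, prey) in seen:
                continue
            seen.add((bait, prey))
            cleaned.append((bait, prey))
        if n_self:
            warnings.warn(
                f"study {self.study_id}: dropped {n_self} self-interaction record(s)",
                stacklevel=2,
            )
        self.interactions = cleaned

    @property
    def baits(self) -> set:
        return {b for b, _ in self.interactions}

    @property
    def preys(self) -> set:
        return {p for _, p in self.interactions}

    @property
    def proteins(self) -> set:
        out = self.baits | self.preys
        for a, b in self.unoriented:
            out.update((a, b))
        return out

    @property
    def edges(self) -> set:
        """Unique undirected interactions, including unoriented records."""
        out = {frozenset(e) for e in self.interactions}
        out |= {frozenset(e) for e in self.unoriented if e[0] != e[1]}
        return out

    @property
    def has_role_info(self) -> bool:
        return len(self.interactions) > 0


def size_balance(n_bait: int, n_prey: int) -> float:
    """min/max ratio of bait and prey counts; 1 means a symmetric design."""
    if n_bait < 1 or n_prey < 1:
        raise ValueError("bait and prey counts must be positive")
    return min(n_bait, n_prey) / max(n_bait, n_prey)


def corrected_degrees(study: RoleAnnotatedStudy) -> dict:
    """Recompute degrees from the larger role set only.

    If the study has no more baits than preys, each protein's degree is the
    number of interactions in which it is the *prey* (and conversely for
    prey-poor studies).  Proteins appearing only in the non-counted role stay
    in the map with degree 0.  Ties (n_bait == n_prey) count prey-degrees.
    """
    if not study.interactions:
        raise ValueError(f"study {study.study_id} has no role-annotated interactions")
    deg = dict.fromkeys(study.baits | study.preys, 0)
    use_prey = len(study.baits) <= len(study.preys)
    for bait, prey in study.interactions:
        deg[prey if use_prey else bait] += 1
    return deg


def normalized_degrees(
    aggregated_degrees: Mapping[Hashable, int], usage: BaitUsage
) -> dict:
    """Degree divided by bait usage; never-baited proteins divide by 1.

    Dividing by max(b(u), 1) keeps the proteins least exposed to study bias in
    the ranking instead of silently dropping them.
    """
    return {
        u: d / max(usage[u], 1) for u, d in aggregated_degrees.items()
    }


def top_hubs(scores: Mapping[Hashable, float], k: int = 50) -> list:
    """The k highest-scoring proteins; ties broken lexicographically by identifier."""
    if k < 1 or k > len(scores):
        raise ValueError(f"k must be in [1, {len(scores)}]")
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return [u for u, _ in ranked[:k]]
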