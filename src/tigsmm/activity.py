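"""Active-reaction comparison across conditions and pathway classification.

Given the sets of reactions carrying non-zero flux in two context-specific
simulations (e.g. growth on glucose vs sucrose), the Venn partition
separates condition-specific reactions from the shared core; the pathway
breakdown tallies a reaction set by the subsystem labels deposited in the
model (no database lookups at run time).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, Set

from tigsmm.model_io import MetabolicModel

__all__ = [
    "VennPartition",
    "PathwayBreakdown",
    "compare_conditions",
    "classify_by_pathway",
]


@dataclass(frozen=True)
class VennPartition:
    """Disjoint split of two reaction sets: A-only, B-only and the core."""

    only_a: frozenset
    only_b: frozenset
    core: frozenset

    @property
    def union_size(self) -> int:
        return len(self.only_a) + len(self.only_b) + len(self.core)

    def sizes(self) -> Dict[str, int]:
        return {
            "only_a": len(self.only_a),
            "only_b": len(self.only_b),
            "core": len(self.core),
            "union": self.union_size,
        }


@dataclass(frozen=True)
class PathwayBreakdown:
    """Counts of a reaction set per subsystem label; unlabeled reactions
    are tallied separately."""

    counts: Dict[str, int]
    unclassified: int

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unclassified


def compare_conditions(active_a: Iterable[str], active_b: Iterable[str]) -> VennPartition:
    """Exact set algebra on two active-reaction sets."""
    a, b = set(active_a), set(active_b)
    return VennPartition(
        only_a=frozenset(a - b), only_b=frozenset(b - a), core=frozenset(a & b)
    )


def classify_by_pathway(
    model: MetabolicModel,
    reaction_set: Iterable[str],
    multi_count: bool = False,
) -> PathwayBreakdown:
    """Tally ``reaction_set`` by subsystem annotation.

    Multiple labels on one reaction (separated by ``;``) count once under
    the first label unless ``multi_count`` is set.
    """
    subsystems = {r.id: r.subsystem for r in model.reactions}
    unknown = set(reaction_set) - set(subsystems)
    if unknown:
        raise KeyError(f"reactions not in model: {sorted(unknown)[:5]}")
    counts: Counter = Counter()
    unclassified = 0
    for rxn_id in reaction_set:
        label = subsystems[rxn_id]
        if not label:
            unclassified += 1
            continue
        labels = [s.strip() for s in label.split(";") if s.strip()]
        if multi_count:
            counts.update(labels)
        else:
            counts[labels[0]] += 1
    return PathwayBreakdown(counts=dict(counts), unclassified=unclassified)
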