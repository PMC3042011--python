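"""Bin maps: group co-mapping markers and pick representative markers.

A bin opens at the first unassigned map position p0 and absorbs every
subsequent position < p0 + bin_width (1 cM by default); the first position
>= p0 + bin_width opens the next bin.  One representative marker per bin —
preferring bridge markers scored in other populations, then information
content — forms the skeleton map used for integration; the residual
members are re-attached at the representative's consensus position
afterwards.
"""

from __future__ import annotations

from typing import Mapping

from .core import Bin, LinkageMap


def build_bins(lmap: LinkageMap, bin_width: float = 1.0) -> list[Bin]:
    """Greedy left-to-right partition of a sorted map into <bin_width bins."""
    bins: list[Bin] = []
    current: Bin | None = None
    for marker, pos in lmap.entries:
        if current is None or pos - current.anchor >= bin_width:
            current = Bin(lg=lmap.lg, anchor=pos, members=[])
            bins.append(current)
        current.members.append((marker, pos))
    return bins


def select_representative(
    b: Bin,
    other_population_markers: Mapping[str, set[str]],
    scores: Mapping[str, int],
) -> str:
    """Pick the bin's representative marker.

    Priority: (1) marker present in the most other populations (at least
    one), (2) highest genotype-score count, (3) lexicographically smallest
    name.
    """
    def bridge_count(m: str) -> int:
        return sum(1 for pop, mset in other_population_markers.items() if m in mset)

    def key(member: tuple[str, float]):
        m = member[0]
        return (-bridge_count(m), -scores[m], m)

    return min(b.members, key=key)[0]


def assign_representatives(
    bins: list[Bin],
    other_population_markers: Mapping[str, set[str]],
    scores: Mapping[str, int],
) -> list[Bin]:
    for b in bins:
        b.representative = select_representative(b, other_population_markers, scores)
    return bins


def skeleton_map(lmap: LinkageMap, bins: list[Bin]) -> LinkageMap:
    """One entry per bin, placed at the representative's own position."""
    entries = []
    for b in bins:
        if b.representative is None:
            raise ValueError("bins must have representatives assigned")
        pos = dict(b.members)[b.representative]
        entries.append((b.representative, pos))
    entries.sort(key=lambda e: (e[1], e[0]))
    return LinkageMap(lmap.map_name, lmap.lg, entries)


def reattach_residuals(
    consensus: LinkageMap, bins_per_population: Mapping[str, list[Bin]]
) -> tuple[LinkageMap, list[str]]:
    """Place residual bin members at their representative's consensus position.

    A marker already present in the consensus keeps its consensus position;
    a residual reached through several populations keeps its first placement
    (populations visited in sorted order).  Residuals whose representative
    was deleted during conflict resolution are reported unplaced.
    """
    placed: dict[str, float] = dict(consensus.entries)
    unplaced: list[str] = []
    cons_pos = dict(consensus.entries)
    for pop in sorted(bins_per_population):
        for b in bins_per_population[pop]:
            rep = b.representative
            if rep is None:
                raise ValueError("bins must have representatives assigned")
            if rep not in cons_pos:
                unplaced.extend(m for m, _ in b.members if m not in placed)
                continue
            for m, _ in b.members:
                if m not in placed:
                    placed[m] = cons_pos[rep]
    unplaced = sorted(set(u for u in unplaced if u not in placed))
    entries = sorted(placed.items(), key=lambda e: (e[1], e[0]))
    return LinkageMap(consensus.map_name, consensus.lg, entries), unplaced
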