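"""Two-point linkage statistics, grouping, ordering and Kosambi distances.

In a DH population each line is a single gamete, so the two-point
recombination fraction between markers i and j is estimated as
r̂ = R / N, with N the lines scored at both markers and R the recombinant
lines.  The two-point LOD against independence is

    LOD = R log10(r̂) + (N − R) log10(1 − r̂) − N log10(0.5)

with the convention that a zero-count term contributes zero, so a pair with
no recombinants attains LOD = N log10 2.  Map distances use the Kosambi
function d = 25 ln((1 + 2r) / (1 − 2r)), inverse r = tanh(d / 50) / 2,
which allows for moderate crossover interference.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
from scipy import stats

from .core import (
    MISSING,
    GenotypeMatrix,
    IntegrationConfig,
    LinkageMap,
    PairwiseLinkage,
)

LOG10_2 = float(np.log10(2.0))


# ---------------------------------------------------------------------------
# Kosambi map function
# ---------------------------------------------------------------------------

def kosambi_to_cM(r: float, r_max: float = 0.4999) -> float:
    """Kosambi map distance (cM) for a recombination fraction."""
    if r >= 0.5:
        warnings.warn(f"r = {r} >= 0.5 clamped to {r_max}")
        r = r_max
    if r < 0:
        raise ValueError("recombination fraction must be >= 0")
    return 25.0 * float(np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r)))


def kosambi_to_r(d: float) -> float:
    """Inverse Kosambi: recombination fraction for a map distance in cM."""
    if d < 0:
        raise ValueError("map distance must be >= 0")
    return 0.5 * float(np.tanh(d / 50.0))


def dh_lod(n: int, r_count: int) -> float:
    """Two-point DH LOD at the MLE r̂ = R/N (zero-count terms drop out)."""
    if n <= 0:
        raise ValueError("need at least one informative line")
    r = r_count / n
    lod = n * LOG10_2
    if r_count > 0:
        lod += r_count * float(np.log10(r))
    if r_count < n:
        lod += (n - r_count) * float(np.log10(1.0 - r))
    return lod


# ---------------------------------------------------------------------------
# pairwise statistics
# ---------------------------------------------------------------------------

def pairwise_rf_lod(matrix: GenotypeMatrix) -> list[PairwiseLinkage]:
    """Two-point r̂ and LOD for every marker pair with >= 1 informative line.

    Vectorized over the call matrix; pairs with no jointly scored lines are
    omitted.
    """
    calls = matrix.calls
    valid = (calls != MISSING).astype(np.int32)
    a = ((calls == 0) & (calls != MISSING)).astype(np.int32)
    b = (calls == 1).astype(np.int32)
    n_mat = valid.T @ valid
    r_mat = a.T @ b + b.T @ a
    out = []
    m = matrix.markers
    for i, j in itertools.combinations(range(len(m)), 2):
        n = int(n_mat[i, j])
        if n == 0:
            continue
        r_count = int(r_mat[i, j])
        out.append(
            PairwiseLinkage(m[i], m[j], n, r_count, r_count / n, dh_lod(n, r_count))
        )
    return out


def group_markers(
    pairs: list[PairwiseLinkage],
    cfg: IntegrationConfig | None = None,
    markers: list[str] | None = None,
) -> list[set[str]]:
    """Partition markers by single-linkage transitive closure.

    Two markers join a group when their pair has LOD >= the grouping
    threshold and r̂ < 0.5.  Markers named in ``markers`` but linked to
    nothing become singleton groups.
    """
    cfg = cfg or IntegrationConfig()
    universe: dict[str, str] = {}  # union-find parent

    def find(x: str) -> str:
        while universe[x] != x:
            universe[x] = universe[universe[x]]
            x = universe[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            universe[max(rx, ry)] = min(rx, ry)

    names = set(markers or [])
    for p in pairs:
        names.update((p.marker_i, p.marker_j))
    for n in sorted(names):
        universe[n] = n
    for p in pairs:
        if p.lod >= cfg.lod_group_threshold and p.r_hat < 0.5:
            union(p.marker_i, p.marker_j)
    groups: dict[str, set[str]] = {}
    for n in universe:
        groups.setdefault(find(n), set()).add(n)
    return [groups[k] for k in sorted(groups)]


# ---------------------------------------------------------------------------
# marker ordering
# ---------------------------------------------------------------------------

def _distance_matrix(
    matrix: GenotypeMatrix, group: list[str], cfg: IntegrationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Kosambi distances and LODs restricted to a marker group."""
    sub = matrix.subset_markers(group)
    n = len(group)
    dist = np.full((n, n), kosambi_to_cM(cfg.r_max, cfg.r_max))
    lod = np.zeros((n, n))
    np.fill_diagonal(dist, 0.0)
    idx = {m: i for i, m in enumerate(group)}
    for p in pairwise_rf_lod(sub):
        i, j = idx[p.marker_i], idx[p.marker_j]
        d = kosambi_to_cM(min(p.r_hat, cfg.r_max), cfg.r_max)
        dist[i, j] = dist[j, i] = d
        lod[i, j] = lod[j, i] = p.lod
    return dist, lod


def _chain_length(order: list[int], dist: np.ndarray) -> float:
    return float(sum(dist[a, b] for a, b in zip(order, order[1:])))


def _ripple(order: list[int], dist: np.ndarray, window: int = 5) -> list[int]:
    """Windowed ripple: segment reversals (2-opt, length <= window) plus
    single-marker relocations, repeated until neither improves the length."""
    n = len(order)
    improved = True
    while improved:
        improved = False
        best_len = _chain_length(order, dist)
        for i in range(n - 1):
            for j in range(i + 1, min(i + window, n)):
                cand = order[:i] + order[i : j + 1][::-1] + order[j + 1 :]
                cand_len = _chain_length(cand, dist)
                if cand_len < best_len - 1e-12:
                    order, best_len = cand, cand_len
                    improved = True
        for seg in range(1, window + 1):
            for i in range(n - seg + 1):
                block = order[i : i + seg]
                base = order[:i] + order[i + seg :]
                for slot in range(len(base) + 1):
                    if slot == i:
                        continue
                    for piece in (block, block[::-1]) if seg > 1 else (block,):
                        cand = base[:slot] + piece + base[slot:]
                        cand_len = _chain_length(cand, dist)
                        if cand_len < best_len - 1e-12:
                            order, best_len = cand, cand_len
                            improved = True
    return order


def order_markers(
    matrix: GenotypeMatrix,
    group: set[str] | list[str],
    cfg: IntegrationConfig | None = None,
    initial_order: list[str] | None = None,
) -> LinkageMap:
    """Order a linkage group's markers and assign Kosambi positions.

    The ordering objective is minimum total adjacent map length (a standard
    surrogate for the multipoint ML order on DH data).  The chain is seeded
    with the highest-LOD pair, extended greedily by the nearest unplaced
    marker at either end, then polished with windowed 2-opt passes (window
    5) until no reversal shortens it.  An ``initial_order`` warm-starts the
    ripple in place of the greedy construction (used when re-ordering after
    masking).  Co-segregating markers share a position and are listed
    lexicographically; the whole map is canonicalized so the forward
    reading of names is lexicographically minimal (use :func:`orient_map`
    to match a reference orientation).
    """
    cfg = cfg or IntegrationConfig()
    members = sorted(group)
    if len(members) == 1:
        return LinkageMap(matrix.population, "LG", [(members[0], 0.0)])
    dist, lod = _distance_matrix(matrix, members, cfg)
    n = len(members)

    if initial_order is not None:
        index = {m: k for k, m in enumerate(members)}
        order = [index[m] for m in initial_order if m in index]
        if len(order) != n:
            raise ValueError("initial_order must cover the group")
    else:
        # seed: highest-LOD pair (ties by index, deterministic)
        best_pair, best_lod = (0, 1), -np.inf
        for i in range(n):
            for j in range(i + 1, n):
                if lod[i, j] > best_lod:
                    best_lod, best_pair = lod[i, j], (i, j)
        order = list(best_pair)
        unplaced = [k for k in range(n) if k not in order]
        while unplaced:
            # nearest unplaced marker to the chain, cheapest insertion slot
            cand = min(
                unplaced, key=lambda k: (min(dist[k, q] for q in order), k)
            )
            slots = []
            for s in range(len(order) + 1):
                trial = order[:s] + [cand] + order[s:]
                slots.append((_chain_length(trial, dist), s, trial))
            order = min(slots)[2]
            unplaced.remove(cand)
    order = _ripple(order, dist)

    positions = np.concatenate(
        ([0.0], np.cumsum([dist[a, b] for a, b in zip(order, order[1:])]))
    )
    entries = [(members[k], float(p)) for k, p in zip(order, positions)]

    # lexicographic order within co-located runs
    entries = _sort_colocated(entries)
    names = [m for m, _ in entries]
    rev = LinkageMap(matrix.population, "LG", entries).reversed()
    rev_entries = _sort_colocated(rev.entries)
    if [m for m, _ in rev_entries] < names:
        entries = rev_entries
    return LinkageMap(matrix.population, "LG", entries)


def _sort_colocated(entries: list[tuple[str, float]]) -> list[tuple[str, float]]:
    out: list[tuple[str, float]] = []
    i = 0
    while i < len(entries):
        j = i
        while j < len(entries) and abs(entries[j][1] - entries[i][1]) < 1e-9:
            j += 1
        out.extend(sorted(entries[i:j]))
        i = j
    return out


def orient_map(lmap: LinkageMap, reference: LinkageMap) -> LinkageMap:
    """Reverse a map when shared-marker order runs opposite to a reference."""
    shared = [m for m in lmap.markers if m in reference.as_dict()]
    if len(shared) < 2:
        warnings.warn(
            f"LG {lmap.lg}: fewer than 2 markers shared with reference; not oriented"
        )
        return lmap
    pos_self = [lmap.position_of(m) for m in shared]
    pos_ref = [reference.position_of(m) for m in shared]
    rho = stats.spearmanr(pos_self, pos_ref).statistic
    if np.isnan(rho):
        return lmap
    if rho < 0:
        return lmap.reversed()
    return lmap
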