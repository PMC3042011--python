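"""Integrate skeleton maps across populations; compare marker orders.

Two contrasting engines are provided.

* **Pooled-recombination regression** combines per-population two-point
  estimates into meiosis-weighted mean recombination fractions and summed
  LODs, then builds each linkage group by weighted least squares: markers
  are inserted in decreasing total-LOD order at the slot minimizing

      S = sum_{pairs} w_ij (d_ij - |x_i - x_j|)^2,

  with d_ij the Kosambi distance of the pooled fraction and w_ij the
  squared summed LOD.  A marker whose insertion raises the normalized S by
  more than the "jump" threshold is deferred; deferred markers are retried
  once (Round 2) and finally forced (Round 3, the headline map).

* **DAG merging** converts each component map to a directed acyclic graph
  of marker adjacencies (edge weight = cM gap), merges the graphs on shared
  vertices, deletes a minimum-weight set of marker *occurrences* to break
  any order conflicts (cycles), and linearises the consensus DAG with
  longest-path coordinates.  Longest-path coordinates deliberately
  incorporate each component's length over-estimates, which is the
  documented behaviour of this family of algorithms; a least-squares
  coordinate assignment would hide it.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .core import (
    IntegrationConfig,
    LinkageMap,
    PairwiseLinkage,
    PooledPair,
    RegressionFit,
)
from .linkage import kosambi_to_cM


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def pool_pairs(per_population: list[list[PairwiseLinkage]]) -> list[PooledPair]:
    """Meiosis-weighted pooled recombination fractions and summed LODs."""
    acc: dict[tuple[str, str], list[PairwiseLinkage]] = {}
    for pairs in per_population:
        for p in pairs:
            key = tuple(sorted((p.marker_i, p.marker_j)))
            acc.setdefault(key, []).append(p)
    out = []
    for (mi, mj), plist in sorted(acc.items()):
        n_total = sum(p.n_informative for p in plist)
        r_mean = sum(p.n_informative * p.r_hat for p in plist) / n_total
        lod_sum = sum(p.lod for p in plist)
        out.append(PooledPair(mi, mj, r_mean, lod_sum, n_total))
    return out


# ---------------------------------------------------------------------------
# regression integration
# ---------------------------------------------------------------------------

def _pair_tables(
    pooled: list[PooledPair], cfg: IntegrationConfig
) -> dict[tuple[str, str], tuple[float, float]]:
    """(distance cM, weight) per unordered pair."""
    table = {}
    for p in pooled:
        d = kosambi_to_cM(min(p.r_mean, cfg.r_max), cfg.r_max)
        table[(p.marker_i, p.marker_j)] = (d, p.lod_sum**2)
    return table


def _fit_positions(
    order: list[str], table: dict[tuple[str, str], tuple[float, float]]
) -> tuple[dict[str, float], float]:
    """Weighted least-squares coordinates for a fixed marker order.

    Minimizes sum w (d_ij - (x_j - x_i))^2 over pairs with both markers in
    the order (j later than i).  The first marker anchors the origin.
    """
    n = len(order)
    if n == 0:
        return {}, 0.0
    if n == 1:
        return {order[0]: 0.0}, 0.0
    idx = {m: k for k, m in enumerate(order)}
    rows, rhs, weights = [], [], []
    for (mi, mj), (d, w) in table.items():
        if mi in idx and mj in idx:
            i, j = idx[mi], idx[mj]
            if i > j:
                i, j = j, i
            row = np.zeros(n)
            row[j] = 1.0
            row[i] = -1.0
            rows.append(row)
            rhs.append(d)
            weights.append(w)
    if not rows:
        return {m: 0.0 for m in order}, 0.0
    a_mat = np.array(rows)
    b_vec = np.array(rhs)
    w_vec = np.sqrt(np.array(weights))
    # anchor x[0] = 0 by eliminating the first column
    sol, *_ = np.linalg.lstsq(a_mat[:, 1:] * w_vec[:, None], b_vec * w_vec, rcond=None)
    x = np.concatenate(([0.0], sol))
    resid = a_mat @ x - b_vec
    sse = float(np.sum(np.array(weights) * resid**2))
    return {m: float(x[idx[m]]) for m in order}, sse


def _best_insertion(
    order: list[str], marker: str, table
) -> tuple[list[str], dict[str, float], float]:
    best = None
    for slot in range(len(order) + 1):
        cand = order[:slot] + [marker] + order[slot:]
        pos, sse = _fit_positions(cand, table)
        if best is None or sse < best[2] - 1e-12:
            best = (cand, pos, sse)
    return best


def _reshuffle(order: list[str], recent: list[str], table) -> tuple[list[str], float]:
    """Try relocating each recently placed marker; keep improvements."""
    _, sse = _fit_positions(order, table)
    for m in recent:
        if m not in order:
            continue
        base = [x for x in order if x != m]
        cand_order, _, cand_sse = _best_insertion(base, m, table)
        if cand_sse < sse - 1e-9:
            order, sse = cand_order, cand_sse
    return order, sse


def regression_integrate(
    pooled: list[PooledPair], cfg: IntegrationConfig | None = None
) -> list[RegressionFit]:
    """Three-round regression integration of one LG's pooled pairs.

    Round 1 inserts markers in decreasing total-LOD order, deferring any
    marker whose jump statistic — the increase in S per placed marker,
    normalized by the mean pair weight — exceeds ``cfg.jump_threshold``.
    Round 2 retries the deferred markers once; Round 3 forces the rest.
    """
    cfg = cfg or IntegrationConfig()
    table = _pair_tables(pooled, cfg)
    total_lod: dict[str, float] = {}
    for p in pooled:
        total_lod[p.marker_i] = total_lod.get(p.marker_i, 0.0) + p.lod_sum
        total_lod[p.marker_j] = total_lod.get(p.marker_j, 0.0) + p.lod_sum
    queue = sorted(total_lod, key=lambda m: (-total_lod[m], m))

    order: list[str] = []
    sse = 0.0
    recent: list[str] = []

    def mean_weight(markers: list[str]) -> float:
        ws = [w for (mi, mj), (_, w) in table.items() if mi in markers and mj in markers]
        return float(np.mean(ws)) if ws else 1.0

    def try_place(m: str, enforce_jump: bool) -> bool:
        nonlocal order, sse, recent
        if not order:
            order, sse = [m], 0.0
            recent = [m]
            return True
        cand_order, _, cand_sse = _best_insertion(order, m, table)
        if enforce_jump:
            in_set = set(cand_order)
            jump = (cand_sse - sse) / (max(1, len(order)) * mean_weight(in_set))
            if jump > cfg.jump_threshold:
                return False
        order, sse = cand_order, cand_sse
        recent = (recent + [m])[-3:]
        order, sse = _reshuffle(order, recent, table)
        return True

    fits: list[RegressionFit] = []
    deferred: list[str] = []
    for m in queue:
        if not try_place(m, enforce_jump=True):
            deferred.append(m)
    pos, sse = _fit_positions(order, table)
    fits.append(RegressionFit(_rebase(pos), sse, list(deferred), 1))

    still: list[str] = []
    for m in deferred:
        if not try_place(m, enforce_jump=True):
            still.append(m)
    pos, sse = _fit_positions(order, table)
    fits.append(RegressionFit(_rebase(pos), sse, list(still), 2))

    for m in still:
        try_place(m, enforce_jump=False)
    pos, sse = _fit_positions(order, table)
    fits.append(RegressionFit(_rebase(pos), sse, [], 3))
    return fits


def _rebase(positions: dict[str, float]) -> dict[str, float]:
    if not positions:
        return {}
    p0 = min(positions.values())
    return {m: p - p0 for m, p in positions.items()}


def fit_to_map(fit: RegressionFit, lg: str = "LG", map_name: str = "consensus") -> LinkageMap:
    entries = sorted(fit.positions.items(), key=lambda e: (e[1], e[0]))
    return LinkageMap(map_name, lg, entries)


# ---------------------------------------------------------------------------
# DAG merging
# ---------------------------------------------------------------------------

@dataclass
class ConsensusGraph:
    """Merged marker-adjacency multigraph with per-map provenance.

    ``components`` holds the source maps keyed by map name; ``deleted``
    holds (marker, map) occurrences removed during conflict resolution.
    The active graph is rebuilt from these, bypassing deleted occurrences
    with summed-weight edges so component distances are conserved.
    """

    components: dict[str, LinkageMap] = field(default_factory=dict)
    deleted: set[tuple[str, str]] = field(default_factory=set)

    @property
    def graph(self) -> nx.MultiDiGraph:
        return build_graph(self.components, self.deleted)

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.graph)


def build_graph(
    components: dict[str, LinkageMap], deleted: set[tuple[str, str]] = frozenset()
) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    for name in sorted(components):
        lmap = components[name]
        entries = sorted(lmap.entries, key=lambda e: (e[1], e[0]))
        active = [(m, p) for m, p in entries if (m, name) not in deleted]
        for m, _ in active:
            g.add_node(m)
        for (u, pu), (v, pv) in zip(active, active[1:]):
            g.add_edge(u, v, key=name, weight=pv - pu, provenance=name)
    return g


def map_to_dag(lmap: LinkageMap) -> ConsensusGraph:
    """A single component map as a consensus-graph fragment.

    Consecutive markers are joined u -> v with weight = cM gap; co-located
    markers are joined by a 0-weight edge in lexicographic direction.
    """
    return ConsensusGraph(components={lmap.map_name: lmap})


def merge_dags(fragments: list[ConsensusGraph]) -> ConsensusGraph:
    """Union of fragments on shared marker vertices, provenance retained."""
    components: dict[str, LinkageMap] = {}
    deleted: set[tuple[str, str]] = set()
    for f in fragments:
        for name, lmap in f.components.items():
            if name in components:
                raise ValueError(f"duplicate component map name {name!r}")
            components[name] = lmap
        deleted |= f.deleted
    return ConsensusGraph(components, deleted)


def occurrence_weight(
    marker: str, map_name: str, components: dict[str, LinkageMap]
) -> float:
    """Deletion weight of one marker occurrence.

    1 + (number of other maps where the marker's local order is consistent
    with this map) / 10 — occurrences supported by several concordant maps
    are expensive to delete, poorly supported ones cheap.  Consistency with
    map j means a strict majority of the markers shared between the two
    maps lie on the same side of the marker in both.
    """
    k = components[map_name]
    pos_k = k.as_dict()
    consistent = 0
    for other, lmap in components.items():
        if other == map_name:
            continue
        pos_j = lmap.as_dict()
        if marker not in pos_j:
            continue
        shared = [m for m in pos_j if m in pos_k and m != marker]
        if not shared:
            continue
        agree = sum(
            1
            for s in shared
            if (pos_j[marker] - pos_j[s]) * (pos_k[marker] - pos_k[s]) > 0
        )
        if agree * 2 > len(shared):
            consistent += 1
    return 1.0 + consistent / 10.0


def _scc_occurrences(
    scc: set[str], components: dict[str, LinkageMap], deleted: set[tuple[str, str]]
) -> list[tuple[str, str]]:
    occ = []
    for name in sorted(components):
        markers = set(components[name].markers)
        for m in sorted(scc):
            if m in markers and (m, name) not in deleted:
                occ.append((m, name))
    return occ


def _scc_resolved(
    scc: set[str], components, deleted: set[tuple[str, str]]
) -> bool:
    g = build_graph(components, deleted)
    sub = g.subgraph(n for n in scc if n in g)
    return nx.is_directed_acyclic_graph(nx.DiGraph(sub))


def _resolve_scc_exact(
    scc: set[str], components, deleted: set[tuple[str, str]]
) -> set[tuple[str, str]]:
    occ = _scc_occurrences(scc, components, deleted)
    weights = [occurrence_weight(m, k, components) for m, k in occ]
    best: tuple[float, tuple] | None = None
    n = len(occ)
    for mask in range(1, 1 << n):
        subset = tuple(occ[i] for i in range(n) if mask >> i & 1)
        w = sum(weights[i] for i in range(n) if mask >> i & 1)
        if best is not None and (w, subset) >= best:
            continue
        if _scc_resolved(scc, components, deleted | set(subset)):
            best = (w, subset)
    if best is None:  # cannot happen: deleting all occurrences empties the SCC
        return set(occ)
    return set(best[1])


def _resolve_scc_greedy(
    scc: set[str], components, deleted: set[tuple[str, str]]
) -> set[tuple[str, str]]:
    removed: set[tuple[str, str]] = set()
    while not _scc_resolved(scc, components, deleted | removed):
        g = build_graph(components, deleted | removed)
        sub = g.subgraph(n for n in scc if n in g)
        cycles = list(itertools.islice(nx.simple_cycles(nx.DiGraph(sub)), 200))
        counts: dict[tuple[str, str], int] = {}
        for cyc in cycles:
            for u, v in zip(cyc, cyc[1:] + cyc[:1]):
                for key in g[u][v]:
                    counts[(u, key)] = counts.get((u, key), 0) + 1
                    counts[(v, key)] = counts.get((v, key), 0) + 1
        if not counts:
            break
        pick = max(
            counts,
            key=lambda o: (counts[o], -occurrence_weight(o[0], o[1], components), o),
        )
        removed.add(pick)
    # prune deletions made redundant by later ones (heaviest first)
    for occ in sorted(
        removed, key=lambda o: (-occurrence_weight(o[0], o[1], components), o)
    ):
        trial = removed - {occ}
        if _scc_resolved(scc, components, deleted | trial):
            removed = trial
    # exchange improvement: replace any two deletions with a single one
    all_occ = _scc_occurrences(scc, components, deleted)
    improved = True
    while improved and len(removed) >= 2:
        improved = False
        for o1, o2 in itertools.combinations(sorted(removed), 2):
            for cand in all_occ:
                if cand in removed:
                    continue
                trial = (removed - {o1, o2}) | {cand}
                if _scc_resolved(scc, components, deleted | trial):
                    removed = trial
                    improved = True
                    break
            if improved:
                break
    return removed


def resolve_conflicts(
    cg: ConsensusGraph, exact_limit: int = 12, force_greedy: bool = False
) -> tuple[ConsensusGraph, list[tuple[str, str]]]:
    """Delete a minimum-weight set of marker occurrences to break cycles.

    Each strongly connected component with more than one node is resolved
    independently: by exhaustive subset search when it involves at most
    ``exact_limit`` occurrences, by a cycle-counting greedy heuristic
    otherwise.  Bypass edges keep per-map distances additive, and the loop
    re-checks global acyclicity after every resolution.
    """
    deleted = set(cg.deleted)
    new_deletions: list[tuple[str, str]] = []
    while True:
        g = build_graph(cg.components, deleted)
        sccs = [s for s in nx.strongly_connected_components(g) if len(s) > 1]
        if not sccs:
            break
        scc = min(sccs, key=lambda s: min(s))
        occ = _scc_occurrences(scc, cg.components, deleted)
        if not force_greedy and len(occ) <= exact_limit:
            removal = _resolve_scc_exact(scc, cg.components, deleted)
        else:
            removal = _resolve_scc_greedy(scc, cg.components, deleted)
        if not removal:  # safety: never loop forever
            removal = {occ[0]}
        deleted |= removal
        new_deletions.extend(sorted(removal))

    # global minimality pass over everything deleted in this call: drop
    # redundant occurrences, then try replacing any two with a single one
    def acyclic_with(dels: set[tuple[str, str]]) -> bool:
        return nx.is_directed_acyclic_graph(build_graph(cg.components, cg.deleted | dels))

    current = set(new_deletions)
    for occ in sorted(
        current, key=lambda o: (-occurrence_weight(o[0], o[1], cg.components), o)
    ):
        if acyclic_with(current - {occ}):
            current -= {occ}
    all_occ = [
        (m, name)
        for name in sorted(cg.components)
        for m in cg.components[name].markers
        if (m, name) not in cg.deleted
    ]
    improved = True
    while improved and len(current) >= 2:
        improved = False
        for o1, o2 in itertools.combinations(sorted(current), 2):
            for cand in all_occ:
                if cand in current:
                    continue
                trial = (current - {o1, o2}) | {cand}
                if acyclic_with(trial):
                    current, improved = trial, True
                    break
            if improved:
                break
    deleted = cg.deleted | current
    return ConsensusGraph(cg.components, deleted), sorted(current)


def linearize(cg: ConsensusGraph, map_name: str = "consensus", lg: str = "LG") -> LinkageMap:
    """Topological order with longest-path coordinates.

    Ties between simultaneously available markers break by mean normalized
    component-map rank, then name.  position(v) = max over predecessors of
    position(u) + weight(u -> v); origin 0.  Longest-path coordinates make
    the consensus at least as long as every component path.
    """
    g = cg.graph
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("consensus graph contains cycles; resolve conflicts first")

    rank: dict[str, float] = {}
    for lmap in cg.components.values():
        n = len(lmap.entries)
        for i, (m, _) in enumerate(lmap.entries):
            r = 0.5 if n == 1 else i / (n - 1)
            rank.setdefault(m, 0.0)
            rank[m] += r
    counts: dict[str, int] = {}
    for lmap in cg.components.values():
        for m, _ in lmap.entries:
            counts[m] = counts.get(m, 0) + 1
    mean_rank = {m: rank[m] / counts[m] for m in rank if m in g}

    # distinct-predecessor counts (parallel provenance edges count once)
    indeg = {n: len(set(g.predecessors(n))) for n in g.nodes}
    ready = [(mean_rank.get(n, 0.5), n) for n, d in indeg.items() if d == 0]
    heapq.heapify(ready)
    pos: dict[str, float] = {}
    emitted: list[str] = []
    while ready:
        _, u = heapq.heappop(ready)
        preds = [
            pos[p] + max(d["weight"] for d in g[p][u].values())
            for p in g.predecessors(u)
        ]
        pos[u] = max(preds) if preds else 0.0
        emitted.append(u)
        for v in g.successors(u):
            indeg[v] -= 1
            if indeg[v] == 0:
                heapq.heappush(ready, (mean_rank.get(v, 0.5), v))
    if len(emitted) != g.number_of_nodes():
        raise ValueError("graph not fully linearised (cycle?)")
    emit_idx = {m: i for i, m in enumerate(emitted)}
    entries = sorted(pos.items(), key=lambda e: (e[1], emit_idx[e[0]]))
    return LinkageMap(map_name, lg, entries)


# ---------------------------------------------------------------------------
# map comparison
# ---------------------------------------------------------------------------

def spearman_order(
    map_a: LinkageMap, map_b: LinkageMap
) -> tuple[float, float, int]:
    """Spearman rank correlation of shared-marker orders.

    Average ranks for ties.  The p-value is exact (full permutation
    enumeration, two-sided) for up to 8 shared markers and uses the
    t-approximation above that.  Fewer than 2 shared markers: (nan, nan, n).
    """
    pos_b = map_b.as_dict()
    shared = [m for m in map_a.markers if m in pos_b]
    n = len(shared)
    if n < 2:
        return float("nan"), float("nan"), n
    ra = stats.rankdata([map_a.position_of(m) for m in shared])
    rb = stats.rankdata([pos_b[m] for m in shared])
    ca, cb = ra - ra.mean(), rb - rb.mean()
    denom = float(np.sqrt((ca**2).sum() * (cb**2).sum()))
    if denom == 0.0:
        return float("nan"), float("nan"), n
    rho = float(ca @ cb / denom)
    if n <= 8:
        target = abs(rho) - 1e-12
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            r_perm = float(ca @ cb[list(perm)]) / denom
            if abs(r_perm) >= target:
                hits += 1
        p = hits / total
    else:
        p = float(stats.spearmanr(ra, rb).pvalue)
    return rho, p, n


def dotplot_table(
    map_a: LinkageMap, map_b: LinkageMap
) -> list[tuple[str, float, float]]:
    """Shared markers with coordinates in both maps (dot-plot input)."""
    pos_b = map_b.as_dict()
    return [
        (m, p, pos_b[m]) for m, p in map_a.entries if m in pos_b
    ]
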