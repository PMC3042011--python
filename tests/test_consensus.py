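import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from mapfuse.consensus import (
    ConsensusGraph,
    build_graph,
    dotplot_table,
    fit_to_map,
    linearize,
    map_to_dag,
    merge_dags,
    occurrence_weight,
    pool_pairs,
    regression_integrate,
    resolve_conflicts,
    spearman_order,
)
from mapfuse.core import IntegrationConfig, LinkageMap, PairwiseLinkage, PooledPair
from mapfuse.linkage import kosambi_to_cM, kosambi_to_r

from conftest import make_map


def plink(i, j, n, r):
    return PairwiseLinkage(i, j, n, int(round(r * n)), r, 10.0)


class TestPoolPairs:
    def test_meiosis_weighted_mean(self):
        pooled = pool_pairs([[plink("a", "b", 100, 0.10)], [plink("a", "b", 50, 0.16)]])
        (p,) = pooled
        assert p.r_mean == pytest.approx(0.12)
        assert p.n_total == 150
        assert p.lod_sum == pytest.approx(20.0)

    def test_single_population_identity(self):
        (p,) = pool_pairs([[plink("a", "b", 80, 0.2)]])
        assert p.r_mean == pytest.approx(0.2) and p.lod_sum == 10.0

    def test_pair_missing_from_one_population(self):
        pooled = pool_pairs(
            [[plink("a", "b", 100, 0.1)], [plink("a", "b", 100, 0.1)], [plink("a", "c", 100, 0.2)]]
        )
        by_key = {(p.marker_i, p.marker_j): p for p in pooled}
        assert by_key[("a", "b")].n_total == 200
        assert by_key[("a", "c")].n_total == 100


def pooled_from_distances(positions, lod=20.0):
    """Consistent pooled pairs from true positions (exact metric)."""
    out = []
    names = sorted(positions)
    for a, b in itertools.combinations(names, 2):
        d = abs(positions[a] - positions[b])
        out.append(PooledPair(a, b, kosambi_to_r(d), lod, 100))
    return out


def oracle_regression(pooled, cfg):
    """Brute force: all orders, exact weighted least squares per order."""
    names = sorted({m for p in pooled for m in (p.marker_i, p.marker_j)})
    table = {}
    for p in pooled:
        table[(p.marker_i, p.marker_j)] = (
            kosambi_to_cM(min(p.r_mean, cfg.r_max)),
            p.lod_sum**2,
        )
    best = None
    for perm in itertools.permutations(names):
        if perm[0] > perm[-1]:
            continue
        idx = {m: k for k, m in enumerate(perm)}
        rows, rhs, w = [], [], []
        for (mi, mj), (d, wt) in table.items():
            i, j = sorted((idx[mi], idx[mj]))
            row = np.zeros(len(perm))
            row[j], row[i] = 1.0, -1.0
            rows.append(row)
            rhs.append(d)
            w.append(wt)
        a_mat, b_vec, w_vec = np.array(rows), np.array(rhs), np.sqrt(np.array(w))
        sol, *_ = np.linalg.lstsq(
            a_mat[:, 1:] * w_vec[:, None], b_vec * w_vec, rcond=None
        )
        x = np.concatenate(([0.0], sol))
        sse = float(np.sum(np.array(w) * (a_mat @ x - b_vec) ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, {m: float(x[idx[m]]) for m in perm})
    return best


def aligned(got: dict, want: dict, tol=1e-6) -> bool:
    """Equal positions after rebasing, allowing a full reversal."""
    if set(got) != set(want):
        return False
    g0 = min(got.values())
    w0, w1 = min(want.values()), max(want.values())
    fwd = all(abs((got[m] - g0) - (want[m] - w0)) < tol for m in want)
    rev = all(abs((got[m] - g0) - (w1 - want[m])) < tol for m in want)
    return fwd or rev


class TestRegressionIntegrate:
    def test_exact_metric_three_markers(self):
        pooled = pooled_from_distances({"a": 0.0, "b": 10.0, "c": 25.0})
        fits = regression_integrate(pooled)
        final = fits[-1]
        assert final.sse == pytest.approx(0.0, abs=1e-9)
        assert aligned(final.positions, {"a": 0.0, "b": 10.0, "c": 25.0})

    @pytest.mark.parametrize("n_markers", [4, 5, 6])
    def test_matches_brute_force_least_squares(self, n_markers, rng):
        cfg = IntegrationConfig()
        for trial in range(5):
            true = np.sort(rng.uniform(0, 30, n_markers))
            positions = {f"m{k}": float(true[k]) for k in range(n_markers)}
            pooled = []
            for p in pooled_from_distances(positions):
                # small multiplicative noise on the pooled fractions
                r = min(max(p.r_mean * float(rng.uniform(0.95, 1.05)), 0.0), 0.49)
                pooled.append(PooledPair(p.marker_i, p.marker_j, r, p.lod_sum, p.n_total))
            fits = regression_integrate(pooled, cfg)
            oracle_sse, oracle_pos = oracle_regression(pooled, cfg)
            assert fits[-1].sse == pytest.approx(oracle_sse, abs=1e-6)
            assert aligned(fits[-1].positions, oracle_pos)

    def test_inconsistent_marker_deferred_until_round3(self):
        pooled = pooled_from_distances({"a": 0.0, "b": 10.0, "c": 20.0, "d": 30.0})
        # marker x claims to be 1 cM from both ends: mutually impossible
        for anchor in ("a", "d"):
            pooled.append(PooledPair(anchor, "x", kosambi_to_r(1.0), 15.0, 100))
        fits = regression_integrate(pooled)
        assert fits[0].excluded == ["x"]
        assert fits[1].excluded == ["x"]
        assert fits[2].excluded == [] and "x" in fits[2].positions

    def test_single_population_degenerates_to_component_order(self):
        positions = {"a": 0.0, "b": 4.0, "c": 9.0, "d": 17.0, "e": 26.0}
        pooled = pooled_from_distances(positions)
        fits = regression_integrate(pooled)
        lmap = fit_to_map(fits[-1])
        assert lmap.markers in (list("abcde"), list("edcba"))
        gaps = np.diff(lmap.positions)
        assert np.allclose(sorted(gaps), sorted(np.diff(sorted(positions.values()))), atol=1e-6)


class TestDagConstruction:
    def test_consecutive_edges_and_weights(self):
        frag = map_to_dag(make_map([0.0, 2.0, 5.0], names=["A", "B", "C"], map_name="m1"))
        g = frag.graph
        assert g["A"]["B"]["m1"]["weight"] == pytest.approx(2.0)
        assert g["B"]["C"]["m1"]["weight"] == pytest.approx(3.0)
        assert g.number_of_edges() == 2

    def test_colocated_zero_weight_lexicographic(self):
        frag = map_to_dag(make_map([0.0, 0.0], names=["Z", "A"], map_name="m1"))
        g = frag.graph
        assert g.has_edge("A", "Z")
        assert g["A"]["Z"]["m1"]["weight"] == 0.0

    def test_empty_map_empty_fragment(self):
        frag = map_to_dag(LinkageMap("m1", "LG1", []))
        assert frag.graph.number_of_nodes() == 0

    def test_merge_identical_orders_acyclic(self):
        m1 = make_map([0.0, 1.0, 2.0], names=["A", "B", "C"], map_name="m1")
        m2 = make_map([0.0, 2.0, 3.0], names=["A", "B", "C"], map_name="m2")
        merged = merge_dags([map_to_dag(m1), map_to_dag(m2)])
        assert merged.is_acyclic()

    def test_merge_conflicting_orders_creates_cycle(self):
        m1 = make_map([0.0, 1.0, 2.0], names=["A", "B", "C"], map_name="m1")
        m2 = make_map([0.0, 1.0, 2.0], names=["A", "C", "B"], map_name="m2")
        merged = merge_dags([map_to_dag(m1), map_to_dag(m2)])
        assert not merged.is_acyclic()

    def test_disjoint_markers_disconnected_acyclic(self):
        m1 = make_map([0.0, 1.0], names=["A", "B"], map_name="m1")
        m2 = make_map([0.0, 1.0], names=["X", "Y"], map_name="m2")
        merged = merge_dags([map_to_dag(m1), map_to_dag(m2)])
        assert merged.is_acyclic()
        assert nx.number_weakly_connected_components(merged.graph) == 2


def oracle_min_deletion(components):
    """Exhaustive minimum-weight occurrence deletion (independent oracle)."""
    occurrences = [
        (m, name) for name in sorted(components) for m in components[name].markers
    ]
    best = None
    for size in range(len(occurrences) + 1):
        for subset in itertools.combinations(occurrences, size):
            g = nx.MultiDiGraph()
            for name in sorted(components):
                ents = [
                    e for e in sorted(components[name].entries, key=lambda e: (e[1], e[0]))
                    if (e[0], name) not in set(subset)
                ]
                for (u, _), (v, _) in zip(ents, ents[1:]):
                    g.add_edge(u, v)
            if nx.is_directed_acyclic_graph(g):
                w = sum(occurrence_weight(m, k, components) for m, k in subset)
                if best is None or w < best - 1e-12:
                    best = w
        if best is not None and size >= 1 and best <= size:
            # any larger subset weighs at least size+1 > best
            break
    return best


class TestResolveConflicts:
    def test_simple_conflict_one_deletion(self):
        m1 = make_map([0.0, 1.0, 2.0], names=["A", "B", "C"], map_name="m1")
        m2 = make_map([0.0, 1.0, 2.0], names=["A", "C", "B"], map_name="m2")
        merged = merge_dags([map_to_dag(m1), map_to_dag(m2)])
        resolved, deletions = resolve_conflicts(merged)
        assert len(deletions) == 1
        assert deletions[0][0] in ("B", "C")
        assert resolved.is_acyclic()

    def test_minority_map_loses(self):
        maps = [
            make_map([0.0, 1.0, 2.0], names=["A", "B", "C"], map_name=f"m{k}")
            for k in (1, 2)
        ] + [make_map([0.0, 1.0, 2.0], names=["A", "C", "B"], map_name="m3")]
        merged = merge_dags([map_to_dag(m) for m in maps])
        _, deletions = resolve_conflicts(merged)
        assert len(deletions) == 1
        assert deletions[0][1] == "m3"

    def test_conflict_free_untouched(self):
        m1 = make_map([0.0, 1.0], names=["A", "B"], map_name="m1")
        m2 = make_map([0.0, 3.0], names=["A", "B"], map_name="m2")
        merged = merge_dags([map_to_dag(m1), map_to_dag(m2)])
        resolved, deletions = resolve_conflicts(merged)
        assert deletions == []
        assert resolved.graph.number_of_edges() == 2

    def test_exact_matches_exhaustive_oracle(self, rng):
        for trial in range(12):
            n = int(rng.integers(3, 5))
            names = [f"M{k}" for k in range(n)]
            components = {}
            for mi in range(3):
                perm = list(rng.permutation(n))
                sub = sorted(rng.choice(n, size=int(rng.integers(2, n + 1)), replace=False).tolist())
                chosen = [names[perm[k]] for k in sub]
                components[f"map{mi}"] = LinkageMap(
                    f"map{mi}", "LG1", [(m, float(j)) for j, m in enumerate(chosen)]
                )
            merged = ConsensusGraph(components=components)
            resolved, deletions = resolve_conflicts(merged)
            assert resolved.is_acyclic()
            got = sum(occurrence_weight(m, k, components) for m, k in deletions)
            want = oracle_min_deletion(components)
            assert got == pytest.approx(want, abs=1e-9)

    def test_greedy_matches_exact_deletion_count(self, rng):
        for trial in range(10):
            n = 4
            names = [f"M{k}" for k in range(n)]
            components = {}
            for mi in range(2):
                perm = list(rng.permutation(n))
                components[f"map{mi}"] = LinkageMap(
                    f"map{mi}", "LG1", [(names[p], float(j)) for j, p in enumerate(perm)]
                )
            merged = ConsensusGraph(components=components)
            _, exact = resolve_conflicts(merged)
            _, greedy = resolve_conflicts(merged, force_greedy=True)
            assert len(greedy) == len(exact)


class TestLinearize:
    def test_chain_positions(self):
        frag = map_to_dag(make_map([0.0, 2.0, 5.0], names=["A", "B", "C"], map_name="m1"))
        lmap = linearize(frag)
        assert lmap.entries == [("A", 0.0), ("B", 2.0), ("C", 5.0)]

    def test_diamond_longest_path(self):
        m1 = make_map([0.0, 2.0, 4.0], names=["A", "B", "D"], map_name="m1")
        m2 = make_map([0.0, 3.0, 4.0], names=["A", "C", "D"], map_name="m2")
        merged = merge_dags([map_to_dag(m1), map_to_dag(m2)])
        lmap = linearize(merged)
        assert lmap.position_of("D") == pytest.approx(4.0)  # max(2+2, 3+1)
        assert lmap.position_of("C") == pytest.approx(3.0)

    def test_cycle_raises(self):
        m1 = make_map([0.0, 1.0], names=["A", "B"], map_name="m1")
        m2 = make_map([0.0, 1.0], names=["B", "A"], map_name="m2")
        merged = merge_dags([map_to_dag(m1), map_to_dag(m2)])
        with pytest.raises(ValueError, match="cycle"):
            linearize(merged)

    def test_consensus_at_least_component_length(self, rng):
        for trial in range(30):
            n = int(rng.integers(4, 10))
            true = np.sort(rng.uniform(0, 50, n))
            names = [f"M{k:02d}" for k in range(n)]
            components = {}
            for mi in range(3):
                keep = sorted(
                    rng.choice(n, size=int(rng.integers(2, n + 1)), replace=False).tolist()
                )
                components[f"map{mi}"] = LinkageMap(
                    f"map{mi}", "LG1", [(names[k], float(true[k])) for k in keep]
                )
            merged = ConsensusGraph(components=components)
            lmap = linearize(merged)
            for comp in components.values():
                assert lmap.length >= comp.length - 1e-9


class TestSpearmanOrder:
    def test_identical_orders(self):
        a = make_map([0, 1, 2, 3], names=list("wxyz"))
        b = make_map([0, 5, 9, 12], names=list("wxyz"))
        r, p, n = spearman_order(a, b)
        assert r == pytest.approx(1.0) and n == 4

    def test_fully_reversed(self):
        a = make_map([0, 1, 2], names=list("xyz"))
        b = make_map([0, 1, 2], names=list("zyx"))
        r, _, _ = spearman_order(a, b)
        assert r == pytest.approx(-1.0)

    def test_known_rank_displacement(self):
        # orders 1,2,3,4,5 vs 1,3,2,5,4: r = 1 - 6*4/(5*24) = 0.8
        a = make_map([0, 1, 2, 3, 4], names=list("abcde"))
        b = make_map([0, 1, 2, 3, 4], names=["a", "c", "b", "e", "d"])
        r, _, _ = spearman_order(a, b)
        assert r == pytest.approx(0.8)

    def test_exact_permutation_p_value(self):
        # n = 4, perfect agreement: only 2 of 4! = 24 permutations reach |r| = 1
        a = make_map([0, 1, 2, 3], names=list("wxyz"))
        b = make_map([0, 1, 2, 3], names=list("wxyz"))
        _, p, _ = spearman_order(a, b)
        assert p == pytest.approx(2 / 24)

    def test_large_n_uses_t_approximation(self, rng):
        names = [f"m{k:02d}" for k in range(20)]
        a = make_map(list(range(20)), names=names)
        perm = rng.permutation(20)
        b = make_map(list(range(20)), names=[names[k] for k in perm])
        r, p, n = spearman_order(a, b)
        pos_a = [a.position_of(m) for m in names]
        pos_b = [b.position_of(m) for m in names]
        ref = stats.spearmanr(pos_a, pos_b)
        assert r == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))

    def test_too_few_shared_missing(self):
        a = make_map([0.0], names=["only"])
        b = make_map([0.0], names=["only"])
        r, p, n = spearman_order(a, b)
        assert np.isnan(r) and n == 1


class TestDotplot:
    def test_shared_markers_only(self):
        a = make_map([0, 1, 2, 3, 4], names=list("abcde"))
        b = make_map([0, 1, 2], names=["b", "d", "q"])
        rows = dotplot_table(a, b)
        assert [r[0] for r in rows] == ["b", "d"]

    def test_no_shared_empty(self):
        a = make_map([0], names=["a"])
        b = make_map([0], names=["z"])
        assert dotplot_table(a, b) == []

    def test_row_count_matches_spearman_n(self, rng):
        names = [f"m{k}" for k in range(10)]
        a = make_map(list(range(10)), names=names)
        b = make_map(list(range(6)), names=[names[k] for k in rng.choice(10, 6, replace=False)])
        _, _, n = spearman_order(a, b)
        assert len(dotplot_table(a, b)) == n
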