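"""End-to-end orchestration: consolidate -> bin -> integrate -> compare.

The workflow mirrors standard multi-population map integration practice:
genotype matrices arrive already pooled per linkage group, so
consolidation orders all markers of an LG matrix directly (the LOD
grouping operation remains available as a stand-alone QC step for
unassigned panels).  Consolidation is two-stage: an initial order, a
single masking pass removing single-locus double crossovers, then
re-estimation and re-ordering on the masked matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .binning import assign_representatives, build_bins, reattach_residuals, skeleton_map
from .consensus import (
    ConsensusGraph,
    RegressionFit,
    fit_to_map,
    linearize,
    map_to_dag,
    merge_dags,
    pool_pairs,
    regression_integrate,
    resolve_conflicts,
)
from .core import Bin, GenotypeMatrix, IntegrationConfig, LinkageMap
from .genotypes import mask_double_crossovers
from .linkage import order_markers, orient_map, pairwise_rf_lod


@dataclass
class ConsolidatedPopulation:
    population: str
    lg: str
    map: LinkageMap
    matrix: GenotypeMatrix  # masked matrix
    n_masked: int
    bins: list[Bin] = field(default_factory=list)
    skeleton: LinkageMap | None = None


def consolidate_lg(
    matrix: GenotypeMatrix,
    lg: str,
    cfg: IntegrationConfig | None = None,
    reference: LinkageMap | None = None,
) -> ConsolidatedPopulation:
    """Order one LG's markers, mask double crossovers, re-order.

    The masking pass runs once against the initial order; the masked
    matrix is then re-analysed with the same ordering algorithm.  With a
    ``reference`` map the result is oriented to it, otherwise the
    canonical orientation from :func:`order_markers` stands.
    """
    cfg = cfg or IntegrationConfig()
    initial = order_markers(matrix, set(matrix.markers), cfg)
    masked, n_masked = mask_double_crossovers(matrix, initial)
    final = order_markers(
        masked, set(matrix.markers), cfg, initial_order=initial.markers
    )
    final = LinkageMap(matrix.population, lg, final.entries)
    if reference is not None:
        final = orient_map(final, reference)
    return ConsolidatedPopulation(matrix.population, lg, final, masked, n_masked)


def skeletonize(
    pops: Sequence[ConsolidatedPopulation], cfg: IntegrationConfig | None = None
) -> None:
    """Build bin maps and bridge-first skeletons for each population (in place)."""
    cfg = cfg or IntegrationConfig()
    marker_sets = {p.population: set(p.map.markers) for p in pops}
    for p in pops:
        others = {k: v for k, v in marker_sets.items() if k != p.population}
        scores = {m: p.matrix.n_scored(m) for m in p.map.markers}
        bins = build_bins(p.map, cfg.bin_width)
        assign_representatives(bins, others, scores)
        p.bins = bins
        p.skeleton = skeleton_map(p.map, bins)


@dataclass
class IntegrationResult:
    engine: str
    consensus: LinkageMap  # skeleton-level consensus
    full_map: LinkageMap  # with residual markers re-attached
    unplaced: list[str]
    rounds: list[RegressionFit] | None = None
    deletions: list[tuple[str, str]] | None = None


def integrate_regression(
    pops: Sequence[ConsolidatedPopulation],
    lg: str,
    cfg: IntegrationConfig | None = None,
) -> IntegrationResult:
    """Pooled-recombination regression integration of skeleton maps."""
    cfg = cfg or IntegrationConfig()
    per_pop_pairs = []
    for p in pops:
        if p.skeleton is None:
            raise ValueError("run skeletonize first")
        # pair statistics from this population's masked matrix over every
        # representative marker it scored (its own and other populations')
        skeleton_union = sorted(
            {
                m
                for q in pops
                if q.skeleton is not None
                for m in q.skeleton.markers
                if m in p.matrix.markers
            }
        )
        per_pop_pairs.append(pairwise_rf_lod(p.matrix.subset_markers(skeleton_union)))
    pooled = pool_pairs(per_pop_pairs)
    rounds = regression_integrate(pooled, cfg)
    consensus = fit_to_map(rounds[-1], lg=lg)
    # the least-squares coordinates are sign-blind; orient like the components
    consensus = orient_map(consensus, pops[0].map)
    bins_per_pop = {p.population: p.bins for p in pops}
    full, unplaced = reattach_residuals(consensus, bins_per_pop)
    return IntegrationResult("regression", consensus, full, unplaced, rounds=rounds)


def integrate_dag(
    pops: Sequence[ConsolidatedPopulation], lg: str
) -> IntegrationResult:
    """DAG merge integration of skeleton maps with conflict resolution."""
    fragments = []
    for p in pops:
        if p.skeleton is None:
            raise ValueError("run skeletonize first")
        fragments.append(map_to_dag(p.skeleton))
    merged = merge_dags(fragments)
    resolved, deletions = resolve_conflicts(merged)
    consensus = linearize(resolved, lg=lg)
    consensus = orient_map(consensus, pops[0].map)
    bins_per_pop = {p.population: p.bins for p in pops}
    full, unplaced = reattach_residuals(consensus, bins_per_pop)
    return IntegrationResult(
        "dag", consensus, full, unplaced, deletions=deletions
    )
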