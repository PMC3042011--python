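"""Map summary statistics and interval histograms.

Density conventions: locus density = total length / unique locus count and
marker density = total length / marker count, both reported to 2 decimals;
physical densities are genome size / count to the nearest Kbp; the mean LG
length is reported to 1 decimal.  Percentages are computed on unrounded
values and rounded last.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import LinkageMap


@dataclass
class MapSummary:
    per_lg: pd.DataFrame  # columns: lg, n_markers, n_loci, length_cm
    total_markers: int
    total_loci: int
    total_length_cm: float
    cm_per_locus: float
    cm_per_marker: float
    mean_lg_length_cm: float
    kbp_per_locus: int | None = None
    kbp_per_marker: int | None = None


def per_lg_table(maps: Iterable[LinkageMap]) -> pd.DataFrame:
    """Per-LG marker counts, unique locus counts and lengths from maps."""
    rows = []
    for lmap in maps:
        positions = lmap.positions
        rows.append(
            {
                "lg": lmap.lg,
                "n_markers": len(lmap),
                "n_loci": len(np.unique(np.round(positions, 9))),
                "length_cm": lmap.length,
            }
        )
    return pd.DataFrame(rows, columns=["lg", "n_markers", "n_loci", "length_cm"])


def summarize_table(
    table: pd.DataFrame, genome_size_mbp: float | None = None
) -> MapSummary:
    """Summary arithmetic over a per-LG table (lg, n_markers, n_loci, length_cm)."""
    total_markers = int(table["n_markers"].sum())
    total_loci = int(table["n_loci"].sum())
    total_length = float(table["length_cm"].sum())
    if total_markers == 0:
        raise ValueError("summary of a map with zero markers")
    summary = MapSummary(
        per_lg=table.reset_index(drop=True),
        total_markers=total_markers,
        total_loci=total_loci,
        total_length_cm=total_length,
        cm_per_locus=round(total_length / total_loci, 2),
        cm_per_marker=round(total_length / total_markers, 2),
        mean_lg_length_cm=round(total_length / len(table), 1),
    )
    if genome_size_mbp is not None:
        summary.kbp_per_locus = round(genome_size_mbp * 1000.0 / total_loci)
        summary.kbp_per_marker = round(genome_size_mbp * 1000.0 / total_markers)
    return summary


def summarize(
    maps: Iterable[LinkageMap], genome_size_mbp: float | None = None
) -> MapSummary:
    """Summary statistics over a set of LG maps."""
    return summarize_table(per_lg_table(maps), genome_size_mbp)


def interval_histogram(
    maps: Iterable[LinkageMap], edges: Sequence[float] | None = None
) -> dict[str, int]:
    """Histogram of consecutive inter-locus gaps across LGs.

    Default edges give 1-cM classes up to 10 cM with a 0.2-cM sub-partition
    of the 0-1 cM class (map-interval distributions are typically highly
    skewed toward short gaps).  Gaps land in [edge_i, edge_{i+1}); the last
    class is open-ended.
    """
    if edges is None:
        edges = [0.0, 0.2, 0.4, 0.6, 0.8] + [float(k) for k in range(1, 11)]
    edges = list(edges)
    gaps: list[float] = []
    for lmap in maps:
        # gaps between consecutive unique loci
        uniq = np.unique(np.round(lmap.positions, 9))
        gaps.extend(np.diff(uniq).tolist())
    bins = np.array(edges + [np.inf])
    counts, _ = np.histogram(gaps, bins=bins)
    labels = [
        f"{bins[i]:g}-{bins[i + 1]:g} cM" if np.isfinite(bins[i + 1]) else f">{bins[i]:g} cM"
        for i in range(len(bins) - 1)
    ]
    return dict(zip(labels, (int(c) for c in counts)))
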