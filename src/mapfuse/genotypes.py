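"""Genotype curation: source merging, segregation distortion, masking.

A DH population segregates 1:1 at every locus under Mendelian expectation,
so distortion is tested with a one-degree-of-freedom chi-square on the
non-missing allele counts.  Single-locus double crossovers (a lone call
disagreeing with both flanking calls) are overwhelmingly genotyping errors
at typical marker densities and are masked to missing before re-mapping.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import stats

from .core import (
    A,
    B,
    MISSING,
    GenotypeMatrix,
    LgSkewSummary,
    LinkageMap,
    SegregationResult,
)

log = logging.getLogger(__name__)


def merge_score_sources(sources: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Merge genotype sources for one population into a single matrix.

    Where a marker was scored in more than one source, the source with the
    greater number of non-missing genotype scores contributes its column;
    ties keep the earlier-listed source.  Line sets are unioned (absent
    scores become missing).
    """
    if not sources:
        raise ValueError("no sources to merge")
    pops = {s.population for s in sources}
    if len(pops) > 1:
        raise ValueError(f"sources span multiple populations: {sorted(pops)}")
    population = sources[0].population

    lines: list[str] = []
    for s in sources:
        for ln in s.lines:
            if ln not in lines:
                lines.append(ln)
    line_idx = {ln: i for i, ln in enumerate(lines)}

    # best source per marker: (non-missing count, earliest index wins ties)
    best: dict[str, tuple[int, int]] = {}  # marker -> (source index, count)
    order: list[str] = []
    for si, s in enumerate(sources):
        scored = (s.calls != MISSING).sum(axis=0)
        for mj, m in enumerate(s.markers):
            if m not in best:
                best[m] = (si, int(scored[mj]))
                order.append(m)
            elif int(scored[mj]) > best[m][1]:
                log.info(
                    "marker %s: source %d (%d scores) replaces source %d (%d scores)",
                    m, si, int(scored[mj]), best[m][0], best[m][1],
                )
                best[m] = (si, int(scored[mj]))

    calls = np.full((len(lines), len(order)), MISSING, dtype=np.int8)
    for mj, m in enumerate(order):
        si, _ = best[m]
        src = sources[si]
        col = src.column(m)
        for li, ln in enumerate(src.lines):
            calls[line_idx[ln], mj] = col[li]
    return GenotypeMatrix(population, lines, order, calls)


def segregation_test(
    matrix: GenotypeMatrix, alpha: float = 0.05
) -> list[SegregationResult]:
    """Chi-square (1 df) test of 1:1 segregation per marker.

    Markers with zero non-missing calls are omitted with a warning.  A
    significant excess of A calls favors the female parent, of B calls the
    male parent.
    """
    results = []
    for j, m in enumerate(matrix.markers):
        col = matrix.calls[:, j]
        a = int((col == A).sum())
        b = int((col == B).sum())
        if a + b == 0:
            warnings.warn(f"marker {m}: no non-missing calls, omitted")
            continue
        chi2 = (a - b) ** 2 / (a + b)
        p = float(stats.chi2.sf(chi2, df=1))
        if p >= alpha:
            favored = "none"
        else:
            favored = "female" if a > b else "male"
        results.append(SegregationResult(m, a, b, chi2, p, favored))
    return results


def lg_skew_summary(matrix: GenotypeMatrix, lmap: LinkageMap) -> LgSkewSummary:
    """Pooled allele-ratio skew over all mapped loci of one LG.

    Counts are pooled over loci and lines before the chi-square (pooling,
    not averaging of per-locus statistics).
    """
    missing = [m for m in lmap.markers if m not in matrix.markers]
    if missing:
        raise ValueError(f"map markers absent from matrix: {missing[:5]}")
    idx = [matrix.markers.index(m) for m in lmap.markers]
    sub = matrix.calls[:, idx]
    total_a = int((sub == A).sum())
    total_b = int((sub == B).sum())
    if total_a + total_b == 0:
        raise ValueError(f"LG {lmap.lg}: no non-missing calls")
    chi2 = (total_a - total_b) ** 2 / (total_a + total_b)
    p = float(stats.chi2.sf(chi2, df=1))
    ratio = total_a / total_b if total_b else float("inf")
    return LgSkewSummary(lmap.lg, ratio, chi2, p)


def mask_double_crossovers(
    matrix: GenotypeMatrix, lmap: LinkageMap
) -> tuple[GenotypeMatrix, int]:
    """Mask single-locus double crossovers to missing.

    For each line, a non-missing call is set to missing when its nearest
    non-missing neighbours on both sides (in map order) agree with each
    other and differ from it.  All eliminations are decided simultaneously
    against the input matrix — one pass, not iterated — and terminal loci
    are never masked.
    """
    order = [m for m in lmap.markers if m in matrix.markers]
    cols = np.array([matrix.markers.index(m) for m in order])
    out = matrix.copy()
    n_masked = 0
    for li in range(matrix.n_lines):
        row = matrix.calls[li, cols]
        observed = np.nonzero(row != MISSING)[0]
        if len(observed) < 3:
            continue
        vals = row[observed]
        # interior observed loci flanked by agreeing, differing neighbours
        flagged = (vals[1:-1] != vals[:-2]) & (vals[:-2] == vals[2:])
        for k in np.nonzero(flagged)[0]:
            out.calls[li, cols[observed[k + 1]]] = MISSING
            n_masked += 1
    return out, n_masked
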