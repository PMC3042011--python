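"""Homology-hit filtering, collinearity-block detection, comparative mapping.

A collinearity block is a chained run of mapped loci whose homologs fall on
one target chromosome, with at least ``min_loci`` loci, no genetic gap
above ``max_gap_genetic`` cM and no physical gap above
``max_gap_physical`` bp between chained neighbours.  The "one shared locus
every X" phrasing of such criteria is equivalent, for a chain, to the
pairwise consecutive-gap constraint used here, which is decidable greedily.
Physical gaps use absolute bp differences so inverted blocks chain
naturally; orientation is decided afterwards from the sign of the rank
correlation of cM against bp.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import (
    CollinearityBlock,
    HitFilterProfile,
    HomologyHit,
    LinkageMap,
    SyntenyCriteria,
)


# ---------------------------------------------------------------------------
# hit filtering
# ---------------------------------------------------------------------------

def filter_hits(
    hits: Sequence[HomologyHit], profile: HitFilterProfile
) -> list[HomologyHit]:
    """Keep hits satisfying all three thresholds; order-preserving."""
    return [
        h
        for h in hits
        if h.evalue <= profile.max_evalue
        and h.identity >= profile.min_identity
        and h.aln_len >= profile.min_aln_len
    ]


def best_hit(hits: Sequence[HomologyHit]) -> dict[str, HomologyHit]:
    """Highest-bitscore hit per query (ties: lowest e-value, then smallest
    target coordinate, then target name)."""
    best: dict[str, HomologyHit] = {}
    for h in hits:
        cur = best.get(h.query)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[h.query] = h
    return best


def _hit_rank(h: HomologyHit) -> tuple:
    return (-h.bitscore, h.evalue, h.target_start, h.target_seq)


# ---------------------------------------------------------------------------
# virtual PCR on primer-pair hits
# ---------------------------------------------------------------------------

def virtual_pcr(
    forward_hits: Sequence[HomologyHit],
    reverse_hits: Sequence[HomologyHit],
    max_mismatches: int = 1,
    min_product: int = 150,
    max_product: int = 1000,
) -> tuple[str, int, int] | None:
    """Accept a primer pair's target interval when it could amplify.

    Requires both primers on the same target chromosome, on opposite
    strands pointing inward, each with at most ``max_mismatches``, and an
    outermost product span strictly between ``min_product`` and
    ``max_product`` bp.  Returns (chrom, start, end) of the best-supported
    product (smallest combined e-value) or None.
    """
    best = None
    for f, r in itertools.product(forward_hits, reverse_hits):
        if f.target_seq != r.target_seq:
            continue
        if f.mismatches > max_mismatches or r.mismatches > max_mismatches:
            continue
        if f.strand == r.strand:
            continue
        plus, minus = (f, r) if f.strand == "+" else (r, f)
        if plus.target_start > minus.target_start:
            continue  # not pointing inward
        start = min(f.target_start, r.target_start)
        end = max(f.target_end, r.target_end)
        length = end - start + 1
        if not (min_product < length < max_product):
            continue
        score = f.evalue + r.evalue
        if best is None or score < best[0]:
            best = (score, (f.target_seq, start, end))
    return best[1] if best else None


# ---------------------------------------------------------------------------
# transitive homology via annotated BACs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    seq_id: str  # annotated BAC/scaffold
    gene: str
    start: int
    end: int


def transitive_homology(
    bac_hits: Mapping[str, Sequence[HomologyHit]],
    annotations: Sequence[GeneAnnotation],
    direct: Mapping[str, str] | None = None,
) -> dict[str, dict]:
    """Infer marker-to-gene homology through annotated intermediate clones.

    A marker inherits every annotated gene overlapping its hit interval on
    the clone; more than one overlapping gene is reported with an
    ``ambiguous`` flag.  Markers with a direct assignment keep it and skip
    the transitive inference.
    """
    direct = direct or {}
    by_seq: dict[str, list[GeneAnnotation]] = {}
    for ann in annotations:
        by_seq.setdefault(ann.seq_id, []).append(ann)
    out: dict[str, dict] = {}
    for marker in sorted(bac_hits):
        if marker in direct:
            out[marker] = {"genes": [direct[marker]], "ambiguous": False, "source": "direct"}
            continue
        genes: list[str] = []
        for h in bac_hits[marker]:
            for ann in by_seq.get(h.target_seq, []):
                if h.target_start <= ann.end and ann.start <= h.target_end:
                    if ann.gene not in genes:
                        genes.append(ann.gene)
        if genes:
            out[marker] = {
                "genes": sorted(genes),
                "ambiguous": len(genes) > 1,
                "source": "transitive",
            }
    return out


# ---------------------------------------------------------------------------
# collinearity blocks
# ---------------------------------------------------------------------------

def detect_blocks(
    lmap: LinkageMap,
    locus_homology: Mapping[str, tuple[str, int] | Sequence[tuple[str, int]]],
    criteria: SyntenyCriteria = SyntenyCriteria(),
) -> list[CollinearityBlock]:
    """Chain homologous loci into conserved collinearity blocks.

    Loci are taken in genetic order per target chromosome; a chain breaks
    when the genetic gap exceeds ``max_gap_genetic`` or the absolute
    physical gap exceeds ``max_gap_physical``.  Chains with at least
    ``min_loci`` loci are emitted with the Spearman correlation of cM vs bp
    and its two-sided p-value; orientation is forward when r >= 0.  A locus
    homologous to several chromosomes is chained on each independently, so
    nested and overlapping blocks are all reported.
    """
    per_chrom: dict[str, list[tuple[str, float, int]]] = {}
    for m, pos in lmap.entries:
        if m not in locus_homology:
            continue
        hom = locus_homology[m]
        targets = [hom] if isinstance(hom, tuple) else list(hom)
        for chrom, bp in targets:
            per_chrom.setdefault(chrom, []).append((m, pos, int(bp)))

    blocks: list[CollinearityBlock] = []
    for chrom in sorted(per_chrom):
        loci = sorted(per_chrom[chrom], key=lambda t: (t[1], t[0]))
        chain: list[tuple[str, float, int]] = []
        for locus in loci:
            if chain:
                prev = chain[-1]
                if (
                    locus[1] - prev[1] > criteria.max_gap_genetic
                    or abs(locus[2] - prev[2]) > criteria.max_gap_physical
                ):
                    blocks.extend(_emit(lmap.lg, chrom, chain, criteria))
                    chain = []
            chain.append(locus)
        blocks.extend(_emit(lmap.lg, chrom, chain, criteria))
    blocks.sort(key=lambda b: (b.genetic_span, b.target_chrom))
    return blocks


def _emit(
    lg: str, chrom: str, chain: list[tuple[str, float, int]], criteria: SyntenyCriteria
) -> list[CollinearityBlock]:
    if len(chain) < criteria.min_loci:
        return []
    cm = np.array([c[1] for c in chain])
    bp = np.array([c[2] for c in chain])
    if len(set(cm)) > 1 and len(set(bp)) > 1:
        res = stats.spearmanr(cm, bp)
        r, p = float(res.statistic), float(res.pvalue)
    else:
        r, p = 0.0, 1.0
    return [
        CollinearityBlock(
            lg=lg,
            genetic_span=(float(cm.min()), float(cm.max())),
            target_chrom=chrom,
            physical_span=(int(bp.min()), int(bp.max())),
            loci=list(chain),
            orientation="forward" if r >= 0 else "inverted",
            order_r=r,
            order_p=p,
        )
    ]


def block_summary(
    blocks: Sequence[CollinearityBlock],
    map_total_cM: float,
    genome_size_bp: int | None = None,
    alpha_block: float = 0.05,
) -> dict:
    """Counts, mean sizes and genetic/physical coverage of a block set.

    Percentages are computed on unrounded values, then rounded to 1 dp.
    """
    if not blocks:
        return {
            "n_blocks": 0,
            "mean_loci": 0.0,
            "mean_genetic_length": 0.0,
            "mean_physical_length": 0.0,
            "total_genetic": 0.0,
            "genetic_coverage_pct": 0.0,
            "total_physical": 0,
            "physical_coverage_pct": 0.0 if genome_size_bp else None,
            "n_significant": 0,
        }
    total_genetic = float(sum(b.genetic_length for b in blocks))
    total_physical = int(sum(b.physical_length for b in blocks))
    out = {
        "n_blocks": len(blocks),
        "mean_loci": float(np.mean([b.n_loci for b in blocks])),
        "mean_genetic_length": float(np.mean([b.genetic_length for b in blocks])),
        "mean_physical_length": float(np.mean([b.physical_length for b in blocks])),
        "total_genetic": total_genetic,
        "genetic_coverage_pct": round(100.0 * total_genetic / map_total_cM, 1),
        "total_physical": total_physical,
        "physical_coverage_pct": (
            round(100.0 * total_physical / genome_size_bp, 1) if genome_size_bp else None
        ),
        "n_significant": sum(1 for b in blocks if b.order_p < alpha_block),
    }
    return out


def coverage_percent(total_block_cM: float, map_total_cM: float) -> float:
    """Percent of map length covered by blocks, rounded to 1 dp."""
    return round(100.0 * total_block_cM / map_total_cM, 1)


# ---------------------------------------------------------------------------
# genetic vs physical comparison and scaffold anchoring
# ---------------------------------------------------------------------------

def genetic_vs_physical(
    lmap: LinkageMap,
    physical: Mapping[str, int],
    window: tuple[float, float] | None = None,
) -> tuple[float, float, int]:
    """Spearman correlation of genetic (cM) vs physical (bp) positions.

    ``window`` restricts to markers with cM inside [start, end].  Fewer
    than 2 usable markers: (nan, nan, n).
    """
    pts = [
        (pos, physical[m])
        for m, pos in lmap.entries
        if m in physical and (window is None or window[0] <= pos <= window[1])
    ]
    n = len(pts)
    if n < 2:
        return float("nan"), float("nan"), n
    cm = [p[0] for p in pts]
    bp = [p[1] for p in pts]
    res = stats.spearmanr(cm, bp)
    return float(res.statistic), float(res.pvalue), n


def anchor_scaffolds(
    scaffold_hits: Mapping[str, Sequence[str]],
    maps: Sequence[LinkageMap],
    min_markers: int = 2,
) -> dict[str, str | None]:
    """Assign scaffolds to LGs by strict majority of mapped-marker hits.

    A scaffold needs at least ``min_markers`` hits to mapped markers and a
    strict majority on one LG; ties or sub-threshold evidence leave it
    unanchored (None) — unresolvable for repeat-rich or duplicated regions.
    """
    marker_lg = {m: lmap.lg for lmap in maps for m in lmap.markers}
    out: dict[str, str | None] = {}
    for scaf in sorted(scaffold_hits):
        votes: dict[str, int] = {}
        for marker in scaffold_hits[scaf]:
            lg = marker_lg.get(marker)
            if lg is not None:
                votes[lg] = votes.get(lg, 0) + 1
        total = sum(votes.values())
        if total < min_markers:
            out[scaf] = None
            continue
        top_lg, top = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
        out[scaf] = top_lg if 2 * top > total else None
    return out


def local_reorder_physical(
    consensus: LinkageMap,
    bins: Sequence,  # Bin objects (possibly from several populations)
    co_location: Mapping[str, tuple[str, int]],
    orientations: Mapping[str, str] | None = None,
) -> tuple[LinkageMap, float]:
    """Reorder co-located markers by physical proximity on shared sequences.

    Only markers inside the same bin and hitting the same target sequence
    are permuted — recombination evidence always wins where it exists.  The
    sort is by bp, ascending inside forward blocks and descending inside
    inverted ones (``orientations`` per seq_id, default forward).  cM
    positions are unchanged; the returned fraction counts markers whose
    listing rank changed.
    """
    orientations = orientations or {}
    order = list(consensus.markers)
    slot_pos = [p for _, p in consensus.entries]  # positions stay with slots
    rank = {m: i for i, m in enumerate(order)}
    for b in bins:
        members = [m for m in b.marker_names if m in rank]
        by_seq: dict[str, list[str]] = {}
        for m in members:
            if m in co_location:
                by_seq.setdefault(co_location[m][0], []).append(m)
        for seq_id, group in by_seq.items():
            if len(group) < 2:
                continue
            slots = sorted(rank[m] for m in group)
            descending = orientations.get(seq_id) == "inverted"
            resorted = sorted(
                group, key=lambda m: co_location[m][1], reverse=descending
            )
            for slot, m in zip(slots, resorted):
                order[slot] = m
            rank = {m: i for i, m in enumerate(order)}
    n_changed = sum(1 for i, m in enumerate(order) if consensus.markers[i] != m)
    fraction = n_changed / len(order) if order else 0.0
    entries = list(zip(order, slot_pos))
    return LinkageMap(consensus.map_name, consensus.lg, entries), fraction
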