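"""Synthetic multi-population DH panels and synthetic homology structure.

Each simulated line is one gamete: a Markov chain along the ordered
markers of an LG, starting A or B with equal probability and switching
between adjacent markers with probability given by the inverse Kosambi
function of the true interval (no crossover interference beyond what
Kosambi implies — the process is Markov per interval, matching the
assumptions of two-point estimation).  Genotyping error then flips calls
independently, and missingness blanks them.  Segregation distortion is
modelled as single-locus viability selection by acceptance-rejection:
a gamete carrying the disfavoured (male, B) allele at a distortion locus
is accepted with probability w, giving an expected allele ratio 1/w : 1.

The homology structure emulates an ancestrally triplicated genome: each
pseudo-reference chromosome segment recurs in ``triplication_copies`` map
segments, with random orientation, so block detection can be exercised
without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import A, B, MISSING, GenotypeMatrix, HomologyHit, LinkageMap
from .linkage import kosambi_to_r

# genetic-to-physical scale of the synthetic reference (bp per cM); 200 kb/cM
# keeps marker spacings compatible with the 1 Mb physical-gap block criterion
# at the default marker densities.
BP_PER_CM = 200_000


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic panels.

    Defaults emulate a three-population DH panel of ~100 lines each on a
    100 cM linkage group with 40 markers, 30% bridge markers scored in all
    populations, 0.5% genotyping error and 5% missing data.
    """

    n_populations: int = 3
    lines_per_population: int = 100
    lgs: list[tuple[str, float, int]] = field(
        default_factory=lambda: [("LG1", 100.0, 40)]
    )
    bridge_fraction: float = 0.3
    error_rate: float = 0.005
    missing_rate: float = 0.05
    distortion: list[tuple[str, float, float]] = field(default_factory=list)
    triplication_copies: int = 3
    segments_per_lg: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.bridge_fraction, self.error_rate, self.missing_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        for _, length, n in self.lgs:
            if length <= 0 or n <= 0:
                raise ValueError("LG lengths and marker counts must be positive")


@dataclass
class Segment:
    """One map segment and the reference interval it is homologous to."""

    lg: str
    cm_start: float
    cm_end: float
    ref_chrom: str
    ref_start: int
    ref_end: int
    orientation: str  # "+" | "-"
    markers: list[str]


@dataclass
class Truth:
    maps: list[LinkageMap]
    homology: dict[str, tuple[str, int, str]]  # marker -> (ref chrom, bp, strand)
    segments: list[Segment]
    scored_by: dict[str, set[int]]  # marker -> population indices scoring it


def _rng(seed: int, *streams: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), *streams])


def simulate_truth(cfg: SimulationConfig) -> Truth:
    """True marker positions, population assignments and homology table."""
    rng = _rng(cfg.seed, 0)
    maps: list[LinkageMap] = []
    segments: list[Segment] = []
    homology: dict[str, tuple[str, int, str]] = {}
    scored_by: dict[str, set[int]] = {}

    all_segments: list[Segment] = []
    for lg, length, n in cfg.lgs:
        pos = np.sort(rng.uniform(0.0, length, size=n))
        names = [f"{lg}m{i:03d}" for i in range(n)]
        maps.append(LinkageMap("truth", lg, list(zip(names, pos))))
        bounds = np.linspace(0.0, length, cfg.segments_per_lg + 1)
        for s in range(cfg.segments_per_lg):
            members = [
                names[i]
                for i in range(n)
                if bounds[s] <= pos[i] < bounds[s + 1] or (s == cfg.segments_per_lg - 1 and pos[i] == length)
            ]
            all_segments.append(
                Segment(lg, float(bounds[s]), float(bounds[s + 1]), "", 0, 0, "+", members)
            )
        # population scoring: bridge markers go to every population, the
        # rest to exactly one
        for name in names:
            if rng.uniform() < cfg.bridge_fraction:
                scored_by[name] = set(range(cfg.n_populations))
            else:
                scored_by[name] = {int(rng.integers(cfg.n_populations))}

    n_ref = int(np.ceil(len(all_segments) / cfg.triplication_copies))
    perm = rng.permutation(len(all_segments))
    for ref_idx in range(n_ref):
        chrom = f"Chr{ref_idx + 1:02d}"
        seg_ids = perm[
            ref_idx * cfg.triplication_copies : (ref_idx + 1) * cfg.triplication_copies
        ]
        for seg_id in seg_ids:
            seg = all_segments[seg_id]
            span_cm = seg.cm_end - seg.cm_start
            seg.ref_chrom = chrom
            seg.ref_start = 1
            seg.ref_end = max(2, int(span_cm * BP_PER_CM))
            seg.orientation = "+" if rng.uniform() < 0.5 else "-"
            lmap = next(m for m in maps if m.lg == seg.lg)
            for marker in seg.markers:
                frac = (lmap.position_of(marker) - seg.cm_start) / max(span_cm, 1e-9)
                if seg.orientation == "-":
                    frac = 1.0 - frac
                bp = seg.ref_start + int(frac * (seg.ref_end - seg.ref_start))
                homology[marker] = (chrom, bp, seg.orientation)
            segments.append(seg)

    return Truth(maps, homology, segments, scored_by)


def simulate_dh_population(
    truth: Truth, cfg: SimulationConfig, pop_index: int
) -> GenotypeMatrix:
    """One DH population's genotype matrix over its scored markers."""
    rng = _rng(cfg.seed, 1, pop_index)
    cols: list[str] = []
    blocks: list[np.ndarray] = []
    n_lines = cfg.lines_per_population
    for lmap in truth.maps:
        names = lmap.markers
        pos = lmap.positions
        n = len(names)
        trans = np.array(
            [kosambi_to_r(pos[i + 1] - pos[i]) for i in range(n - 1)]
        )
        dist_idx = [
            int(np.argmin(np.abs(pos - at)))
            for lg, at, _ in cfg.distortion
            if lg == lmap.lg
        ]
        dist_w = [w for lg, _, w in cfg.distortion if lg == lmap.lg]

        gametes = np.empty((n_lines, n), dtype=np.int8)
        for li in range(n_lines):
            while True:
                g = np.empty(n, dtype=np.int8)
                g[0] = A if rng.uniform() < 0.5 else B
                flips = rng.uniform(size=n - 1) < trans
                for k in range(1, n):
                    g[k] = (g[k - 1] + flips[k - 1]) % 2
                accept = True
                for idx, w in zip(dist_idx, dist_w):
                    if g[idx] == B and rng.uniform() >= w:
                        accept = False
                        break
                if accept:
                    gametes[li] = g
                    break
        cols.extend(names)
        blocks.append(gametes)

    calls = np.concatenate(blocks, axis=1)
    # genotyping error, then missingness, independent per call
    err = rng.uniform(size=calls.shape) < cfg.error_rate
    calls = np.where(err, 1 - calls, calls).astype(np.int8)
    miss = rng.uniform(size=calls.shape) < cfg.missing_rate
    calls[miss] = MISSING

    scored = [i for i, m in enumerate(cols) if pop_index in truth.scored_by[m]]
    lines = [f"P{pop_index}_L{i:03d}" for i in range(n_lines)]
    return GenotypeMatrix(
        f"pop{pop_index}", lines, [cols[i] for i in scored], calls[:, scored]
    )


def simulate_hits(
    truth: Truth,
    cfg: SimulationConfig,
    noise: float = 0.0,
    true_identity: tuple[float, float] = (92.0, 99.5),
    spurious_identity: tuple[float, float] = (40.0, 70.0),
    aln_len: int = 150,
) -> list[HomologyHit]:
    """One strong true hit per marker plus Poisson spurious sub-threshold hits."""
    rng = _rng(cfg.seed, 2)
    chroms = sorted({chrom for chrom, _, _ in truth.homology.values()})
    hits: list[HomologyHit] = []
    for marker in sorted(truth.homology):
        chrom, bp, strand = truth.homology[marker]
        ident = float(rng.uniform(*true_identity))
        hits.append(
            HomologyHit(
                query=marker,
                target_seq=chrom,
                target_start=bp,
                target_end=bp + aln_len - 1,
                strand=strand,
                identity=ident,
                aln_len=aln_len,
                evalue=1e-40,
                bitscore=2.0 * aln_len * ident / 100.0,
            )
        )
        for _ in range(rng.poisson(noise)):
            s_chrom = chroms[int(rng.integers(len(chroms)))]
            s_bp = int(rng.integers(1, 5_000_000))
            s_len = int(rng.integers(20, 60))
            s_ident = float(rng.uniform(*spurious_identity))
            hits.append(
                HomologyHit(
                    query=marker,
                    target_seq=s_chrom,
                    target_start=s_bp,
                    target_end=s_bp + s_len - 1,
                    strand="+" if rng.uniform() < 0.5 else "-",
                    identity=s_ident,
                    aln_len=s_len,
                    evalue=float(rng.uniform(1e-3, 1.0)),
                    bitscore=s_len * s_ident / 100.0,
                )
            )
    return hits
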