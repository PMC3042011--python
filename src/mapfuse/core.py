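"""Core containers for multi-population linkage-map integration.

Alleles in a doubled-haploid (DH) population are homozygous: every line
carries either the female-parent allele ``A`` or the male-parent allele
``B`` at each locus, with ``-`` marking a missing score.  Internally calls
are stored as a small integer matrix (lines x markers): 0 = A, 1 = B,
-1 = missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# allele codes
A = 0
B = 1
MISSING = -1

ALLELE_SYMBOLS = {A: "A", B: "B", MISSING: "-"}
SYMBOL_CODES = {"A": A, "B": B, "-": MISSING}

ASSAY_CLASSES = frozenset({"RFLP", "SSR", "SNP", "AFLP", "RAPD", "OTHER"})


class ParseError(ValueError):
    """Raised when an external file violates its format contract."""


@dataclass(frozen=True)
class MarkerAssay:
    """A canonical marker assay and the populations in which it was scored."""

    name: str
    assay_class: str = "OTHER"
    populations: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("marker name must be non-empty")
        if self.assay_class not in ASSAY_CLASSES:
            raise ValueError(f"unknown assay class {self.assay_class!r}")


@dataclass
class GenotypeMatrix:
    """Allele calls of one DH population, lines x markers."""

    population: str
    lines: list[str]
    markers: list[str]
    calls: np.ndarray  # int8, shape (n_lines, n_markers)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.lines), len(self.markers)):
            raise ValueError("calls shape does not match lines x markers")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker names")
        if len(set(self.lines)) != len(self.lines):
            raise ValueError("duplicate line names")
        bad = ~np.isin(self.calls, (A, B, MISSING))
        if bad.any():
            raise ValueError("calls outside the {A, B, MISSING} domain")

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_index(self, name: str) -> int:
        return self.markers.index(name)

    def column(self, name: str) -> np.ndarray:
        return self.calls[:, self.markers.index(name)]

    def n_scored(self, name: str) -> int:
        """Number of non-missing calls for a marker."""
        return int((self.column(name) != MISSING).sum())

    def subset_markers(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.markers.index(n) for n in names]
        return GenotypeMatrix(
            self.population, list(self.lines), list(names), self.calls[:, idx].copy()
        )

    def to_dataframe(self) -> pd.DataFrame:
        sym = np.vectorize(ALLELE_SYMBOLS.get)(self.calls)
        return pd.DataFrame(sym, index=self.lines, columns=self.markers)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.population, list(self.lines), list(self.markers), self.calls.copy()
        )


@dataclass
class LinkageMap:
    """Ordered (marker, cM) entries of one linkage group (LG)."""

    map_name: str
    lg: str
    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        names = [m for m, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate marker within LG {self.lg}")
        pos = [p for _, p in self.entries]
        if any(b < a - 1e-12 for a, b in zip(pos, pos[1:])):
            raise ValueError(f"positions not non-decreasing in LG {self.lg}")

    @property
    def markers(self) -> list[str]:
        return [m for m, _ in self.entries]

    @property
    def positions(self) -> np.ndarray:
        return np.array([p for _, p in self.entries], dtype=float)

    @property
    def length(self) -> float:
        if not self.entries:
            return 0.0
        p = self.positions
        return float(p[-1] - p[0])

    def position_of(self, marker: str) -> float:
        for m, p in self.entries:
            if m == marker:
                return p
        raise KeyError(marker)

    def as_dict(self) -> dict[str, float]:
        return {m: p for m, p in self.entries}

    def normalized(self) -> "LinkageMap":
        """Shift positions so the first locus sits at 0.0 cM."""
        if not self.entries:
            return replace(self)
        p0 = self.entries[0][1]
        return LinkageMap(
            self.map_name, self.lg, [(m, p - p0) for m, p in self.entries]
        )

    def reversed(self) -> "LinkageMap":
        """Flip orientation; positions re-based to start at 0.0."""
        if not self.entries:
            return replace(self)
        end = self.entries[-1][1]
        ents = [(m, end - p) for m, p in reversed(self.entries)]
        return LinkageMap(self.map_name, self.lg, ents)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class PairwiseLinkage:
    """Two-point recombination estimate for a marker pair in one DH population."""

    marker_i: str
    marker_j: str
    n_informative: int
    n_recomb: int
    r_hat: float
    lod: float


@dataclass(frozen=True)
class HomologyHit:
    """One high-scoring alignment segment of a marker sequence on a target.

    Coordinates are 1-based inclusive with ``start <= end``; strand records
    the alignment orientation.
    """

    query: str
    target_seq: str
    target_start: int
    target_end: int
    strand: str
    identity: float
    aln_len: int
    evalue: float
    bitscore: float
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.target_start > self.target_end:
            raise ValueError("start must be <= end")
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError("identity outside [0, 100]")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass
class IntegrationConfig:
    """Tunable thresholds of the map-construction and integration pipeline.

    lod_group_threshold: two-point LOD above which markers are grouped
        (conventional range 3.0-5.0).
    jump_threshold: normalized goodness-of-fit increase above which a marker
        is deferred during regression integration (range 4.0-6.0).
    alpha: significance level for segregation-distortion and order tests.
    bin_width: cM width of a mapping bin.
    r_max: cap applied to recombination fractions before map-distance
        conversion (Kosambi diverges at r = 0.5).
    """

    lod_group_threshold: float = 4.0
    jump_threshold: float = 5.0
    alpha: float = 0.05
    bin_width: float = 1.0
    r_max: float = 0.4999
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.r_max < 0.5):
            raise ValueError("r_max must lie in (0, 0.5)")


@dataclass(frozen=True)
class SegregationResult:
    marker: str
    count_a: int
    count_b: int
    chi2: float
    p: float
    favored: str  # "female" | "male" | "none"


@dataclass(frozen=True)
class LgSkewSummary:
    lg: str
    ratio: float
    chi2: float
    p: float


@dataclass
class Bin:
    """Run of markers within ``bin_width`` cM of the bin's first position."""

    lg: str
    anchor: float
    members: list[tuple[str, float]]
    representative: str | None = None

    @property
    def marker_names(self) -> list[str]:
        return [m for m, _ in self.members]


@dataclass(frozen=True)
class PooledPair:
    """Meiosis-weighted pooled two-point estimate across populations."""

    marker_i: str
    marker_j: str
    r_mean: float
    lod_sum: float
    n_total: int


@dataclass
class RegressionFit:
    """State of one round of regression map integration."""

    positions: dict[str, float]
    sse: float
    excluded: list[str]
    round: int


@dataclass(frozen=True)
class SyntenyCriteria:
    """Thresholds defining a conserved collinearity block."""

    min_loci: int = 4
    max_gap_genetic: float = 5.0  # cM
    max_gap_physical: int = 1_000_000  # bp
    alpha_block: float = 0.05

    def __post_init__(self) -> None:
        if min(self.min_loci, self.max_gap_genetic, self.max_gap_physical) <= 0:
            raise ValueError("criteria must be strictly positive")


@dataclass(frozen=True)
class HitFilterProfile:
    """Alignment-quality thresholds for retaining homology hits."""

    max_evalue: float
    min_identity: float
    min_aln_len: int


# Presets used for the marker classes and target genomes of the study system:
# RFLP probes vs a diverged dicot reference; SSR clone sequences vs the same
# reference; and Brassica marker sequences vs Brassica BACs/scaffolds, where
# the divergence cutoff is raised.
RFLP_PROFILE = HitFilterProfile(max_evalue=1e-7, min_identity=86.0, min_aln_len=100)
SSR_PROFILE = HitFilterProfile(max_evalue=1e-3, min_identity=80.0, min_aln_len=30)
INTRAGENUS_PROFILE = HitFilterProfile(max_evalue=1e-3, min_identity=90.0, min_aln_len=30)


@dataclass
class CollinearityBlock:
    """Chained run of homologous loci linking a map segment to a chromosome."""

    lg: str
    genetic_span: tuple[float, float]
    target_chrom: str
    physical_span: tuple[int, int]
    loci: list[tuple[str, float, int]]  # (marker, cM, bp)
    orientation: str  # "forward" | "inverted"
    order_r: float
    order_p: float

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def genetic_length(self) -> float:
        return self.genetic_span[1] - self.genetic_span[0]

    @property
    def physical_length(self) -> int:
        return self.physical_span[1] - self.physical_span[0]
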