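"""Readers and writers for the toolkit's external tabular formats.

All formats are plain TSV.  Physical coordinates are kept 1-based inclusive
(the BLAST convention); BED-like inputs are converted on read and the
conversion is logged.  Reader/writer pairs are exact round trips on valid
files, and ingest never silently drops records.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    A,
    B,
    MISSING,
    SYMBOL_CODES,
    GenotypeMatrix,
    HomologyHit,
    LinkageMap,
    ParseError,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# genotype matrices
# ---------------------------------------------------------------------------

def read_genotype_matrix(path: str | Path, population: str) -> GenotypeMatrix:
    """Read a lines x markers TSV of DH allele calls.

    Header row holds marker names; the first column holds line identifiers.
    Cells must be ``A``, ``B`` or ``-``; heterozygote symbols are invalid in
    doubled-haploid data and rejected rather than coerced.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({m for m in header if header.count(m) > 1})
        raise ParseError(f"{path}: duplicate marker column(s) {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.columns = header
    markers = [str(c) for c in df.columns]
    lines = [str(i) for i in df.index]
    calls = np.empty(df.shape, dtype=np.int8)
    values = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            sym = values[i, j].strip()
            if sym not in SYMBOL_CODES:
                raise ParseError(
                    f"{path}: unknown symbol {sym!r} at line {lines[i]!r}, "
                    f"marker {markers[j]!r}"
                )
            calls[i, j] = SYMBOL_CODES[sym]
    return GenotypeMatrix(population, lines, markers, calls)


def write_genotype_matrix(matrix: GenotypeMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", index_label="line")


# ---------------------------------------------------------------------------
# linkage maps
# ---------------------------------------------------------------------------

def read_map(path: str | Path, map_name: str | None = None) -> list[LinkageMap]:
    """Read a (marker, lg, cM) TSV into per-LG maps.

    Each LG's entries are sorted by cM and shifted so the first locus sits at
    0.0 (the data carry no origin convention of their own).
    """
    name = map_name if map_name is not None else Path(path).stem
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "lg": str})
    required = {"marker", "lg", "cM"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    if (df["cM"] < 0).any():
        bad = df.loc[df["cM"] < 0, "marker"].iloc[0]
        raise ParseError(f"{path}: negative cM position for marker {bad!r}")
    maps = []
    for lg, sub in df.groupby("lg", sort=True):
        if sub["marker"].duplicated().any():
            dup = sub.loc[sub["marker"].duplicated(), "marker"].iloc[0]
            raise ParseError(f"{path}: duplicate marker {dup!r} within LG {lg}")
        sub = sub.sort_values(["cM", "marker"], kind="mergesort")
        entries = list(zip(sub["marker"], sub["cM"].astype(float)))
        maps.append(LinkageMap(name, str(lg), entries).normalized())
    return maps


def write_map(maps: Iterable[LinkageMap], path: str | Path) -> None:
    rows = [
        {"marker": m, "lg": lmap.lg, "cM": pos}
        for lmap in maps
        for m, pos in lmap.entries
    ]
    pd.DataFrame(rows, columns=["marker", "lg", "cM"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def write_mapchart(maps: Iterable[LinkageMap], path: str | Path) -> None:
    """Export maps as MapChart-compatible plain text (group blocks)."""
    with open(path, "w") as fh:
        for lmap in maps:
            fh.write(f"group {lmap.lg}\n")
            for m, pos in lmap.entries:
                fh.write(f"{m}\t{pos:.2f}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# homology hits (BLAST tabular, outfmt 6)
# ---------------------------------------------------------------------------

_OUTFMT6_COLUMNS = [
    "query",
    "target",
    "identity",
    "aln_len",
    "mismatches",
    "gapopens",
    "qstart",
    "qend",
    "tstart",
    "tend",
    "evalue",
    "bitscore",
]


def read_hits(path: str | Path) -> list[HomologyHit]:
    """Read 12-column BLAST tabular hits.

    Minus-strand alignments are reported by BLAST with tstart > tend; the
    strand is inferred and coordinates swapped so start <= end.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            names=_OUTFMT6_COLUMNS,
            comment="#",
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    for col in ("identity", "aln_len", "mismatches", "tstart", "tend", "evalue", "bitscore"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.loc[pd.to_numeric(df[col], errors="coerce").isna(), col]
            raise ParseError(f"{path}: non-numeric value {bad.iloc[0]!r} in column {col}")
    hits = []
    for row in df.itertuples(index=False):
        tstart, tend = int(row.tstart), int(row.tend)
        strand = "+" if tstart <= tend else "-"
        start, end = (tstart, tend) if tstart <= tend else (tend, tstart)
        hits.append(
            HomologyHit(
                query=str(row.query),
                target_seq=str(row.target),
                target_start=start,
                target_end=end,
                strand=strand,
                identity=float(row.identity),
                aln_len=int(row.aln_len),
                evalue=float(row.evalue),
                bitscore=float(row.bitscore),
                mismatches=int(row.mismatches),
            )
        )
    return hits


def write_hits(hits: Sequence[HomologyHit], path: str | Path) -> None:
    """Write hits back to BLAST tabular layout (round-trips with read_hits)."""
    rows = []
    for h in hits:
        tstart, tend = (
            (h.target_start, h.target_end)
            if h.strand == "+"
            else (h.target_end, h.target_start)
        )
        rows.append(
            (
                h.query, h.target_seq, h.identity, h.aln_len, h.mismatches, 0,
                1, h.aln_len, tstart, tend, h.evalue, h.bitscore,
            )
        )
    pd.DataFrame(rows, columns=_OUTFMT6_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# physical position tables
# ---------------------------------------------------------------------------

def read_positions(path: str | Path, bed: bool = False) -> dict[str, tuple[str, int]]:
    """Read a (marker, seq_id, bp) TSV mapping markers to physical positions.

    With ``bed=True`` the coordinate is treated as 0-based half-open and
    converted to 1-based inclusive (logged).
    """
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "seq_id": str})
    required = {"marker", "seq_id", "bp"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    offset = 1 if bed else 0
    if bed:
        log.info("%s: converting BED-like 0-based coordinates to 1-based", path)
    return {
        str(r.marker): (str(r.seq_id), int(r.bp) + offset)
        for r in df.itertuples(index=False)
    }


def write_positions(positions: dict[str, tuple[str, int]], path: str | Path) -> None:
    rows = [
        {"marker": m, "seq_id": s, "bp": bp} for m, (s, bp) in positions.items()
    ]
    pd.DataFrame(rows, columns=["marker", "seq_id", "bp"]).to_csv(
        path, sep="\t", index=False
    )
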