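"""Ingestion of break-mapping data into strand-specific 5'-end coverage.

Break mapping and sequencing protocols blunt each double-strand-break end and
ligate the first sequencing adaptor to it, so the 5'-most nucleotide of read 1
maps the break-proximal nucleotide exactly. This module turns the three input
dialects (per-strand ``genomecov -dz`` depth text, BED6 of single-nucleotide
break ends, or filtered paired-end alignments) into sparse per-strand,
per-chromosome coverage maps, and applies interval masks (e.g. centromeres).

All coordinates are 0-based, half-open, matching bedtools/BED conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, TextIO

import numpy as np

POSITIVE = "+"
NEGATIVE = "-"
_STRANDS = (POSITIVE, NEGATIVE)

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "GenomeBuild",
    "StrandProfile",
    "MaskSet",
    "load_genome_tsv",
    "load_depth_dz",
    "write_depth_dz",
    "write_bedgraph",
    "load_break_bed",
    "write_break_bed",
    "load_mask_bed",
    "apply_mask",
    "extract_read1_5prime",
]


class ParseError(ValueError):
    """Malformed input line; message carries the 1-based line number."""


@dataclass(frozen=True)
class GenomeBuild:
    """Reference frame: ordered chromosome names with lengths in nucleotides."""

    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return list(self.chrom_lengths)

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths


def load_genome_tsv(path: str | Path) -> GenomeBuild:
    """Read a two-column chromosome-sizes table (``chrom<TAB>length``)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            sizes[fields[0]] = int(fields[1])
    return GenomeBuild(sizes)


@dataclass
class StrandProfile:
    """Sparse map position -> break-end read count for one strand.

    This is the x(i) (positive strand) or y(i) (negative strand) signal of the
    cross-correlation statistic. Zero counts are never stored; every stored
    position lies within its chromosome.
    """

    strand: str
    genome: GenomeBuild
    data: dict[str, dict[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    def add(self, chrom: str, pos: int, count: int = 1) -> None:
        if chrom not in self.genome:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.genome.length(chrom):
            raise ValueError(
                f"position {pos} out of bounds for {chrom} "
                f"(length {self.genome.length(chrom)})"
            )
        if count <= 0:
            raise ValueError(f"count must be positive, got {count}")
        self.data.setdefault(chrom, {})[pos] = self.data.get(chrom, {}).get(pos, 0) + count

    def total(self) -> int:
        return sum(sum(d.values()) for d in self.data.values())

    def n_positions(self) -> int:
        return sum(len(d) for d in self.data.values())

    def is_empty(self) -> bool:
        return self.n_positions() == 0

    def chroms(self) -> list[str]:
        return [c for c in self.genome.names if c in self.data]

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted position array and matching count array for one chromosome."""
        d = self.data.get(chrom, {})
        if not d:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        pos = np.fromiter(d.keys(), dtype=np.int64, count=len(d))
        cnt = np.fromiter(d.values(), dtype=np.int64, count=len(d))
        order = np.argsort(pos, kind="stable")
        return pos[order], cnt[order]

    def set_arrays(self, chrom: str, pos: np.ndarray, cnt: np.ndarray) -> None:
        """Replace one chromosome's contents from parallel arrays (counts > 0)."""
        self.data[chrom] = dict(zip(pos.tolist(), cnt.tolist()))

    def sum_sq(self) -> float:
        """Genome-wide sum of squared counts (a normalization term)."""
        return float(sum(c * c for d in self.data.values() for c in d.values()))

    def copy(self) -> "StrandProfile":
        return StrandProfile(
            self.strand, self.genome, {c: dict(d) for c, d in self.data.items()}
        )

    def merged_with(self, other: "StrandProfile") -> "StrandProfile":
        """Position-wise sum of two profiles on the same strand and genome."""
        if other.strand != self.strand:
            raise ValueError("cannot merge profiles from different strands")
        out = self.copy()
        for chrom, d in other.data.items():
            for pos, cnt in d.items():
                out.add(chrom, pos, cnt)
        return out


# ---------------------------------------------------------------------------
# dz depth dialect (bedtools genomecov -dz: chrom <TAB> 0-based pos <TAB> depth)
# ---------------------------------------------------------------------------

def load_depth_dz(path: str | Path, strand: str, genome: GenomeBuild) -> StrandProfile:
    """Read a per-strand ``genomecov -dz`` depth file into a profile.

    Each position may appear at most once (the dz dialect emits each covered
    base a single time); duplicates, unknown chromosomes, out-of-bounds
    positions and malformed lines are hard errors.
    """
    profile = StrandProfile(strand, genome)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected 'chrom<TAB>pos<TAB>depth'")
            chrom = fields[0]
            try:
                pos, depth = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer position or depth") from None
            if chrom not in genome:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not 0 <= pos < genome.length(chrom):
                raise ParseError(
                    f"{path}:{lineno}: position {pos} out of bounds for {chrom}"
                )
            if depth < 1:
                raise ParseError(f"{path}:{lineno}: depth must be >= 1, got {depth}")
            chrom_map = profile.data.setdefault(chrom, {})
            if pos in chrom_map:
                raise ParseError(f"{path}:{lineno}: duplicate position {chrom}:{pos}")
            chrom_map[pos] = depth
    return profile


def write_depth_dz(profile: StrandProfile, path: str | Path) -> None:
    """Write a profile as dz depth text, positions sorted within chromosome."""
    with open(path, "w") as fh:
        for chrom in profile.chroms():
            for pos in sorted(profile.data[chrom]):
                fh.write(f"{chrom}\t{pos}\t{profile.data[chrom][pos]}\n")


def write_bedgraph(profile: StrandProfile, path: str | Path) -> None:
    """Write a profile as single-base bedGraph intervals."""
    with open(path, "w") as fh:
        for chrom in profile.chroms():
            for pos in sorted(profile.data[chrom]):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{profile.data[chrom][pos]}\n")


# ---------------------------------------------------------------------------
# BED6 of single-nucleotide break ends
# ---------------------------------------------------------------------------

def load_break_bed(
    path: str | Path, genome: GenomeBuild
) -> tuple[StrandProfile, StrandProfile]:
    """Read BED6 single-nucleotide break ends into (positive, negative) profiles.

    Every record must span exactly one base (end == start + 1); the strand
    column routes the count to the corresponding profile. A positive integer
    score is taken as the read count at that position ('.', '0' or a
    non-integer score means one read, the per-read-record convention);
    counts at the same (chrom, position, strand) accumulate.
    """
    pos_profile = StrandProfile(POSITIVE, genome)
    neg_profile = StrandProfile(NEGATIVE, genome)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 record needs 6 columns")
            chrom, start, end, strand = fields[0], int(fields[1]), int(fields[2]), fields[5]
            if end != start + 1:
                raise ParseError(
                    f"{path}:{lineno}: break-end records must be single-nucleotide "
                    f"(end == start+1), got [{start},{end})"
                )
            try:
                count = max(int(fields[4]), 1)
            except ValueError:
                count = 1
            if strand == POSITIVE:
                pos_profile.add(chrom, start, count)
            elif strand == NEGATIVE:
                neg_profile.add(chrom, start, count)
            else:
                raise ParseError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
    return pos_profile, neg_profile


def write_break_bed(
    pos_profile: StrandProfile, neg_profile: StrandProfile, path: str | Path
) -> None:
    """Write both profiles as BED6, one record per (position, strand) with the
    count in the score column."""
    with open(path, "w") as fh:
        for profile in (pos_profile, neg_profile):
            for chrom in profile.chroms():
                for pos in sorted(profile.data[chrom]):
                    fh.write(
                        f"{chrom}\t{pos}\t{pos + 1}\tbreak\t"
                        f"{profile.data[chrom][pos]}\t{profile.strand}\n"
                    )


# ---------------------------------------------------------------------------
# Interval masks (centromeres etc.)
# ---------------------------------------------------------------------------

@dataclass
class MaskSet:
    """Normalized (sorted, merged) genomic intervals to discard."""

    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"mask interval {chrom}:{start}-{end} has start >= end")
        self.intervals = self._normalize(self.intervals)

    @staticmethod
    def _normalize(ivs: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
        out: list[tuple[str, int, int]] = []
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in ivs:
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom in sorted(by_chrom):
            merged: list[tuple[int, int]] = []
            for s, e in sorted(by_chrom[chrom]):
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            out.extend((chrom, s, e) for s, e in merged)
        return out

    def by_chrom(self) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in self.intervals:
            out.setdefault(chrom, []).append((s, e))
        return out


def load_mask_bed(path: str | Path) -> MaskSet:
    """Read mask intervals from a BED file (first three columns used)."""
    ivs: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED record needs >= 3 columns")
            ivs.append((fields[0], int(fields[1]), int(fields[2])))
    return MaskSet(ivs)


def apply_mask(profile: StrandProfile, mask: MaskSet) -> StrandProfile:
    """Return a copy of ``profile`` with every position inside the mask removed."""
    out = profile.copy()
    by_chrom = mask.by_chrom()
    for chrom, intervals in by_chrom.items():
        d = out.data.get(chrom)
        if not d:
            continue
        starts = np.array([s for s, _ in intervals], dtype=np.int64)
        ends = np.array([e for _, e in intervals], dtype=np.int64)
        pos = np.fromiter(d.keys(), dtype=np.int64, count=len(d))
        # intervals are sorted and disjoint: position is masked iff the
        # preceding interval start has end > position
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.maximum(idx, 0)])
        for p in pos[inside].tolist():
            del d[p]
    return out


# ---------------------------------------------------------------------------
# Alignment ingestion (optional path; requires pysam)
# ---------------------------------------------------------------------------

def _passes_break_filters(read, min_mapq: int) -> bool:
    # mirrors samtools -f 67 (paired, proper pair, read 1) and
    # -F 2820 (unmapped, secondary, QC-fail, supplementary) plus -F 1024 (dup)
    return (
        read.is_paired
        and read.is_proper_pair
        and read.is_read1
        and not read.is_unmapped
        and not read.is_secondary
        and not read.is_supplementary
        and not read.is_qcfail
        and not read.is_duplicate
        and read.mapping_quality >= min_mapq
    )


def extract_read1_5prime(
    alignments: str | Path | Iterable,
    genome: GenomeBuild,
    min_mapq: int = 0,
) -> tuple[StrandProfile, StrandProfile]:
    """Accumulate read-1 5' ends of filtered alignments into strand profiles.

    ``alignments`` is a path to a coordinate-sorted alignment file or an
    iterable of pysam aligned segments. Only paired, proper-pair, primary,
    non-supplementary, non-duplicate, QC-pass read-1 records with mapping
    quality >= ``min_mapq`` contribute. The 5' end is the leftmost aligned
    reference base for forward-strand reads and the rightmost aligned base for
    reverse-strand reads (soft-clipped bases excluded).
    """
    pos_profile = StrandProfile(POSITIVE, genome)
    neg_profile = StrandProfile(NEGATIVE, genome)

    if isinstance(alignments, (str, Path)):
        import pysam  # soft dependency: only the alignment path needs it

        handle = pysam.AlignmentFile(str(alignments))
        records: Iterator = iter(handle)
    else:
        records = iter(alignments)

    n_used = 0
    for read in records:
        if not _passes_break_filters(read, min_mapq):
            continue
        chrom = read.reference_name
        if read.is_reverse:
            neg_profile.add(chrom, read.reference_end - 1)
        else:
            pos_profile.add(chrom, read.reference_start)
        n_used += 1
    if n_used == 0:
        warnings.warn("no alignment passed the break-mapping filters; profiles are empty")
    return pos_profile, neg_profile
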