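"""Spike-pair detection and sequence export.

A single cut with a 3' overhang of L nt leaves, after end blunting, a
negative-strand coverage spike L+1 nt upstream of a positive-strand spike —
i.e. a gap of L reference nucleotides between the two single-nucleotide
spikes. Scanning the two strand profiles for such pairs at a fixed gap
identifies the individual loci that generate a given cross-correlation spike
(gap L corresponds to the CNCC spike at shift -1 - L), and their flanking
sequences can be exported as FASTA for external motif discovery.

Note the convention used throughout: "separated by 4 nt" means a 4-nt GAP
(pos_pos = neg_pos + 5), the geometry produced by trim-to-blunt processing of
a 4-nt 3' overhang and consistent with that enzyme's CNCC spike at -5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, TextIO

import numpy as np

from .break_io import StrandProfile

__all__ = ["SpikePair", "find_pairs", "export_pair_fasta", "write_pairs_bed", "read_pairs_bed"]


@dataclass(frozen=True)
class SpikePair:
    """Negative/positive strand spike pair at a fixed separation."""

    chrom: str
    neg_pos: int
    pos_pos: int
    neg_reads: int
    pos_reads: int

    @property
    def gap_nt(self) -> int:
        return self.pos_pos - self.neg_pos - 1


def find_pairs(
    pos: StrandProfile, neg: StrandProfile, gap_nt: int = 4, min_reads: int = 2
) -> list[SpikePair]:
    """All (negative spike at p, positive spike at p + gap_nt + 1) pairs with
    both read counts >= ``min_reads``, genome-wide, sorted by coordinate."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    pairs: list[SpikePair] = []
    for chrom in neg.genome.names:
        yd = neg.data.get(chrom)
        xd = pos.data.get(chrom)
        if not yd or not xd:
            continue
        yp, yc = neg.arrays(chrom)
        xp, xc = pos.arrays(chrom)
        keep = yc >= min_reads
        yp, yc = yp[keep], yc[keep]
        targets = yp + gap_nt + 1
        idx = np.searchsorted(xp, targets)
        idx_c = np.minimum(idx, len(xp) - 1)
        hit = (idx < len(xp)) & (xp[idx_c] == targets) & (xc[idx_c] >= min_reads)
        for p, y, x in zip(yp[hit].tolist(), yc[hit].tolist(), xc[idx_c[hit]].tolist()):
            pairs.append(SpikePair(chrom, p, p + gap_nt + 1, y, x))
    return pairs


def export_pair_fasta(
    pairs: list[SpikePair],
    reference: Mapping[str, str],
    flank_nt: int = 5,
    out: str | Path | TextIO | None = None,
) -> list[tuple[str, str]]:
    """Extract [neg_pos - flank, pos_pos + 1 + flank) for each pair.

    ``reference`` is any mapping from chromosome name to sequence (a
    ``pyfaidx.Fasta`` works directly). Pairs running past a chromosome edge
    are clipped with a warning. Returns (header, sequence) records and, if
    ``out`` is given, also writes them as FASTA.
    """
    records: list[tuple[str, str]] = []
    for pair in pairs:
        try:
            rec = reference[pair.chrom]
        except KeyError:
            raise KeyError(f"reference lacks chromosome {pair.chrom!r}") from None
        length = len(rec)
        start = pair.neg_pos - flank_nt
        end = pair.pos_pos + 1 + flank_nt
        if start < 0 or end > length:
            warnings.warn(
                f"pair at {pair.chrom}:{pair.neg_pos}-{pair.pos_pos} clipped at a "
                "chromosome edge"
            )
            start, end = max(start, 0), min(end, length)
        records.append((f"{pair.chrom}:{start}-{end}", str(rec[start:end])))
    if out is not None:
        handle = open(out, "w") if isinstance(out, (str, Path)) else out
        try:
            for header, seq in records:
                handle.write(f">{header}\n{seq}\n")
        finally:
            if isinstance(out, (str, Path)):
                handle.close()
    return records


def write_pairs_bed(pairs: list[SpikePair], path: str | Path) -> None:
    """BED spanning [neg_pos, pos_pos+1); score = min of the two read counts;
    the two per-strand counts follow as extra columns."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(
                f"{p.chrom}\t{p.neg_pos}\t{p.pos_pos + 1}\tpair\t"
                f"{min(p.neg_reads, p.pos_reads)}\t.\t{p.neg_reads}\t{p.pos_reads}\n"
            )


def read_pairs_bed(path: str | Path) -> list[SpikePair]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            pairs.append(
                SpikePair(f[0], int(f[1]), int(f[2]) - 1, int(f[6]), int(f[7]))
            )
    return pairs
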