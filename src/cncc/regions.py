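"""Genomic region annotation and break density (BPMM).

Five strand-aware region classes partition the genome exactly:

* promoter:  -1000..-250 nt upstream of the transcription start site (TSS)
* TSS:       +/-250 nt around the TSS
* TTS:       +/-250 nt around the transcription termination site
* gene body: +250 nt of the TSS to -250 nt of the TTS
* intergenic: everything else

All intervals are 0-based half-open; overlaps between classes (short genes,
adjacent genes) are resolved by the fixed precedence TSS > promoter > TTS >
gene body, so every position carries exactly one label.

Break density per class is reported as BPMM (breaks per megabase per million
mapped breaks): counts in the class, divided by the class size in Mb, divided
by the library total in millions — invariant to duplicating the dataset.
A rank-based group comparison (Kruskal-Wallis, Dunn post hoc with
Benjamini-Hochberg correction) is provided as a convenience over per-window
densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .break_io import GenomeBuild, StrandProfile

LABELS = ("promoter", "TSS", "TTS", "gene_body", "intergenic")
#: overlap-resolution order (first wins)
PRECEDENCE = ("TSS", "promoter", "TTS", "gene_body")

__all__ = [
    "LABELS",
    "GeneModel",
    "RegionSet",
    "read_genes_tsv",
    "read_genes_gtf",
    "build_regions",
    "break_density_bpmm",
    "window_densities",
    "compare_densities",
    "kruskal_dunn",
]


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene: TSS and TTS in genomic (0-based) coordinates."""

    chrom: str
    strand: str
    tss: int
    tts: int

    def __post_init__(self) -> None:
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError(f"+ strand gene needs TSS < TTS, got {self.tss},{self.tts}")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError(f"- strand gene needs TSS > TTS, got {self.tss},{self.tts}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def read_genes_tsv(path: str | Path) -> list[GeneModel]:
    """Minimal 4-column gene table: chrom, strand, TSS, TTS (0-based)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            chrom, strand, tss, tts = line.split("\t")[:4]
            genes.append(GeneModel(chrom, strand, int(tss), int(tts)))
    return genes


def read_genes_gtf(path: str | Path) -> list[GeneModel]:
    """Gene lines of a GTF (feature == 'gene'); GTF is 1-based inclusive, so
    start-1 is the 0-based left end. For '+' genes TSS = start-1, TTS = end-1;
    for '-' genes TSS = end-1, TTS = start-1."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8 or fields[2] != "gene":
                continue
            chrom, start, end, strand = fields[0], int(fields[3]) - 1, int(fields[4]) - 1, fields[6]
            if strand == "+":
                genes.append(GeneModel(chrom, "+", start, end))
            else:
                genes.append(GeneModel(chrom, "-", end, start))
    return genes


# -- interval arithmetic (sorted, half-open, per chromosome) -----------------

def _merge(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """a minus b; both sorted merged."""
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def _complement(ivs: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    return _subtract([(0, length)], ivs)


@dataclass
class RegionSet:
    """The five-label partition: label -> chrom -> sorted disjoint intervals."""

    genome: GenomeBuild
    intervals: dict[str, dict[str, list[tuple[int, int]]]]

    def total_bp(self) -> dict[str, int]:
        return {
            label: sum(e - s for ivs in per_chrom.values() for s, e in ivs)
            for label, per_chrom in self.intervals.items()
        }

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for label in LABELS:
                for chrom, ivs in self.intervals[label].items():
                    for s, e in ivs:
                        fh.write(f"{chrom}\t{s}\t{e}\t{label}\n")


def build_regions(genes: Sequence[GeneModel], genome: GenomeBuild) -> RegionSet:
    """Partition the genome into the five region classes.

    Region spans are strand-aware mirrors of the '+'-strand definitions;
    genes shorter than 500 nt simply contribute no gene-body interval.
    """
    raw: dict[str, dict[str, list[tuple[int, int]]]] = {
        label: {} for label in PRECEDENCE
    }

    def put(label: str, chrom: str, s: int, e: int) -> None:
        length = genome.length(chrom)
        s, e = max(s, 0), min(e, length)
        if s < e:
            raw[label].setdefault(chrom, []).append((s, e))

    for g in genes:
        if g.chrom not in genome:
            raise KeyError(f"gene on unknown chromosome {g.chrom!r}")
        if g.strand == "+":
            put("promoter", g.chrom, g.tss - 1000, g.tss - 250)
            put("gene_body", g.chrom, g.tss + 250, g.tts - 250)
        else:
            put("promoter", g.chrom, g.tss + 250, g.tss + 1000)
            put("gene_body", g.chrom, g.tts + 250, g.tss - 250)
        put("TSS", g.chrom, g.tss - 250, g.tss + 250)
        put("TTS", g.chrom, g.tts - 250, g.tts + 250)

    final: dict[str, dict[str, list[tuple[int, int]]]] = {l: {} for l in LABELS}
    for chrom in genome.names:
        taken: list[tuple[int, int]] = []
        for label in PRECEDENCE:
            merged = _merge(raw[label].get(chrom, []))
            resolved = _subtract(merged, taken)
            if resolved:
                final[label][chrom] = resolved
            taken = _merge(taken + resolved)
        inter = _complement(taken, genome.length(chrom))
        if inter:
            final["intergenic"][chrom] = inter
    return RegionSet(genome, final)


def _counts_in_intervals(
    pos: StrandProfile, neg: StrandProfile, chrom: str, ivs: list[tuple[int, int]]
) -> np.ndarray:
    """Break counts (both strands summed) per interval."""
    starts = np.array([s for s, _ in ivs], dtype=np.int64)
    ends = np.array([e for _, e in ivs], dtype=np.int64)
    out = np.zeros(len(ivs), dtype=np.int64)
    for profile in (pos, neg):
        p, c = profile.arrays(chrom)
        if len(p) == 0:
            continue
        cum = np.concatenate([[0], np.cumsum(c)])
        lo = np.searchsorted(p, starts, side="left")
        hi = np.searchsorted(p, ends, side="left")
        out += cum[hi] - cum[lo]
    return out


def break_density_bpmm(
    pos: StrandProfile, neg: StrandProfile, regions: RegionSet
) -> dict[str, float]:
    """Breaks per megabase per million mapped breaks, per region class."""
    total = pos.total() + neg.total()
    if total == 0:
        raise ValueError("no breaks in the profiles")
    densities: dict[str, float] = {}
    for label in LABELS:
        bp = 0
        breaks = 0
        for chrom, ivs in regions.intervals.get(label, {}).items():
            bp += sum(e - s for s, e in ivs)
            breaks += int(_counts_in_intervals(pos, neg, chrom, ivs).sum())
        if bp == 0:
            warnings.warn(f"region class {label!r} has zero width; excluded")
            continue
        densities[label] = (breaks / (bp / 1e6)) / (total / 1e6)
    return densities


def window_densities(
    pos: StrandProfile,
    neg: StrandProfile,
    regions: RegionSet,
    window_bp: int = 1000,
) -> dict[str, np.ndarray]:
    """Per-window BPMM observations within each region class.

    Each region interval is tiled with non-overlapping full windows of
    ``window_bp``; partial tails are dropped so all observations share the
    same width (and hence the same sampling variance under uniformity).
    """
    total = pos.total() + neg.total()
    if total == 0:
        raise ValueError("no breaks in the profiles")
    out: dict[str, np.ndarray] = {}
    for label in LABELS:
        vals: list[float] = []
        for chrom, ivs in regions.intervals.get(label, {}).items():
            windows = []
            for s, e in ivs:
                windows.extend(
                    (w, w + window_bp) for w in range(s, e - window_bp + 1, window_bp)
                )
            if not windows:
                continue
            counts = _counts_in_intervals(pos, neg, chrom, windows)
            vals.extend(
                (counts / (window_bp / 1e6)) / (total / 1e6)
            )
        out[label] = np.asarray(vals, dtype=float)
    return out


# -- rank-based group comparison ---------------------------------------------

def kruskal_dunn(groups: Mapping[str, Sequence[float]]) -> dict:
    """Kruskal-Wallis H test plus Dunn's pairwise post hoc with BH correction.

    Returns ``{"H", "p", "dunn"}`` where ``dunn`` is a DataFrame of pairwise
    z statistics and raw/adjusted two-sided p values. Constant data yields
    H = 0, p = 1 without raising.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    samples = [np.asarray(groups[n], dtype=float) for n in names]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least two observations")

    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        dunn = pd.DataFrame(
            [(a, b, 0.0, 1.0, 1.0) for a, b in combinations(names, 2)],
            columns=["group1", "group2", "z", "p", "p_adj"],
        )
        return {"H": 0.0, "p": 1.0, "dunn": dunn}

    H, p = stats.kruskal(*samples)

    ranks = stats.rankdata(pooled)
    N = len(pooled)
    sizes = [len(s) for s in samples]
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(names))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12 * (N - 1))
    var = N * (N + 1) / 12 - tie_term

    rows = []
    for (i, a), (j, b) in combinations(enumerate(names), 2):
        se = np.sqrt(var * (1 / sizes[i] + 1 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        rows.append((a, b, float(z), float(2 * stats.norm.sf(abs(z)))))
    dunn = pd.DataFrame(rows, columns=["group1", "group2", "z", "p"])
    dunn["p_adj"] = stats.false_discovery_control(dunn["p"].to_numpy(), method="bh")
    return {"H": float(H), "p": float(p), "dunn": dunn}


def compare_densities(
    per_region: Mapping[str, Mapping[str, Sequence[float]]]
) -> pd.DataFrame:
    """Run :func:`kruskal_dunn` for every region class.

    ``per_region`` maps region label -> treatment group -> per-window density
    observations. Returns a long-format report with the omnibus test per
    region followed by the pairwise Dunn rows.
    """
    rows = []
    for region, groups in per_region.items():
        res = kruskal_dunn(groups)
        rows.append(
            {"region": region, "test": "kruskal", "group1": "", "group2": "",
             "stat": res["H"], "p": res["p"], "p_adj": np.nan}
        )
        for r in res["dunn"].itertuples(index=False):
            rows.append(
                {"region": region, "test": "dunn", "group1": r.group1,
                 "group2": r.group2, "stat": r.z, "p": r.p, "p_adj": r.p_adj}
            )
    return pd.DataFrame(rows)
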