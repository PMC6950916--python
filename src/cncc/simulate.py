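"""Synthetic break-mapping data with known ground truth.

The generator emulates the post-alignment input domain of the method: the
single-nucleotide 5'-end positions of read 1 on each strand. A restriction
cut at position p (with the blunting chemistry's trim/fill-in processing)
emits a negative-strand 5' end at p and a positive-strand 5' end at

* p + 1      for a blunt cut,
* p + 1 + L  for a 3' overhang of L nt (trimmed ends separate),
* p + 1 - L  for a 5' overhang of L nt (filled-in ends overlap).

Per-site read depth is heterogeneous by default: each site draws a log-normal
"strength" (median-preserving, sigma ``site_strength_sigma``) around the mean
``reads_per_end`` and each end then draws a Poisson count from it, mimicking
the strong over-dispersion and the within-site correlation of the two ends'
depths seen in real digests. ``site_strength_sigma=0`` gives exactly equal
integer counts at every end, the regime used for linearity checks. A uniform
background emits single reads at random positions and strands.

Read-level details (sequences, qualities, aligner behavior) are out of scope:
the method consumes 5'-end coverage, which is what is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .break_io import NEGATIVE, POSITIVE, GenomeBuild, StrandProfile
from .core import BLUNT, FIVE_PRIME, THREE_PRIME, EndStructureCall

__all__ = [
    "SimConfig",
    "simulate_digest",
    "simulate_resection",
    "simulate_minor_species",
    "profiles_from_truth",
]

TRUTH_COLUMNS = [
    "chrom",
    "cut_pos",
    "kind",
    "overhang",
    "neg_end",
    "pos_end",
    "neg_reads",
    "pos_reads",
    "captured",
    "skipped",
    "species",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated break species.

    Either explicit ``site_positions`` or a count ``n_sites`` of random cut
    sites may be given; ``overhang_lengths`` (with optional ``overhang_probs``)
    switches a 3'-overhang species into resection mode where each site draws
    its own length.
    """

    genome: GenomeBuild
    n_sites: int = 0
    site_positions: tuple[tuple[str, int], ...] | None = None
    end_structure: EndStructureCall = field(default_factory=lambda: EndStructureCall(BLUNT))
    overhang_lengths: tuple[int, ...] | None = None
    overhang_probs: tuple[float, ...] | None = None
    reads_per_end: float = 10.0
    site_strength_sigma: float = 1.25
    capture_efficiency: float = 1.0
    background_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.site_positions) if self.site_positions is not None else self.n_sites
        if n == 0 and self.background_rate <= 0:
            raise ValueError("need at least one cut site or a positive background rate")
        if not 0 < self.capture_efficiency <= 1:
            raise ValueError("capture_efficiency must be in (0, 1]")
        if self.reads_per_end <= 0:
            raise ValueError("reads_per_end must be positive")
        if self.site_strength_sigma < 0:
            raise ValueError("site_strength_sigma must be >= 0")
        if self.overhang_lengths is not None:
            if any(L < 1 for L in self.overhang_lengths):
                raise ValueError("resection overhang lengths must be positive")
            if self.overhang_probs is not None and len(self.overhang_probs) != len(
                self.overhang_lengths
            ):
                raise ValueError("overhang_probs must match overhang_lengths")


def _end_positions(cut_pos: int, kind: str, L: int) -> tuple[int, int]:
    neg_end = cut_pos
    if kind == BLUNT:
        return neg_end, cut_pos + 1
    if kind == THREE_PRIME:
        return neg_end, cut_pos + 1 + L
    return neg_end, cut_pos + 1 - L


def _random_sites(
    cfg: SimConfig, rng: np.random.Generator, margin: int
) -> list[tuple[str, int]]:
    """Distinct random cut positions, chromosomes weighted by length."""
    genome = cfg.genome
    lengths = np.array([genome.length(c) for c in genome.names], dtype=float)
    probs = lengths / lengths.sum()
    sites: set[tuple[str, int]] = set()
    while len(sites) < cfg.n_sites:
        need = cfg.n_sites - len(sites)
        chosen = rng.choice(len(lengths), size=need, p=probs)
        for ci in chosen.tolist():
            chrom = genome.names[ci]
            lo, hi = margin, genome.length(chrom) - margin
            if hi <= lo:
                raise ValueError(f"chromosome {chrom} too short for the cut geometry")
            sites.add((chrom, int(rng.integers(lo, hi))))
    return sorted(sites)


def _emit_reads(
    cfg: SimConfig, rng: np.random.Generator, n_sites: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site read counts for each end (negative, positive)."""
    if cfg.site_strength_sigma == 0:
        fixed = int(round(cfg.reads_per_end))
        return (
            np.full(n_sites, fixed, dtype=np.int64),
            np.full(n_sites, fixed, dtype=np.int64),
        )
    sigma = cfg.site_strength_sigma
    strength = cfg.reads_per_end * rng.lognormal(-0.5 * sigma**2, sigma, size=n_sites)
    return rng.poisson(strength), rng.poisson(strength)


def _add_background(
    cfg: SimConfig,
    rng: np.random.Generator,
    pos_profile: StrandProfile,
    neg_profile: StrandProfile,
) -> int:
    if cfg.background_rate <= 0:
        return 0
    genome = cfg.genome
    n_bg = int(rng.poisson(cfg.background_rate * genome.total_length))
    if n_bg == 0:
        return 0
    lengths = np.array([genome.length(c) for c in genome.names], dtype=float)
    chrom_idx = rng.choice(len(lengths), size=n_bg, p=lengths / lengths.sum())
    offsets = rng.random(n_bg)
    strands = rng.integers(0, 2, size=n_bg)
    for ci, u, s in zip(chrom_idx.tolist(), offsets.tolist(), strands.tolist()):
        chrom = genome.names[ci]
        p = int(u * genome.length(chrom))
        (pos_profile if s else neg_profile).add(chrom, p)
    return n_bg


def simulate_digest(
    cfg: SimConfig, species: str = "digest"
) -> tuple[StrandProfile, StrandProfile, pd.DataFrame]:
    """Simulate a digest with a single end structure (or per-site overhangs).

    Returns (positive profile, negative profile, truth table). Sites whose
    geometry would fall outside the chromosome are skipped with a row in the
    truth table marking ``skipped``. Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    genome = cfg.genome
    max_L = (
        max(cfg.overhang_lengths)
        if cfg.overhang_lengths is not None
        else cfg.end_structure.overhang_len
    )
    margin = max_L + 2

    if cfg.site_positions is not None:
        sites = list(cfg.site_positions)
    else:
        sites = _random_sites(cfg, rng, margin)

    n = len(sites)
    if cfg.overhang_lengths is not None:
        lengths = rng.choice(
            np.asarray(cfg.overhang_lengths, dtype=np.int64),
            size=n,
            p=cfg.overhang_probs,
        )
        kinds = [THREE_PRIME] * n
    else:
        lengths = np.full(n, cfg.end_structure.overhang_len, dtype=np.int64)
        kinds = [cfg.end_structure.kind] * n

    captured = rng.random(n) < cfg.capture_efficiency
    neg_reads, pos_reads = _emit_reads(cfg, rng, n)

    pos_profile = StrandProfile(POSITIVE, genome)
    neg_profile = StrandProfile(NEGATIVE, genome)
    rows: list[tuple] = []
    for i, (chrom, cut_pos) in enumerate(sites):
        L = int(lengths[i])
        neg_end, pos_end = _end_positions(cut_pos, kinds[i], L)
        length = genome.length(chrom)
        skipped = not (0 <= neg_end < length and 0 <= pos_end < length)
        nr = pr = 0
        if skipped:
            import warnings

            warnings.warn(
                f"site {chrom}:{cut_pos} too close to a chromosome edge for its "
                "geometry; skipped"
            )
        elif captured[i]:
            nr, pr = int(neg_reads[i]), int(pos_reads[i])
            if nr > 0:
                neg_profile.add(chrom, neg_end, nr)
            if pr > 0:
                pos_profile.add(chrom, pos_end, pr)
        rows.append(
            (chrom, cut_pos, kinds[i], L, neg_end, pos_end, nr, pr,
             bool(captured[i]) and not skipped, skipped, species)
        )

    _add_background(cfg, rng, pos_profile, neg_profile)
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return pos_profile, neg_profile, truth


def simulate_resection(
    cfg: SimConfig, species: str = "resection"
) -> tuple[StrandProfile, StrandProfile, pd.DataFrame]:
    """Simulate 3'-overhang breaks whose lengths are drawn per site from the
    configured overhang-length distribution (resection gradient)."""
    if cfg.overhang_lengths is None:
        raise ValueError("resection mode needs cfg.overhang_lengths")
    return simulate_digest(cfg, species=species)


def simulate_minor_species(
    major_cfg: SimConfig, minor_cfg: SimConfig, minor_fraction: float
) -> tuple[StrandProfile, StrandProfile, pd.DataFrame]:
    """Mixture where the minor species contributes ~``minor_fraction`` of reads.

    The major component is simulated as configured; the minor component's mean
    reads per end is rescaled so its expected read total is
    ``minor_fraction / (1 - minor_fraction)`` times the realized major total.
    The truth table distinguishes the two species. The achieved fraction is
    approximate (read emission is stochastic unless sigma = 0).
    """
    if not 0 < minor_fraction < 1:
        raise ValueError("minor_fraction must be in (0, 1)")
    pos_M, neg_M, truth_M = simulate_digest(major_cfg, species="major")
    total_major = pos_M.total() + neg_M.total()
    n_minor = (
        len(minor_cfg.site_positions)
        if minor_cfg.site_positions is not None
        else minor_cfg.n_sites
    )
    if n_minor == 0:
        raise ValueError("minor species needs cut sites")
    target = total_major * minor_fraction / (1 - minor_fraction)
    per_end = target / (2 * n_minor * minor_cfg.capture_efficiency)
    minor_cfg = replace(minor_cfg, reads_per_end=per_end)
    pos_m, neg_m, truth_m = simulate_digest(minor_cfg, species="minor")
    pos_profile = pos_M.merged_with(pos_m)
    neg_profile = neg_M.merged_with(neg_m)
    truth = pd.concat([truth_M, truth_m], ignore_index=True)
    return pos_profile, neg_profile, truth


def profiles_from_truth(
    truth: pd.DataFrame, genome: GenomeBuild
) -> tuple[StrandProfile, StrandProfile]:
    """Rebuild the site-emitted profiles from a truth table (background
    breaks are not part of the truth and are excluded by construction)."""
    pos_profile = StrandProfile(POSITIVE, genome)
    neg_profile = StrandProfile(NEGATIVE, genome)
    for row in truth.itertuples(index=False):
        if row.skipped or not row.captured:
            continue
        if row.neg_reads > 0:
            neg_profile.add(row.chrom, int(row.neg_end), int(row.neg_reads))
        if row.pos_reads > 0:
            pos_profile.add(row.chrom, int(row.pos_end), int(row.pos_reads))
    return pos_profile, neg_profile
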