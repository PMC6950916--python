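"""Coverage-normalized cross correlation (CNCC) and end-structure decoding.

The statistic is a cross correlation between break-end coverage on the
negative strand, y(i), and on the positive strand, x(i), over a range of
integer shifts t, normalized once by total break coverage::

    CNCC(t) = sum_i y(i) x(i - t) / sqrt(sum_i x(i)^2 * sum_i y(i)^2)

The library's blunting chemistry encodes end structure into the relative
positions of the two mapped break ends: 3' overhangs are trimmed (the two
blunted ends separate in reference coordinates), 5' overhangs are filled in
(the ends overlap). A break whose negative-strand end sits at p and
positive-strand end at p + 1 + L therefore concentrates cross-correlation
signal at shift t = -1 - L; the characteristic shifts are -1 for blunt ends,
-1 - L for a 3' overhang of L nt, and -1 + L for a 5' overhang of L nt.

The numerator is accumulated per chromosome (cross-chromosome products never
occur); the denominator uses the genome-wide sums of squares, so the curve is
independent of chromosome order and invariant to scaling all counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .break_io import StrandProfile

BLUNT = "blunt"
THREE_PRIME = "three_prime_overhang"
FIVE_PRIME = "five_prime_overhang"

__all__ = [
    "BLUNT",
    "THREE_PRIME",
    "FIVE_PRIME",
    "ShiftRange",
    "CNCCCurve",
    "EndStructureCall",
    "ResectionSignature",
    "compute_cncc",
    "shift_to_structure",
    "structure_to_shift",
    "dominant_shifts",
    "resection_range",
]


@dataclass(frozen=True)
class ShiftRange:
    """Inclusive range of integer shifts to evaluate."""

    min_shift: int
    max_shift: int

    def __post_init__(self) -> None:
        if self.min_shift > self.max_shift:
            raise ValueError("min_shift must be <= max_shift")

    def shifts(self) -> np.ndarray:
        return np.arange(self.min_shift, self.max_shift + 1, dtype=np.int64)

    def __contains__(self, t: int) -> bool:
        return self.min_shift <= t <= self.max_shift

    def __len__(self) -> int:
        return self.max_shift - self.min_shift + 1


#: default window for genome-wide scans (broad enough for long resection tails)
DEFAULT_SHIFT_RANGE = ShiftRange(-1000, 1000)
#: default window for single-enzyme digests
ENZYME_SHIFT_RANGE = ShiftRange(-50, 50)


@dataclass
class CNCCCurve:
    """CNCC values over an ordered shift grid, with the normalization terms."""

    shifts: np.ndarray
    values: np.ndarray
    total_pos_sq: float
    total_neg_sq: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.shifts.shape != self.values.shape:
            raise ValueError("shifts and values must have the same shape")

    def value_at(self, t: int) -> float:
        idx = np.searchsorted(self.shifts, t)
        if idx >= len(self.shifts) or self.shifts[idx] != t:
            raise KeyError(f"shift {t} not in curve range")
        return float(self.values[idx])

    def argmax_shift(self) -> int:
        """Shift of the maximal value; ties break toward the smallest |shift|,
        then toward the more positive shift, deterministically."""
        vmax = self.values.max()
        candidates = self.shifts[self.values == vmax]
        return int(min(candidates.tolist(), key=lambda t: (abs(t), -t)))

    def same_grid(self, other: "CNCCCurve") -> bool:
        return np.array_equal(self.shifts, other.shifts)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# total_pos_sq={self.total_pos_sq!r}\n")
            fh.write(f"# total_neg_sq={self.total_neg_sq!r}\n")
            for k, v in sorted(self.meta.items()):
                fh.write(f"# {k}={v!r}\n")
            fh.write("shift\tcncc\n")
            for t, v in zip(self.shifts.tolist(), self.values.tolist()):
                fh.write(f"{t}\t{v:.12g}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CNCCCurve":
        shifts: list[int] = []
        values: list[float] = []
        header: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    header[key.strip()] = val
                    continue
                if not line or line.startswith("shift\t"):
                    continue
                t, v = line.split("\t")
                shifts.append(int(t))
                values.append(float(v))
        meta = {
            k: v.strip("'\"")
            for k, v in header.items()
            if k not in ("total_pos_sq", "total_neg_sq")
        }
        return cls(
            np.array(shifts),
            np.array(values),
            float(header.pop("total_pos_sq", "nan")),
            float(header.pop("total_neg_sq", "nan")),
            meta=meta,
        )


@dataclass(frozen=True)
class EndStructureCall:
    """Decoded break end type with overhang length in nucleotides."""

    kind: str
    overhang_len: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (BLUNT, THREE_PRIME, FIVE_PRIME):
            raise ValueError(f"unknown end-structure kind {self.kind!r}")
        if self.kind == BLUNT and self.overhang_len != 0:
            raise ValueError("blunt ends have overhang_len 0")
        if self.kind != BLUNT and self.overhang_len < 1:
            raise ValueError("overhangs need overhang_len >= 1")


def shift_to_structure(t: int) -> EndStructureCall:
    """Decode a characteristic shift into an end-structure call.

    -1 is blunt; shifts below -1 are 3' overhangs of length -1 - t (trimmed
    ends separate); shifts above -1 are 5' overhangs of length t + 1
    (filled-in ends overlap).
    """
    if t == -1:
        return EndStructureCall(BLUNT, 0)
    if t < -1:
        return EndStructureCall(THREE_PRIME, -1 - t)
    return EndStructureCall(FIVE_PRIME, t + 1)


def structure_to_shift(call: EndStructureCall) -> int:
    """Exact inverse of :func:`shift_to_structure`."""
    if call.kind == BLUNT:
        return -1
    if call.kind == THREE_PRIME:
        return -1 - call.overhang_len
    return -1 + call.overhang_len


def compute_cncc(
    pos: StrandProfile, neg: StrandProfile, shift_range: ShiftRange = DEFAULT_SHIFT_RANGE
) -> CNCCCurve:
    """Compute the coverage-normalized cross correlation over a shift range.

    For each shift t the numerator sums y(i) * x(i - t) within each
    chromosome; the denominator is the global sqrt(sum x^2 * sum y^2). Sparse
    evaluation over stored positions gives results identical to a dense
    genome-length computation.
    """
    if pos.is_empty() or neg.is_empty():
        raise ValueError("undefined normalization: both strand profiles must be non-empty")
    sum_x2 = pos.sum_sq()
    sum_y2 = neg.sum_sq()
    shifts = shift_range.shifts()
    num = np.zeros(len(shifts), dtype=float)
    for chrom in pos.chroms():
        if chrom not in neg.data or not neg.data[chrom] or not pos.data[chrom]:
            continue
        xp, xc = pos.arrays(chrom)
        yp, yc = neg.arrays(chrom)
        for k, t in enumerate(shifts.tolist()):
            targets = yp - t
            idx = np.searchsorted(xp, targets)
            idx_c = np.minimum(idx, len(xp) - 1)
            hit = (idx < len(xp)) & (xp[idx_c] == targets)
            if hit.any():
                num[k] += float(np.dot(yc[hit], xc[idx_c[hit]]))
    values = num / np.sqrt(sum_x2 * sum_y2)
    return CNCCCurve(shifts, values, sum_x2, sum_y2)


def dominant_shifts(
    curve: CNCCCurve, k: int = 5, min_prominence: float = 0.0
) -> list[tuple[int, float]]:
    """Top-k local maxima of the curve by value, requiring the given peak
    prominence; returns (shift, value) pairs sorted by descending value.

    A flat curve has no local maxima and yields an empty list; shifts at the
    extreme ends of the evaluated range are not considered peaks.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    peaks, props = find_peaks(curve.values, prominence=max(min_prominence, 0.0) or None)
    if min_prominence > 0:
        peaks = peaks[props["prominences"] >= min_prominence]
    ranked = sorted(peaks.tolist(), key=lambda i: -curve.values[i])[:k]
    return [(int(curve.shifts[i]), float(curve.values[i])) for i in ranked]


@dataclass
class ResectionSignature:
    """The 90%-of-maximum CNCC band within the resection search window.

    Resection (5'->3' nucleolytic degradation) produces 3' overhangs of
    heterogeneous length, which spread CNCC signal over shifts below -1. The
    signature is the maximal contiguous run of shifts, containing the curve's
    argmax in the window, whose values all reach ``threshold_frac`` of the
    window maximum; re-expressed as overhang lengths it brackets the most
    common resection tract lengths.
    """

    window: ShiftRange
    peak_value: float
    peak_shift: int
    range_lo: int
    range_hi: int
    threshold_frac: float

    @property
    def min_overhang(self) -> int:
        return shift_to_structure(self.range_hi).overhang_len

    @property
    def max_overhang(self) -> int:
        return shift_to_structure(self.range_lo).overhang_len


#: default resection search window: 3' overhangs of 1..200 nt
RESECTION_WINDOW = ShiftRange(-201, -2)


def resection_range(
    curve: CNCCCurve,
    window: ShiftRange = RESECTION_WINDOW,
    threshold_frac: float = 0.90,
) -> ResectionSignature:
    """Locate the resection signature band in a CNCC curve."""
    if window.max_shift >= -1:
        raise ValueError("resection window must lie entirely below shift -1")
    if not 0 < threshold_frac <= 1:
        raise ValueError("threshold_frac must be in (0, 1]")
    if window.min_shift not in curve.shifts or window.max_shift not in curve.shifts:
        raise ValueError("resection window outside the curve's shift range")
    sel = (curve.shifts >= window.min_shift) & (curve.shifts <= window.max_shift)
    shifts = curve.shifts[sel]
    vals = curve.values[sel]
    peak_value = float(vals.max())
    peak_candidates = shifts[vals == peak_value]
    peak_shift = int(min(peak_candidates.tolist(), key=lambda t: (abs(t), -t)))
    thr = threshold_frac * peak_value
    ok = vals >= thr
    i = int(np.searchsorted(shifts, peak_shift))
    lo = i
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = i
    while hi + 1 < len(shifts) and ok[hi + 1]:
        hi += 1
    return ResectionSignature(
        window=window,
        peak_value=peak_value,
        peak_shift=peak_shift,
        range_lo=int(shifts[lo]),
        range_hi=int(shifts[hi]),
        threshold_frac=threshold_frac,
    )
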