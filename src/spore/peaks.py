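"""Peak calling on normalized density curves and Δ-tolerant peak matching.

A peak is a local maximum that rises at least ε (default 1 normalized density
unit) above its nearest flanking local minima on *both* sides; chromosome
ends count as minima, so a maximum at the very end of a chromosome cannot be
called. Plateau maxima (equal consecutive samples) report their center
sample.

Matching of predicted against reference peaks is independent per peak, not
one-to-one: a reference peak is recovered if any predicted peak lies within
±Δ of it (sensitivity), and a predicted peak is confirmed if any reference
peak lies within ±Δ (PPV).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .curves import DensityCurve


@dataclass
class PeakList:
    chrom: str
    positions: np.ndarray
    heights: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if len(self.positions) != len(self.heights):
            raise ValueError("one height per position required")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("peak positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class MatchReport:
    delta: float
    n_predicted: int
    n_reference: int
    sensitivity: float  # NaN when undefined (no reference peaks)
    ppv: float          # NaN when undefined (no predicted peaks)


def _runs(values: np.ndarray):
    """Compress equal consecutive samples into (start_idx, end_idx, value) runs."""
    change = np.flatnonzero(np.diff(values) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(values)]))
    return starts, ends, values[starts]


def find_peaks(curve: DensityCurve, epsilon: float = 1.0,
               check_normalized: bool = True) -> PeakList:
    """ε-prominent local maxima of a normalized curve.

    The flanking minimum on each side of a candidate maximum is the lowest
    value between it and the adjacent local maximum (or the chromosome end);
    the candidate is kept iff it exceeds both by at least ε.
    """
    v = curve.values
    if check_normalized and len(v) >= 100:
        p99 = np.percentile(v, 99)
        if not (50.0 < p99 < 150.0):
            warnings.warn("curve does not look normalized (p99 far from 99); "
                          "ε is defined in normalized density units",
                          stacklevel=2)
    if len(v) < 3:
        return PeakList(curve.chrom, np.array([]), np.array([]))
    starts, ends, rv = _runs(v)
    n = len(rv)
    # interior runs strictly above both neighbours are candidate maxima
    max_runs = [i for i in range(1, n - 1) if rv[i] > rv[i - 1] and rv[i] > rv[i + 1]]
    pos, hgt = [], []
    for k, i in enumerate(max_runs):
        left_lo = rv[(max_runs[k - 1] if k else 0):i].min() if i > 0 else rv[i]
        right_hi = max_runs[k + 1] + 1 if k + 1 < len(max_runs) else n
        right_lo = rv[i + 1:right_hi].min()
        if rv[i] - left_lo >= epsilon and rv[i] - right_lo >= epsilon:
            mid = (starts[i] + ends[i] - 1) // 2  # plateau center sample
            pos.append(curve.start + mid * curve.step)
            hgt.append(rv[i])
    return PeakList(curve.chrom, np.array(pos, dtype=float),
                    np.array(hgt, dtype=float))


def find_peaks_genome(curves: Mapping[str, DensityCurve],
                      epsilon: float = 1.0,
                      check_normalized: bool = True) -> dict[str, PeakList]:
    return {c: find_peaks(cv, epsilon, check_normalized)
            for c, cv in curves.items()}


def _count_matched(query: np.ndarray, target: np.ndarray, delta: float) -> int:
    """Number of query positions with at least one target within ±delta."""
    if len(query) == 0 or len(target) == 0:
        return 0
    idx = np.searchsorted(target, query)
    left = np.abs(query - target[np.clip(idx - 1, 0, len(target) - 1)])
    right = np.abs(query - target[np.clip(idx, 0, len(target) - 1)])
    return int(np.sum(np.minimum(left, right) <= delta))


def match_peaks(predicted, reference, delta: float) -> MatchReport:
    """PPV and sensitivity of predicted vs reference peaks at tolerance Δ.

    Accepts :class:`PeakList` objects or ``{chrom: PeakList}`` dicts; counts
    are pooled over chromosomes.
    """
    if isinstance(predicted, PeakList):
        predicted = {predicted.chrom: predicted}
    if isinstance(reference, PeakList):
        reference = {reference.chrom: reference}
    n_pred = sum(len(p) for p in predicted.values())
    n_ref = sum(len(r) for r in reference.values())
    tp_ref = 0  # reference peaks recovered
    tp_pred = 0  # predicted peaks confirmed
    for chrom in set(predicted) | set(reference):
        p = predicted.get(chrom)
        r = reference.get(chrom)
        ppos = p.positions if p is not None else np.array([])
        rpos = r.positions if r is not None else np.array([])
        tp_ref += _count_matched(rpos, ppos, delta)
        tp_pred += _count_matched(ppos, rpos, delta)
    sens = tp_ref / n_ref if n_ref else math.nan
    ppv = tp_pred / n_pred if n_pred else math.nan
    if n_pred == 0 and n_ref > 0:
        sens = 0.0
    return MatchReport(delta, n_pred, n_ref, sens, ppv)


def ppv_sensitivity_sweep(predicted, reference,
                          deltas: Sequence[float]) -> list[MatchReport]:
    """PPV/sensitivity at each Δ; both are nondecreasing in Δ."""
    return [match_peaks(predicted, reference, d) for d in deltas]


def peaks_to_bed(peaks: Mapping[str, PeakList], half_width: int = 0):
    """BED rows (chrom, start, end, name, score) centered on each peak."""
    rows = []
    for chrom, pl in peaks.items():
        for i, (p, h) in enumerate(zip(pl.positions, pl.heights)):
            rows.append((chrom, int(p) - half_width, int(p) + half_width + 1,
                         f"{chrom}_peak{i}", float(h)))
    return rows
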