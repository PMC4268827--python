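"""Hot/cold classification of genomic intervals from a model density curve.

Three classification rules mirror the benchmarking procedures in the field:

- interval rule: a fragment is a hotspot iff the mean of the model curve over
  it exceeds (strictly) the genome-wide curve mean;
- ORF-upstream rule: a gene is a hotspot iff the curve mean over the
  intergenic region upstream of its start is ≥ μ + σ of the curve;
- GC-only rule: a gene is a hotspot iff the maximum of the smoothed GC curve
  over the gene body plus its upstream region is ≥ μ_GC + σ_GC (an
  alternative fixed 4 kb window centered on the gene start is provided as a
  cross-check).

Matched coldspots are drawn by seeded rejection sampling: same chromosome and
length as each hotspot, at most ``max_reads`` of signal inside, mutually
disjoint. ROC curves over interval scores use all thresholds; AUC by the
trapezoid rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

from .curves import DensityCurve, GenomeStats
from .genome_io import GeneRecord, GeneSet, IntergenicRegion, upstream_region_of

HOT, COLD = "hot", "cold"


@dataclass
class LabeledInterval:
    chrom: str
    start: int
    end: int
    label: str
    score: float
    name: str = ""
    flagged: bool = False  # degenerate input (e.g. zero-length upstream region)


@dataclass
class RocReport:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def score_interval(curve: DensityCurve, start: int, end: int) -> float:
    """Mean of the curve samples with position in [start, end)."""
    if end <= start:
        raise ValueError(f"empty interval [{start}, {end})")
    if start < curve.start or end > curve.end:
        raise ValueError(f"interval [{start}, {end}) outside curve coverage "
                         f"[{curve.start}, {curve.end})")
    vals = curve.slice(start, end)
    if vals.size == 0:  # interval narrower than the grid step
        vals = curve.values[curve.index_of(start):curve.index_of(start) + 1]
    return float(vals.mean())


def classify_intervals(curves: Mapping[str, DensityCurve],
                       intervals: Sequence[tuple],
                       genome_mean: float | None = None) -> list[LabeledInterval]:
    """Hot iff the interval's mean curve value strictly exceeds the
    genome-wide mean of the same curve."""
    if genome_mean is None:
        genome_mean = float(np.mean(np.concatenate(
            [c.values for c in curves.values()])))
    out = []
    for iv in intervals:
        chrom, start, end = iv[0], int(iv[1]), int(iv[2])
        name = iv[3] if len(iv) > 3 else ""
        s = score_interval(curves[chrom], start, end)
        out.append(LabeledInterval(chrom, start, end,
                                   HOT if s > genome_mean else COLD, s, name))
    return out


def classify_orf_upstream(curves: Mapping[str, DensityCurve], genes: GeneSet,
                          regions: Sequence[IntergenicRegion]
                          ) -> list[LabeledInterval]:
    """Per gene: score = curve mean over the upstream intergenic region; hot
    iff score ≥ μ + σ of the curve genome-wide. Genes with a zero-length
    upstream region are labeled cold with score 0 and flagged."""
    pooled = np.concatenate([c.values for c in curves.values()])
    thresh = float(pooled.mean() + pooled.std())
    out = []
    for g in genes.records:
        r = upstream_region_of(g, regions)
        if r is None or r.length == 0:
            out.append(LabeledInterval(g.chrom, g.start, g.start, COLD, 0.0,
                                       g.id, flagged=True))
            continue
        s = score_interval(curves[g.chrom], r.start, r.end)
        out.append(LabeledInterval(g.chrom, r.start, r.end,
                                   HOT if s >= thresh else COLD, s, g.id))
    return out


def gc_orf_predictor(gc: Mapping[str, DensityCurve], genes: GeneSet,
                     regions: Sequence[IntergenicRegion],
                     stats: GenomeStats | None = None,
                     mode: str = "upstream_union_gene",
                     window: int = 4000) -> list[LabeledInterval]:
    """GC-only recombination-hotspot predictor.

    ``upstream_union_gene``: hot iff max of the smoothed GC curve over the
    gene body plus its upstream intergenic region is ≥ μ_GC + σ_GC.
    ``start_window``: hot iff the GC curve mean in a fixed window centered on
    the gene start exceeds the same threshold (cross-check mode).
    """
    if stats is None:
        pooled = np.concatenate([c.values for c in gc.values()])
        mu, sd = float(pooled.mean()), float(pooled.std())
    else:
        mu, sd = stats.mu_gc, stats.sigma_gc
    thresh = mu + sd
    out = []
    for g in genes.records:
        c = gc[g.chrom]
        if mode == "upstream_union_gene":
            r = upstream_region_of(g, regions)
            lo, hi = g.start, g.end
            if r is not None and r.length > 0:
                lo, hi = min(lo, r.start), max(hi, r.end)
            vals = c.slice(lo, hi)
            s = float(vals.max()) if vals.size else float(c.values[c.index_of(lo)])
        elif mode == "start_window":
            lo = max(c.start, g.start_codon - window // 2)
            hi = min(c.end, g.start_codon + window // 2)
            s = float(c.slice(lo, hi).mean())
        else:
            raise ValueError(f"unknown mode {mode!r}")
        out.append(LabeledInterval(g.chrom, g.start, g.end,
                                   HOT if s >= thresh else COLD, s, g.id))
    return out


class SaturationError(RuntimeError):
    """Rejection sampling could not place a coldspot."""


def sample_coldspots(hotspots: Sequence[tuple],
                     exclusion: Mapping[str, DensityCurve],
                     max_reads: float = 0, seed: int = 0,
                     max_attempts: int = 10_000) -> list[tuple[str, int, int]]:
    """One coldspot per hotspot: same chromosome and length, total exclusion
    signal ≤ ``max_reads`` inside it, mutually non-overlapping. Seeded
    rejection sampling; raises :class:`SaturationError` after
    ``max_attempts`` failed draws for a fragment."""
    rng = np.random.default_rng(seed)
    taken: dict[str, list[tuple[int, int]]] = {}
    out: list[tuple[str, int, int]] = []
    for hs in hotspots:
        chrom, start, end = hs[0], int(hs[1]), int(hs[2])
        length = end - start
        track = exclusion[chrom]
        limit = track.end - length
        if limit <= track.start:
            raise SaturationError(f"chromosome {chrom}: no room for a "
                                  f"{length} nt coldspot")
        for _ in range(max_attempts):
            s = int(rng.integers(track.start, limit))
            e = s + length
            if any(s < te and e > ts for ts, te in taken.get(chrom, [])):
                continue
            if float(track.slice(s, e).sum()) <= max_reads:
                taken.setdefault(chrom, []).append((s, e))
                out.append((chrom, s, e))
                break
        else:
            raise SaturationError(
                f"chromosome {chrom}: could not place a {length} nt coldspot "
                f"after {max_attempts} attempts")
    return out


def success_rate(predicted: Sequence[str], truth: Sequence[str]
                 ) -> tuple[float, float, float]:
    """(overall accuracy, TPR, FPR) of hot/cold label vectors."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth label lists differ in length")
    pred = np.asarray(predicted)
    tru = np.asarray(truth)
    overall = float(np.mean(pred == tru))
    pos = tru == HOT
    neg = ~pos
    tpr = float(np.mean(pred[pos] == HOT)) if pos.any() else float("nan")
    fpr = float(np.mean(pred[neg] == HOT)) if neg.any() else float("nan")
    return overall, tpr, fpr


def roc_sweep(scores: Sequence[float], truth: Sequence[str]) -> RocReport:
    """ROC over all score thresholds; AUC by the trapezoid rule."""
    y = np.asarray([1 if t == HOT else 0 for t in truth])
    if y.min() == y.max():
        raise ValueError("ROC needs at least one hot and one cold label")
    fpr, tpr, thr = _roc_curve(y, np.asarray(scores, dtype=float))
    return RocReport(fpr, tpr, thr, float(_auc(fpr, tpr)))
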