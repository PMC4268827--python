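"""Model-vs-experiment evaluation: windowed and global correlations, random
position baselines, ablation-table reports, and anchor-centered profiles.

Local correlation slides a 50 kb window along each chromosome in steps of 10%
of the window, computes Pearson or Spearman on co-sampled points (every 10 nt
by default), and averages the per-window coefficients, unweighted, over all
windows of all chromosomes. Windows with zero variance in either curve are
skipped and counted. Global correlation pools the whole genome into one
coefficient.

The random baseline scores, against a reference peak set, peak lists drawn
uniformly at random (over the whole genome or over intergenic regions only),
summarizing the PPV/sensitivity null over many simulations by its best, mean
and 95th percentile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .curves import DensityCurve, KernelSpec, gaussian_smooth
from .genome_io import IntergenicRegion
from .peaks import PeakList, match_peaks


@dataclass
class CorrelationReport:
    method: str
    scope: str  # "local" | "global"
    value: float
    n_windows: int = 1
    window: float = 0.0
    step_fraction: float = 0.0
    sample_step: int = 10
    n_skipped: int = 0


@dataclass
class RandomBaselineReport:
    n_sims: int
    n_positions: int
    domain: str
    best_ppv: float
    best_sens: float
    mean_ppv: float
    mean_sens: float
    p05_ppv: float   # 95th percentile of the null (p-value 5% level)
    p05_sens: float


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def _cosample(a: DensityCurve, b: DensityCurve, sample_step: int):
    if a.step != b.step or a.start != b.start:
        raise ValueError("curves must share grid start and step")
    k = max(1, int(round(sample_step / a.step)))
    n = min(len(a), len(b))
    return a.values[:n:k], b.values[:n:k], k


def local_correlation(a: Mapping[str, DensityCurve] | DensityCurve,
                      b: Mapping[str, DensityCurve] | DensityCurve,
                      method: str = "pearson", window: float = 50_000,
                      step_fraction: float = 0.1,
                      sample_step: int = 10) -> CorrelationReport:
    """Mean sliding-window correlation over all chromosomes.

    Tail windows are included iff at least half the window lies on the
    chromosome.
    """
    if isinstance(a, DensityCurve):
        a, b = {a.chrom: a}, {b.chrom: b}
    coeffs: list[float] = []
    skipped = 0
    for chrom in a:
        va, vb, k = _cosample(a[chrom], b[chrom], sample_step)
        eff_step = a[chrom].step * k
        w = max(2, int(round(window / eff_step)))
        hop = max(1, int(round(step_fraction * w)))
        n = len(va)
        start = 0
        while start < n:
            seg_a, seg_b = va[start:start + w], vb[start:start + w]
            if len(seg_a) < max(2, w // 2):  # tail window under 50% coverage
                break
            if np.ptp(seg_a) == 0 or np.ptp(seg_b) == 0:
                skipped += 1
            else:
                coeffs.append(_corr(seg_a, seg_b, method))
            start += hop
    if not coeffs:
        raise ValueError("no window with nonzero variance in both curves")
    return CorrelationReport(method, "local", float(np.mean(coeffs)),
                             len(coeffs), window, step_fraction, sample_step,
                             skipped)


def global_correlation(a, b, method: str = "pearson",
                       sample_step: int = 10) -> CorrelationReport:
    """Single coefficient over the genome-wide co-sampled vectors."""
    if isinstance(a, DensityCurve):
        a, b = {a.chrom: a}, {b.chrom: b}
    xs, ys = [], []
    for chrom in a:
        va, vb, _ = _cosample(a[chrom], b[chrom], sample_step)
        xs.append(va)
        ys.append(vb)
    x, y = np.concatenate(xs), np.concatenate(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance track: correlation undefined")
    return CorrelationReport(method, "global", _corr(x, y, method),
                             sample_step=sample_step)


def _draw_positions(rng: np.random.Generator, n: int,
                    chrom_lengths: Mapping[str, int] | None,
                    regions: Sequence[IntergenicRegion] | None):
    """Uniform positions over the whole genome or over intergenic intervals,
    returned as {chrom: sorted unique array}."""
    if regions is not None:
        intervals = [(r.chrom, r.start, r.end) for r in regions if r.length > 0]
    else:
        intervals = [(c, 0, l) for c, l in chrom_lengths.items()]
    lens = np.array([e - s for _, s, e in intervals], dtype=float)
    total = lens.sum()
    if n > total:
        raise ValueError(f"cannot draw {n} positions from a domain of "
                         f"{int(total)} nt")
    offsets = rng.random(n) * total
    cum = np.cumsum(lens)
    which = np.searchsorted(cum, offsets, side="right")
    out: dict[str, list[int]] = {}
    for w, off in zip(which, offsets):
        chrom, s, _ = intervals[w]
        rel = off - (cum[w] - lens[w])
        out.setdefault(chrom, []).append(int(s + rel))
    return {c: np.unique(np.array(p, dtype=float)) for c, p in out.items()}


def random_baseline(reference: Mapping[str, PeakList], n_positions: int,
                    delta: float, domain: str = "whole_genome",
                    chrom_lengths: Mapping[str, int] | None = None,
                    regions: Sequence[IntergenicRegion] | None = None,
                    n_sims: int = 1000, seed: int = 0) -> RandomBaselineReport:
    """Null distribution of PPV/sensitivity for uniformly drawn peak sets."""
    if domain == "intergenic_only":
        if regions is None:
            raise ValueError("intergenic_only domain requires regions")
    elif domain == "whole_genome":
        regions = None
        if chrom_lengths is None:
            raise ValueError("whole_genome domain requires chrom_lengths")
    else:
        raise ValueError(f"unknown domain {domain!r}")
    rng = np.random.default_rng(seed)
    ppvs, senss = np.empty(n_sims), np.empty(n_sims)
    for i in range(n_sims):
        drawn = _draw_positions(rng, n_positions, chrom_lengths, regions)
        pred = {c: PeakList(c, p, np.ones_like(p)) for c, p in drawn.items()}
        rep = match_peaks(pred, reference, delta)
        ppvs[i], senss[i] = rep.ppv, rep.sensitivity
    return RandomBaselineReport(
        n_sims, n_positions, domain,
        best_ppv=float(np.nanmax(ppvs)), best_sens=float(np.nanmax(senss)),
        mean_ppv=float(np.nanmean(ppvs)), mean_sens=float(np.nanmean(senss)),
        p05_ppv=float(np.nanpercentile(ppvs, 95)),
        p05_sens=float(np.nanpercentile(senss, 95)))


def table1_report(model_tracks: Mapping[str, Mapping[str, DensityCurve]],
                  experimental: Mapping[str, DensityCurve] | None,
                  epsilon: float = 1.0,
                  window: float = 50_000) -> pd.DataFrame:
    """Ablation table: local/global Pearson and Spearman plus peak counts for
    each model variant against an experimental track. Without an experimental
    track only the peak counts are reported."""
    from .curves import normalize_density
    from .peaks import find_peaks_genome

    rows = []
    for name, track in model_tracks.items():
        row: dict[str, object] = {"model": name}
        try:
            norm = normalize_density(track)
            row["n_peaks"] = sum(
                len(p) for p in find_peaks_genome(norm, epsilon).values())
        except ValueError:
            row["n_peaks"] = 0
        if experimental is not None:
            for method in ("pearson", "spearman"):
                row[f"{method}_local"] = local_correlation(
                    track, experimental, method, window).value
                row[f"{method}_global"] = global_correlation(
                    track, experimental, method).value
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_profile(track: Mapping[str, DensityCurve] | DensityCurve,
                      anchors: Sequence[tuple], flank: int,
                      sigma: float = 20.0) -> np.ndarray:
    """Orientation-aware mean profile of a track around anchor positions.

    ``anchors`` are (chrom, position, orientation) with orientation in
    {'+', '-'}; '-' anchors are mirrored before averaging. The track is
    smoothed with a σ = 20 nt kernel first. Anchors whose ±flank window falls
    off the chromosome are dropped.
    """
    if isinstance(track, DensityCurve):
        track = {track.chrom: track}
    if not anchors:
        raise ValueError("empty anchor list")
    smoothed = {}
    rows = []
    for anc in anchors:
        chrom, pos, orient = (anc if len(anc) == 3 else (*anc, "+"))
        c = track[chrom]
        if chrom not in smoothed:
            smoothed[chrom] = (gaussian_smooth(c, KernelSpec(sigma))
                               if sigma and sigma >= c.step else c)
        c = smoothed[chrom]
        k = int(round(flank / c.step))
        i = c.index_of(int(pos))
        if i - k < 0 or i + k >= len(c):
            continue
        seg = c.values[i - k:i + k + 1]
        rows.append(seg[::-1] if orient == "-" else seg)
    if not rows:
        raise ValueError("no anchor with a complete window on the track")
    return np.mean(rows, axis=0)
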