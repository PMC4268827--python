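"""Uniform-grid genomic signals and Gaussian-kernel smoothing.

A :class:`DensityCurve` samples a real-valued signal along one chromosome on
a fixed grid (default step 10 nt). All model outputs, GC tracks and
experimental tracks live in this representation; genome-wide tracks are plain
``{chrom: DensityCurve}`` dicts.

Smoothing uses a discrete Gaussian kernel normalized to unit mass and
truncated at ±4σ. At chromosome ends the kernel mass falling outside is
dropped, not renormalized: densities decay toward the ends rather than being
inflated there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d


@dataclass
class DensityCurve:
    chrom: str
    start: int
    step: int
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        if self.step < 1:
            raise ValueError("grid step must be >= 1 nt")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def end(self) -> int:
        """Coordinate one step past the last sample."""
        return self.start + len(self.values) * self.step

    def positions(self) -> np.ndarray:
        return self.start + np.arange(len(self.values)) * self.step

    def index_of(self, position: int) -> int:
        """Nearest grid sample to a genomic position (clipped to the grid)."""
        i = round((position - self.start) / self.step)
        return int(min(max(i, 0), len(self.values) - 1))

    def slice(self, start: int, end: int) -> np.ndarray:
        """Samples with position in [start, end)."""
        i0 = max(0, int(np.ceil((start - self.start) / self.step)))
        i1 = max(i0, int(np.ceil((end - self.start) / self.step)))
        return self.values[i0:min(i1, len(self.values))]

    def with_values(self, values: np.ndarray, label: str | None = None):
        return replace(self, values=np.asarray(values, dtype=float),
                       label=self.label if label is None else label)

    def mass(self) -> float:
        """Trapezoidal integral of the curve (signal units × nt)."""
        if len(self.values) < 2:
            return 0.0
        return float(np.trapezoid(self.values, dx=self.step))


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian kernel: standard deviation in nt, truncated at ±truncation·σ."""

    sigma: float
    truncation: float = 4.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("kernel sigma must be > 0")
        if self.truncation < 3:
            raise ValueError("kernel truncation must be >= 3 sigma")


@dataclass
class GenomeStats:
    """Genome-wide moments feeding the DSB weights: intergenic-region lengths
    (IRL), smoothed GC content, and optionally a model curve."""

    mu_irl: float = 0.0
    sigma_irl: float = 0.0
    mu_gc: float = 0.0
    sigma_gc: float = 0.0
    curve_mean: float = 0.0
    curve_sd: float = 0.0

    @property
    def irl_max(self) -> float:
        """Cap on the intergenic-length weight, μ_IRL + σ_IRL."""
        return self.mu_irl + self.sigma_irl

    @property
    def gc_min(self) -> float:
        """GC floor subtracted before the quadratic weighting, μ_GC − 3σ_GC."""
        return self.mu_gc - 3.0 * self.sigma_gc


def empty_curve(chrom: str, chrom_length: int, step: int = 10,
                label: str = "") -> DensityCurve:
    n = chrom_length // step + 1
    return DensityCurve(chrom, 0, step, np.zeros(n), label)


def gaussian_smooth(curve: DensityCurve, kernel: KernelSpec) -> DensityCurve:
    """Convolve with a unit-mass discrete Gaussian (σ in nt). The output grid
    equals the input grid; kernel mass beyond the chromosome ends is dropped."""
    if kernel.sigma < curve.step:
        warnings.warn(
            f"kernel sigma {kernel.sigma} nt under-resolves grid step "
            f"{curve.step} nt", stacklevel=2)
    smoothed = gaussian_filter1d(curve.values, sigma=kernel.sigma / curve.step,
                                 mode="constant", cval=0.0,
                                 truncate=kernel.truncation)
    return curve.with_values(smoothed)


def place_gaussians(sites: Sequence[tuple[float, float]], kernel: KernelSpec,
                    grid: DensityCurve, unit_area: bool = False) -> DensityCurve:
    """Sum of Gaussian bumps: Σ w·exp(−(x−p)²/2σ²) over (position p, weight w).

    With ``unit_area`` each bump is the Gaussian density w·N(p, σ²), so the
    trapezoidal mass of the curve equals the summed weights; the two modes
    differ only by a global scale, which no downstream statistic (peaks,
    correlations, normalized density) sees.
    """
    x = grid.positions().astype(float)
    out = np.zeros_like(x)
    half = kernel.truncation * kernel.sigma
    scale = 1.0 / (kernel.sigma * np.sqrt(2 * np.pi)) if unit_area else 1.0
    for p, w in sites:
        i0 = int(np.searchsorted(x, p - half))
        i1 = int(np.searchsorted(x, p + half, side="right"))
        seg = x[i0:i1]
        out[i0:i1] += w * scale * np.exp(-((seg - p) ** 2) / (2 * kernel.sigma ** 2))
    return grid.with_values(out)


def gc_track(sequence: str, kernel: KernelSpec = KernelSpec(1000.0),
             step: int = 10, chrom: str = "") -> DensityCurve:
    """Gaussian-smoothed GC fraction of a sequence over {A,C,G,T,N}.

    N bases are excluded from both numerator and denominator, so the value is
    the kernel-weighted GC fraction over informative bases only; values lie
    in [0, 1].
    """
    seq = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    is_gc = ((seq == ord("G")) | (seq == ord("C"))).astype(float)
    is_acgt = np.isin(seq, np.frombuffer(b"ACGT", dtype=np.uint8)).astype(float)
    if not is_acgt.any():
        raise ValueError("sequence contains no informative (non-N) bases")
    num = gaussian_filter1d(is_gc, kernel.sigma, mode="constant", cval=0.0,
                            truncate=kernel.truncation)
    den = gaussian_filter1d(is_acgt, kernel.sigma, mode="constant", cval=0.0,
                            truncate=kernel.truncation)
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    # masked stretches wider than the kernel: fall back to global mean
    if np.isnan(gc).any():
        gc = np.where(np.isnan(gc), float(is_gc.sum() / is_acgt.sum()), gc)
    vals = np.clip(gc[::step], 0.0, 1.0)
    return DensityCurve(chrom, 0, step, vals, label="gc")


def _pool_values(curves) -> np.ndarray:
    if isinstance(curves, DensityCurve):
        return curves.values
    if isinstance(curves, Mapping):
        return np.concatenate([c.values for c in curves.values()])
    return np.concatenate([c.values for c in curves])


def normalize_density(curves, p_low: float = 1.0, p_high: float = 99.0):
    """Affine-rescale a track so its 1st percentile maps to 1 and the 99th to
    99 (computed genome-wide over all chromosomes, linear interpolation).

    Accepts a single curve or a ``{chrom: curve}`` dict and returns the same
    shape. Raises on flat curves (p1 == p99).
    """
    pooled = _pool_values(curves)
    if pooled.size < 100:
        warnings.warn("normalizing fewer than 100 samples; percentiles are "
                      "poorly determined", stacklevel=2)
    lo, hi = np.percentile(pooled, [p_low, p_high])
    if hi <= lo:
        raise ValueError("degenerate curve: percentiles coincide, cannot "
                         "normalize a flat track")

    def f(c: DensityCurve) -> DensityCurve:
        return c.with_values(p_low + (p_high - p_low) * (c.values - lo) / (hi - lo))

    if isinstance(curves, DensityCurve):
        return f(curves)
    return {k: f(c) for k, c in curves.items()}


def genome_stats(regions=None, gc=None, model=None) -> GenomeStats:
    """Genome-wide moments: μ/σ of intergenic-region lengths, of the smoothed
    GC curve, and of an optional model curve. Standard deviations are
    population SDs."""
    from .genome_io import intergenic_lengths

    st = GenomeStats()
    if regions is not None:
        lens = intergenic_lengths(regions)
        if lens.size == 0:
            raise ValueError("no intergenic regions supplied")
        st.mu_irl = float(lens.mean())
        st.sigma_irl = float(lens.std())
    if gc is not None:
        vals = _pool_values(gc)
        st.mu_gc = float(vals.mean())
        st.sigma_gc = float(vals.std())
    if model is not None:
        vals = _pool_values(model)
        st.curve_mean = float(vals.mean())
        st.curve_sd = float(vals.std())
    return st


def smooth_probes(positions: np.ndarray, values: np.ndarray,
                  kernel: KernelSpec, grid: DensityCurve) -> DensityCurve:
    """Nadaraya–Watson smoother for irregularly spaced probe measurements
    (tiling-array style data). Experimental: exact probe handling is
    data-specific. Grid points farther than the kernel truncation from every
    probe get NaN replaced by the nearest informative value."""
    x = grid.positions().astype(float)
    num = np.zeros_like(x)
    den = np.zeros_like(x)
    half = kernel.truncation * kernel.sigma
    order = np.argsort(positions)
    positions = np.asarray(positions, dtype=float)[order]
    values = np.asarray(values, dtype=float)[order]
    for p, v in zip(positions, values):
        i0 = int(np.searchsorted(x, p - half))
        i1 = int(np.searchsorted(x, p + half, side="right"))
        w = np.exp(-((x[i0:i1] - p) ** 2) / (2 * kernel.sigma ** 2))
        num[i0:i1] += w * v
        den[i0:i1] += w
    out = np.full_like(x, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    if not ok.all():
        if not ok.any():
            raise ValueError("no probe within kernel range of any grid point")
        idx = np.arange(len(x))
        out[~ok] = out[ok][np.searchsorted(idx[ok], idx[~ok]).clip(0, ok.sum() - 1)]
    return grid.with_values(out)
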