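"""Seeded synthetic genomes and pseudo-experimental tracks.

The generator emulates the structural features the models consume: multiple
chromosomes, genes of variable (log-normal) length on both strands, a
realistic intergenic-length distribution (geometric gaps, mean 500 nt —
loosely the budding-yeast scale), and spatially heterogeneous GC content
(uniform, blockwise or gradient profiles). It makes no attempt at codon
structure or motifs: sequences are i.i.d. draws from the local GC
probability.

All randomness flows from one integer seed through a single
``numpy.random.Generator``; identical specs produce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import DensityCurve
from .genome_io import GeneRecord, GeneSet


@dataclass
class SyntheticGenomeSpec:
    n_chrom: int = 2
    chrom_length: int = 300_000
    gene_density: float = 0.5          # genes per kb; yeast ≈ 0.5
    gene_length_mean: float = 1500.0   # nt, log-normal
    gene_length_sd: float = 800.0      # nt
    strand_model: float | str = 0.5    # Bernoulli(+) prob or e.g. "++-+-"
    gc_profile: tuple = ("uniform", 0.4)
    seed: int = 0

    def __post_init__(self):
        if self.n_chrom < 1 or self.chrom_length < 1000:
            raise ValueError("need at least one chromosome of >= 1 kb")
        if isinstance(self.strand_model, float) and not 0 <= self.strand_model <= 1:
            raise ValueError("strand probability must be in [0, 1]")
        mean_gap = 1000.0 / self.gene_density - self.gene_length_mean
        if mean_gap <= 0:
            raise ValueError(
                f"infeasible density: {self.gene_density} genes/kb with mean "
                f"gene length {self.gene_length_mean} nt leaves no intergenic "
                "space")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    var = sd ** 2
    s2 = np.log(1 + var / mean ** 2)
    return np.log(mean) - s2 / 2, np.sqrt(s2)


def gc_probability(spec: SyntheticGenomeSpec, length: int) -> np.ndarray:
    """Per-base GC probability along one chromosome."""
    kind = spec.gc_profile[0]
    if kind == "uniform":
        return np.full(length, float(spec.gc_profile[1]))
    if kind == "blockwise":
        levels, block = spec.gc_profile[1], int(spec.gc_profile[2])
        idx = (np.arange(length) // block) % len(levels)
        return np.asarray(levels, dtype=float)[idx]
    if kind == "gradient":
        lo, hi = float(spec.gc_profile[1]), float(spec.gc_profile[2])
        return np.linspace(lo, hi, length)
    raise ValueError(f"unknown gc profile {kind!r}")


def generate_genome(spec: SyntheticGenomeSpec) -> tuple[dict[str, str], GeneSet]:
    """Deterministic synthetic genome: ``({chrom: sequence}, GeneSet)``.

    Genes are placed left to right, separated by geometric gaps whose mean is
    set so that the requested gene density holds on average; genes never
    overlap.
    """
    rng = np.random.default_rng(spec.seed)
    mean_gap = 1000.0 / spec.gene_density - spec.gene_length_mean
    mu, s = _lognormal_params(spec.gene_length_mean, spec.gene_length_sd)
    sequences: dict[str, str] = {}
    records: list[GeneRecord] = []
    lengths: dict[str, int] = {}
    orient = spec.strand_model if isinstance(spec.strand_model, str) else None
    gi = 0
    for ci in range(spec.n_chrom):
        chrom = f"chr{ci + 1}"
        lengths[chrom] = spec.chrom_length
        # sequence from the local GC probability
        p = gc_probability(spec, spec.chrom_length)
        u = rng.random(spec.chrom_length)
        strong = u < p  # G or C
        half = rng.random(spec.chrom_length) < 0.5
        bases = np.where(strong, np.where(half, ord("G"), ord("C")),
                         np.where(half, ord("A"), ord("T"))).astype(np.uint8)
        sequences[chrom] = bases.tobytes().decode("ascii")
        # gene placement
        pos = int(rng.geometric(1.0 / mean_gap))
        while True:
            glen = int(np.clip(rng.lognormal(mu, s), 60, None))
            if pos + glen + 1 >= spec.chrom_length:
                break
            if orient is not None:
                strand = "+" if orient[gi % len(orient)] == "+" else "-"
            else:
                strand = "+" if rng.random() < spec.strand_model else "-"
            records.append(GeneRecord(f"g{gi:05d}", chrom, pos, pos + glen,
                                      strand, "cds"))
            gi += 1
            pos += glen + int(rng.geometric(1.0 / mean_gap))
    return sequences, GeneSet(records, lengths)


def generate_pseudo_experiment(model, noise_sd: float,
                               probe_spacing: float | None = None,
                               seed: int = 0):
    """Model curve plus white noise, standing in for an experimental track.

    Returns ``{chrom: DensityCurve}`` (or a single curve if given one). With
    ``probe_spacing`` set, instead returns ``{chrom: (positions, values)}``
    sampled at irregular probe positions with exponential gaps of the given
    mean, emulating tiling-array data.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    single = isinstance(model, DensityCurve)
    track = {model.chrom: model} if single else model

    if probe_spacing is None:
        out = {c: cv.with_values(cv.values + rng.normal(0, noise_sd, len(cv)),
                                 label="pseudo_experiment")
               for c, cv in track.items()}
        return out[model.chrom] if single else out

    probes = {}
    for c, cv in track.items():
        gaps = rng.exponential(probe_spacing, int(2 * cv.end / probe_spacing) + 10)
        pos = cv.start + np.cumsum(gaps)
        pos = pos[pos < cv.end - cv.step]
        idx = np.round((pos - cv.start) / cv.step).astype(int)
        vals = cv.values[idx] + rng.normal(0, noise_sd, len(idx))
        probes[c] = (pos, vals)
    return probes[model.chrom] if single else probes
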