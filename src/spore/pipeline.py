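"""End-to-end run: build curves, call peaks, evaluate, emit browser files.

``run_pipeline`` is a pure function of (input files, config, seeds): given a
genome FASTA and an annotation it writes axis and DSB WIG tracks, peak BED
files, a variant-ablation report and a log into the run directory. A config
round-trips through a flat INI file (one section per module); CLI flags
override file values.
"""

from __future__ import annotations

import configparser
import io
import json
import os
import time
from dataclasses import asdict, dataclass

from . import __version__
from .axis_model import AxisModelConfig, axis_curve
from .curves import KernelSpec, gc_track, genome_stats, normalize_density
from .dsb_model import DsbModelConfig, dsb_curve
from .genome_io import (derive_intergenic_regions, read_annotation,
                        read_fasta, read_tfbs, read_wig, write_bed, write_wig)
from .peaks import find_peaks_genome, peaks_to_bed


@dataclass
class RunConfig:
    genome: str = ""
    annotation: str = ""
    tfbs: str = ""
    experiment_axis: str = ""
    experiment_dsb: str = ""
    out_dir: str = "spore_run"
    step: int = 10
    sigma_axis: float = 1500.0
    sigma_dsb: float = 250.0
    sigma_gc: float = 1000.0
    truncation: float = 4.0
    axis_variant: int = 3
    dsb_variant: int = 6
    noise_ratio: float = 0.0      # 0 disables; observed value 3.5
    epsilon: float = 1.0
    window: float = 50_000.0
    deltas: tuple = (1000.0, 1500.0)
    n_sims: int = 1000
    seed: int = 0
    skip_existing: bool = False

    _SECTIONS = {
        "io": ("genome", "annotation", "tfbs", "experiment_axis",
               "experiment_dsb", "out_dir"),
        "curves": ("step", "sigma_axis", "sigma_dsb", "sigma_gc", "truncation"),
        "models": ("axis_variant", "dsb_variant", "noise_ratio"),
        "evaluation": ("epsilon", "window", "deltas", "n_sims", "seed"),
        "run": ("skip_existing",),
    }

    def validate(self) -> None:
        AxisModelConfig(self.axis_variant, self.sigma_axis,
                        self.noise_ratio or None, self.step)
        DsbModelConfig(self.dsb_variant, self.sigma_dsb, step=self.step)
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")

    def to_ini(self, path: str) -> None:
        cp = configparser.ConfigParser()
        for section, keys in self._SECTIONS.items():
            cp[section] = {}
            for k in keys:
                v = getattr(self, k)
                cp[section][k] = (",".join(str(x) for x in v)
                                  if isinstance(v, tuple) else str(v))
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_ini(cls, path: str) -> "RunConfig":
        cp = configparser.ConfigParser()
        if not cp.read(path):
            raise FileNotFoundError(path)
        cfg = cls()
        for section, keys in cls._SECTIONS.items():
            if section not in cp:
                continue
            for k in keys:
                if k not in cp[section]:
                    continue
                raw = cp[section][k]
                default = getattr(cfg, k)
                if isinstance(default, bool):
                    setattr(cfg, k, raw.lower() in ("1", "true", "yes"))
                elif isinstance(default, int):
                    setattr(cfg, k, int(raw))
                elif isinstance(default, float):
                    setattr(cfg, k, float(raw))
                elif isinstance(default, tuple):
                    setattr(cfg, k, tuple(float(x) for x in raw.split(",") if x))
                else:
                    setattr(cfg, k, raw)
        return cfg


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the full workflow; returns {artifact name: path}."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    log = io.StringIO()
    t0 = time.time()
    paths: dict[str, str] = {}

    def stage(name):
        log.write(f"[{time.time() - t0:8.2f}s] {name}\n")

    def out(name):
        p = os.path.join(config.out_dir, name)
        paths[name] = p
        return p

    stage("load inputs")
    seqs = read_fasta(config.genome)
    lengths = {c: len(s) for c, s in seqs.items()}
    genes = read_annotation(config.annotation, chrom_lengths=lengths)
    regions = derive_intergenic_regions(genes)
    tfbs = read_tfbs(config.tfbs, lengths) if config.tfbs else None

    def cached(name, compute):
        """Skip a track stage when its output already exists (on request)."""
        p = out(name)
        if config.skip_existing and os.path.exists(p):
            stage(f"{name} (cached)")
            return read_wig(p)
        track = compute()
        write_wig(track, p)
        return track

    stage("gc track")
    gc = cached("gc.wig", lambda: {
        c: gc_track(s, KernelSpec(config.sigma_gc, config.truncation),
                    step=config.step, chrom=c) for c, s in seqs.items()})
    stats = genome_stats(regions=regions, gc=gc)

    stage("axis model")
    axis = cached("axis.wig", lambda: axis_curve(genes, AxisModelConfig(
        config.axis_variant, config.sigma_axis,
        config.noise_ratio or None, config.step)))

    stage("dsb model")
    dsb = cached("dsb.wig", lambda: dsb_curve(
        genes, regions, gc,
        DsbModelConfig(config.dsb_variant, config.sigma_dsb,
                       use_tfbs=tfbs is not None, step=config.step),
        stats, tfbs))

    stage("peak calling")
    peak_sets = {}
    for name, track in (("axis", axis), ("dsb", dsb)):
        norm = normalize_density(track)
        pk = find_peaks_genome(norm, config.epsilon)
        peak_sets[name] = pk
        write_bed(peaks_to_bed(pk), out(f"{name}_peaks.bed"))

    stage("evaluation")
    from .evaluation import table1_report
    experimental = None
    if config.experiment_dsb:
        experimental = read_wig(config.experiment_dsb)
    report = table1_report({"dsb_model": dsb}, experimental,
                           config.epsilon, config.window)
    if config.experiment_axis:
        axis_exp = read_wig(config.experiment_axis)
        import pandas as pd
        report = pd.concat(
            [report, table1_report({"axis_model": axis}, axis_exp,
                                   config.epsilon, config.window)],
            ignore_index=True)
    report.to_csv(out("report.tsv"), sep="\t", index=False)

    stage("summary")
    summary = {
        "version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "irl_max_nt": stats.irl_max,
        "gc_min": stats.gc_min,
        "n_genes": len(genes),
        "n_axis_peaks": sum(len(p) for p in peak_sets["axis"].values()),
        "n_dsb_peaks": sum(len(p) for p in peak_sets["dsb"].values()),
    }
    with open(out("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    config.to_ini(out("config.ini"))
    stage("done")
    with open(out("run.log"), "w") as fh:
        fh.write(log.getvalue())
    return paths
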