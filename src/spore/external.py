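"""Pinned whole-genome quantities on user-supplied reference data.

These checks need real genome releases (e.g. S. cerevisiae S288C release 64
from SGD, L. kluyveri from Genolevures), which this package does not bundle.
Place the files under ``data/external/`` (or pass paths explicitly):

- ``scer.fa`` / ``scer.gff``   — S. cerevisiae genome + annotation
- ``lklu.fa`` / ``lklu.gff``   — L. kluyveri genome + annotation (optional)

``external_targets`` then recomputes, per genome: IRL_max = μ_IRL + σ_IRL, the
axis model-3 peak count and the DSB model-6 peak count. Reference values for
S. cerevisiae r64: IRL_max = 1202 nt, 1615 axis peaks, 4242 DSB peaks.
"""

from __future__ import annotations

import os

from .axis_model import AxisModelConfig, axis_curve
from .curves import KernelSpec, gc_track, genome_stats, normalize_density
from .dsb_model import DsbModelConfig, dsb_curve
from .genome_io import derive_intergenic_regions, read_annotation, read_fasta
from .peaks import find_peaks_genome


def external_targets(fasta_path: str, annotation_path: str,
                     feature_filter=None, epsilon: float = 1.0) -> dict:
    """IRL_max and model peak counts on a real genome release."""
    for p in (fasta_path, annotation_path):
        if not os.path.exists(p):
            raise FileNotFoundError(
                f"{p}: external reference data not found; download the genome "
                "release and place it as documented in spore.external")
    seqs = read_fasta(fasta_path)
    lengths = {c: len(s) for c, s in seqs.items()}
    kwargs = {"feature_filter": feature_filter} if feature_filter else {}
    genes = read_annotation(annotation_path, chrom_lengths=lengths, **kwargs)
    regions = derive_intergenic_regions(genes)
    gc = {c: gc_track(s, KernelSpec(1000.0), chrom=c) for c, s in seqs.items()}
    stats = genome_stats(regions=regions, gc=gc)

    axis = axis_curve(genes, AxisModelConfig(variant=3))
    dsb = dsb_curve(genes, regions, gc, DsbModelConfig(variant=6), stats)
    n_axis = sum(len(p) for p in
                 find_peaks_genome(normalize_density(axis), epsilon).values())
    n_dsb = sum(len(p) for p in
                find_peaks_genome(normalize_density(dsb), epsilon).values())
    return {
        "irl_max_nt": stats.irl_max,
        "axis_model3_peaks": n_axis,
        "dsb_model6_peaks": n_dsb,
        "n_genes": len(genes),
    }
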