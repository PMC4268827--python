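"""DSB (Spo11-like) density model.

Meiotic double-strand breaks concentrate in promoter-containing intergenic
regions. The model derives one candidate promoter position per gene from the
intergenic region upstream of its start codon:

- convergent regions (two 3′-ends) contain no gene start and receive no site;
- tandem regions carry the single downstream promoter at the region midpoint;
- divergent regions carry two promoters, each one-third of the way into the
  region from its gene's side (so the pair sits at 1/3 and 2/3);
- a TFBS table, when supplied, overrides the geometric placement with the
  mean position of the gene's binding sites.

Each site is weighted by min(irl, IRL_max)·(max(0, gc(p) − GC_min))² where
irl is the upstream intergenic-region length, IRL_max = μ_IRL + σ_IRL caps
very long regions, gc(p) is the σ = 1 kb smoothed GC content at the site and
GC_min = μ_GC − 3σ_GC. The weighted impulses are smoothed with σ = 250 nt.

Ablation variants 1–6 drop or simplify the factors: 1–2 place impulses at
start codons (weight 1 / gene length); 3 uses promoter sites with constant
weight; 4 IRL only; 5 quadratic GC only; 6 the full model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import (DensityCurve, GenomeStats, KernelSpec, empty_curve,
                     place_gaussians)
from .genome_io import DIVERGENT, GeneRecord, GeneSet, IntergenicRegion

VARIANT_NAMES = {
    1: "gene_starts_const",
    2: "gene_starts_length",
    3: "promoters_const",
    4: "promoters_irl",
    5: "promoters_gc",
    6: "promoters_gc_irl",
}


@dataclass(frozen=True)
class DsbModelConfig:
    variant: int = 6
    sigma: float = 250.0
    use_tfbs: bool = False
    step: int = 10

    def __post_init__(self):
        if self.variant not in VARIANT_NAMES:
            raise ValueError(f"DSB model variant must be 1-6, got {self.variant}")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class PromoterSite:
    gene: GeneRecord
    position: float
    source: str  # "geometric" | "tfbs"
    irl: float
    gc_at_p: float = float("nan")


def _geometric_position(gene: GeneRecord, region: IntergenicRegion) -> float:
    """Promoter position inside the gene's upstream region.

    For divergent regions the position is one-third of the way in from the
    gene's own start-codon side; tandem and border regions use the midpoint.
    """
    a0, b0 = region.start, region.end
    length = b0 - a0
    if region.region_class == DIVERGENT:
        # start codon of a + gene abuts the region's right end, of a − gene
        # its left end
        if gene.strand == "+":
            return b0 - length / 3.0
        return a0 + length / 3.0
    return a0 + length / 2.0


def promoter_positions(genes: GeneSet, regions: list[IntergenicRegion],
                       tfbs: dict[str, list[int]] | None = None) -> list[PromoterSite]:
    """Exactly one site per gene. Genes whose upstream region has zero length
    get a degenerate site with irl = 0."""
    up_of: dict[int, IntergenicRegion] = {}
    for r in regions:
        if r.right_gene is not None and r.right_gene.strand == "+":
            up_of[id(r.right_gene)] = r
        if r.left_gene is not None and r.left_gene.strand == "-":
            up_of[id(r.left_gene)] = r
    sites = []
    for g in genes.records:
        region = up_of.get(id(g))
        if region is None:  # no gap record (shouldn't happen on derived regions)
            continue
        if tfbs and g.id in tfbs and tfbs[g.id]:
            pos = float(np.mean(tfbs[g.id]))
            source = "tfbs"
        else:
            pos = _geometric_position(g, region)
            source = "geometric"
        sites.append(PromoterSite(g, pos, source, float(region.length)))
    return sites


def site_weight(site: PromoterSite, stats: GenomeStats, variant: int = 6) -> float:
    """Weight of a promoter site under the chosen variant (nonnegative)."""
    if variant in (1, 2):
        raise ValueError("variants 1-2 weight start codons, not promoter sites")
    if variant == 3:
        return 1.0
    irl_term = min(site.irl, stats.irl_max)
    if variant == 4:
        return irl_term
    if np.isnan(site.gc_at_p):
        raise ValueError(f"gc_at_p missing for gene {site.gene.id} "
                         f"(variant {variant} needs a GC track)")
    gc_term = max(0.0, site.gc_at_p - stats.gc_min) ** 2
    if variant == 5:
        return gc_term
    return irl_term * gc_term


def dsb_curve(genes: GeneSet, regions: list[IntergenicRegion] | None = None,
              gc: dict[str, DensityCurve] | None = None,
              config: DsbModelConfig = DsbModelConfig(),
              stats: GenomeStats | None = None,
              tfbs: dict[str, list[int]] | None = None
              ) -> dict[str, DensityCurve]:
    """Smoothed DSB modeling curve per chromosome.

    ``regions`` and ``stats`` are derived on the fly when omitted (stats needs
    ``gc`` for the GC moments). Convergent regions receive no site.
    """
    from .curves import genome_stats
    from .genome_io import derive_intergenic_regions

    if config.variant >= 3 and regions is None:
        regions = derive_intergenic_regions(genes)
    if config.variant >= 4 and stats is None:
        stats = genome_stats(regions=regions, gc=gc)

    by_chrom_sites: dict[str, list[tuple[float, float]]] = {c: [] for c in genes.chroms()}
    if config.variant in (1, 2):
        for g in genes.records:
            w = 1.0 if config.variant == 1 else float(g.length)
            by_chrom_sites[g.chrom].append((float(g.start_codon), w))
    else:
        sites = promoter_positions(genes, regions,
                                   tfbs if config.use_tfbs or tfbs else None)
        for s in sites:
            if config.variant >= 5:
                if gc is None:
                    raise ValueError(f"variant {config.variant} requires a GC track")
                track = gc[s.gene.chrom]
                s = PromoterSite(s.gene, s.position, s.source, s.irl,
                                 float(track.values[track.index_of(int(s.position))]))
            w = site_weight(s, stats if stats is not None else GenomeStats(),
                            config.variant)
            by_chrom_sites[s.gene.chrom].append((s.position, w))

    kernel = KernelSpec(config.sigma)
    out = {}
    for chrom in genes.chroms():
        clen = genes.chrom_lengths.get(chrom)
        if clen is None:
            clen = max((g.end for g in genes.by_chrom().get(chrom, [])), default=0)
        grid = empty_curve(chrom, clen, config.step,
                           label=f"dsb_model_v{config.variant}")
        out[chrom] = place_gaussians(by_chrom_sites.get(chrom, []), kernel, grid,
                                     unit_area=True)
        out[chrom].label = f"dsb_model_v{config.variant}"
    return out
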