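import numpy as np
import pytest

from conftest import random_geneset
from spore.curves import (DensityCurve, GenomeStats, KernelSpec, empty_curve,
                          gc_track, genome_stats)
from spore.dsb_model import (DsbModelConfig, PromoterSite, dsb_curve,
                             promoter_positions, site_weight)
from spore.genome_io import (GeneRecord, GeneSet, derive_intergenic_regions)


def flat_gc(genes, value=0.45, step=10):
    return {c: DensityCurve(c, 0, step,
                            np.full(genes.chrom_lengths[c] // step + 1, value))
            for c in genes.chrom_lengths}


class TestPromoterPlacement:
    def test_tandem_region_midpoint(self):
        gs = GeneSet([GeneRecord("a", "chr1", 50, 100, "+"),
                      GeneRecord("b", "chr1", 400, 500, "+")], {"chr1": 1000})
        regions = derive_intergenic_regions(gs)
        sites = {s.gene.id: s for s in promoter_positions(gs, regions)}
        assert sites["b"].position == pytest.approx(250.0)  # [100,400] midpoint
        assert sites["b"].irl == 300.0
        assert sites["b"].source == "geometric"

    def test_divergent_region_thirds(self):
        gs = GeneSet([GeneRecord("a", "chr1", 50, 100, "-"),
                      GeneRecord("b", "chr1", 400, 500, "+")], {"chr1": 1000})
        regions = derive_intergenic_regions(gs)
        sites = {s.gene.id: s for s in promoter_positions(gs, regions)}
        # region [100,400]: a's site one-third in from 100, b's from 400
        assert sites["a"].position == pytest.approx(200.0)
        assert sites["b"].position == pytest.approx(300.0)
        assert sites["a"].irl == sites["b"].irl == 300.0  # full region length

    def test_tfbs_mean_overrides_geometry(self):
        gs = GeneSet([GeneRecord("a", "chr1", 50, 100, "+"),
                      GeneRecord("b", "chr1", 400, 500, "+")], {"chr1": 1000})
        regions = derive_intergenic_regions(gs)
        sites = {s.gene.id: s
                 for s in promoter_positions(gs, regions, {"b": [120, 180]})}
        assert sites["b"].position == pytest.approx(150.0)
        assert sites["b"].source == "tfbs"
        assert sites["a"].source == "geometric"

    def test_exactly_one_site_per_gene(self, rng):
        gs = random_geneset(rng, n=50)
        regions = derive_intergenic_regions(gs)
        sites = promoter_positions(gs, regions)
        assert len(sites) == len(gs.records)
        assert {s.gene.id for s in sites} == {g.id for g in gs.records}

    def test_no_site_inside_convergent_regions(self, rng):
        gs = random_geneset(rng, n=50)
        regions = derive_intergenic_regions(gs)
        conv = [(r.start, r.end) for r in regions
                if r.region_class == "convergent" and r.length > 0]
        for s in promoter_positions(gs, regions):
            assert not any(a < s.position < b for a, b in conv)


class TestSiteWeight:
    stats = GenomeStats(mu_irl=1000, sigma_irl=202, mu_gc=0.4, sigma_gc=0.05)

    def test_full_model_arithmetic(self):
        # irl=600, IRL_max=1202, gc=0.45, GC_min=0.25 -> 600 * 0.2^2 = 24
        site = PromoterSite(GeneRecord("g", "chr1", 10, 20, "+"),
                            5.0, "geometric", irl=600.0, gc_at_p=0.45)
        assert site_weight(site, self.stats, 6) == pytest.approx(24.0)

    def test_irl_caps_at_threshold(self):
        site = PromoterSite(GeneRecord("g", "chr1", 10, 20, "+"),
                            5.0, "geometric", irl=5000.0, gc_at_p=0.45)
        assert site_weight(site, self.stats, 4) == pytest.approx(1202.0)
        capped = site_weight(site, self.stats, 6)
        site2 = PromoterSite(site.gene, 5.0, "geometric", 1202.0, 0.45)
        assert capped == site_weight(site2, self.stats, 6)

    def test_gc_floor_clamps_to_zero(self):
        site = PromoterSite(GeneRecord("g", "chr1", 10, 20, "+"),
                            5.0, "geometric", irl=600.0, gc_at_p=0.20)
        assert site_weight(site, self.stats, 5) == 0.0
        assert site_weight(site, self.stats, 6) == 0.0

    def test_monotone_in_gc_and_irl(self):
        base = PromoterSite(GeneRecord("g", "chr1", 10, 20, "+"),
                            5.0, "geometric", irl=600.0, gc_at_p=0.40)
        for v in (5, 6):
            lo = site_weight(base, self.stats, v)
            hi = site_weight(PromoterSite(base.gene, 5.0, "geometric",
                                          600.0, 0.41), self.stats, v)
            assert hi > lo > 0
        w = [site_weight(PromoterSite(base.gene, 5.0, "geometric", irl, 0.4),
                         self.stats, 4) for irl in (100, 600, 1202, 3000)]
        assert w[0] < w[1] < w[2] == w[3]

    def test_variant3_constant_and_missing_gc_rejected(self):
        site = PromoterSite(GeneRecord("g", "chr1", 10, 20, "+"),
                            5.0, "geometric", irl=600.0)
        assert site_weight(site, self.stats, 3) == 1.0
        with pytest.raises(ValueError, match="gc_at_p"):
            site_weight(site, self.stats, 6)


class TestDsbCurve:
    def test_convergent_regions_are_deserts(self, toy_genes):
        regions = derive_intergenic_regions(toy_genes)
        gc = flat_gc(toy_genes)
        track = dsb_curve(toy_genes, regions, gc, DsbModelConfig(variant=6))
        c = track["chr1"]
        sites = [s.position for s in promoter_positions(toy_genes, regions)]
        # convergent gap gA/gB is [2500,3500]; points >= 4 sigma from any site
        for pos in range(2500, 3501, 10):
            if min(abs(pos - p) for p in sites) >= 4 * 250:
                assert c.values[c.index_of(pos)] < 1e-9 * c.values.max()

    def test_divergent_mass_is_twice_tandem_when_matched(self):
        # one divergent and one tandem region with identical length and GC
        gs = GeneSet([
            GeneRecord("a", "chr1", 9_000, 10_000, "-"),
            GeneRecord("b", "chr1", 11_000, 12_000, "+"),   # divergent [10k,11k]
            GeneRecord("c", "chr1", 29_000, 30_000, "+"),
            GeneRecord("d", "chr1", 31_000, 32_000, "+"),   # tandem [30k,31k]
        ], {"chr1": 40_000})
        regions = derive_intergenic_regions(gs)
        gc = flat_gc(gs)
        track = dsb_curve(gs, regions, gc, DsbModelConfig(variant=6))["chr1"]
        div = np.trapezoid(track.slice(8_000, 13_000), dx=10)
        tan = np.trapezoid(track.slice(28_000, 33_000), dx=10)
        assert div == pytest.approx(2 * tan, rel=0.01)

    def test_matches_bruteforce_site_sum(self, rng):
        gs = random_geneset(rng, n=50)
        regions = derive_intergenic_regions(gs)
        gc = {c: gc_track("".join(rng.choice(list("ACGT"), size=l)),
                          KernelSpec(1000.0), chrom=c)
              for c, l in gs.chrom_lengths.items()}
        stats = genome_stats(regions=regions, gc=gc)
        cfg = DsbModelConfig(variant=6)
        track = dsb_curve(gs, regions, gc, cfg, stats)["chr1"]
        # oracle: direct double loop over sites and grid
        x = track.positions().astype(float)
        expected = np.zeros_like(x)
        for s in promoter_positions(gs, regions):
            g = gc[s.gene.chrom]
            gc_p = g.values[g.index_of(int(s.position))]
            w = min(s.irl, stats.irl_max) * max(0.0, gc_p - stats.gc_min) ** 2
            d = np.abs(x - s.position)
            expected += np.where(d <= 4 * 250.0,
                                 w * np.exp(-d ** 2 / (2 * 250.0 ** 2)), 0.0)
        expected /= 250.0 * np.sqrt(2 * np.pi)
        np.testing.assert_allclose(track.values, expected, atol=1e-12)

    def test_total_mass_equals_summed_weights(self, toy_genes):
        regions = derive_intergenic_regions(toy_genes)
        gc = flat_gc(toy_genes)
        stats = genome_stats(regions=regions, gc=gc)
        track = dsb_curve(toy_genes, regions, gc,
                          DsbModelConfig(variant=6), stats)["chr1"]
        total = 0.0
        for s in promoter_positions(toy_genes, regions):
            site = PromoterSite(s.gene, s.position, s.source, s.irl, 0.45)
            total += site_weight(site, stats, 6)
        assert track.mass() == pytest.approx(total, rel=2e-3)

    def test_strand_swap_disjoint_sites(self, rng):
        gs = random_geneset(rng, n=40)
        swapped = GeneSet([GeneRecord(g.id, g.chrom, g.start, g.end,
                                      "+" if g.strand == "-" else "-")
                           for g in gs.records], gs.chrom_lengths)
        r1 = derive_intergenic_regions(gs)
        r2 = derive_intergenic_regions(swapped)
        by_span1 = {(r.start, r.end): r.region_class for r in r1}
        for r in r2:
            if r.region_class == "border":
                continue
            orig = by_span1[(r.start, r.end)]
            assert {orig, r.region_class} in ({"convergent", "divergent"},
                                              {"tandem"})

    def test_gene_start_variants(self, toy_genes):
        track1 = dsb_curve(toy_genes, config=DsbModelConfig(variant=1))["chr1"]
        track2 = dsb_curve(toy_genes, config=DsbModelConfig(variant=2))["chr1"]
        assert track1.mass() == pytest.approx(len(toy_genes), rel=1e-2)
        assert track2.mass() == pytest.approx(
            sum(g.length for g in toy_genes.records), rel=1e-2)

    def test_uniform_gc_shift_increases_weights(self):
        stats = GenomeStats(mu_irl=500, sigma_irl=100, mu_gc=0.4, sigma_gc=0.02)
        g = GeneRecord("g", "chr1", 10, 20, "+")
        for v in (5, 6):
            w0 = site_weight(PromoterSite(g, 5.0, "geometric", 400, 0.40),
                             stats, v)
            w1 = site_weight(PromoterSite(g, 5.0, "geometric", 400, 0.45),
                             stats, v)
            assert w1 > w0 > 0
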