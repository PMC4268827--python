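# spore

Predicts two meiotic chromatin landscapes along a genome — the density of
programmed double-strand breaks (DSBs, made by Spo11) and the density of
chromosomal axis proteins (Red1/Hop1/Rec8) — using nothing but gene
annotation and GC content. It also ships the complete evaluation machinery
for such predictions: ε-prominence peak calling, sliding-window and global
Pearson/Spearman correlation, Δ-tolerant PPV/sensitivity against reference
peak sets, seeded random baselines, matched coldspot sampling and hot/cold
interval classification with ROC/AUC.

Intended users: researchers studying meiotic recombination who want a
parameter-light, annotation-driven prediction for genomes lacking Spo11 or
ChIP data, and anyone benchmarking hotspot predictors against a transparent
geometric baseline.

## The model

Both predictions follow the same two-step scheme: place weights at genomic
positions chosen from the annotation, then smooth with a Gaussian kernel.

**Axis proteins.** Axis proteins load along genes during transcription and
accumulate toward 3′ ends. The raw signal is a per-gene linear ramp,

    h(x) = Σ_g 1_[a_g, b_g](x) · (x − a_g)/(b_g − a_g),

rising from 0 at the start codon `a_g` to 1 at the stop codon `b_g` (oriented
by strand), so the pre-smoothing area under a gene is half its length. The
model curve is `f_axis = h ∗ K_σ` with σ = 1500 nt. Consequently an
intergenic region flanked by two 3′ ends (a *convergent* region) accumulates
twice the mass of a region downstream of a single 3′ end.

**DSBs.** DSBs form in promoter-containing intergenic regions. Each gene g
gets one promoter site `p_g` in its upstream intergenic region `[a, b]`:
midpoint for *tandem* regions (co-directional flanking genes), one-third in
from each gene's side for *divergent* regions (so the two sites sit at 1/3
and 2/3), and none at all in *convergent* regions, which contain no gene
start. If transcription-factor binding sites are supplied, their mean
position replaces the geometric placement. The curve is

    f_DSB(x) = Σ_g min(irl_g, IRL_max) · max(0, gc(p_g) − GC_min)² · K_σ(x − p_g)

with σ = 250 nt, where `irl_g` is the upstream intergenic-region length
capped at `IRL_max = μ_IRL + σ_IRL`, and `gc` is the σ = 1 kb
Gaussian-smoothed GC fraction floored at `GC_min = μ_GC − 3σ_GC`. Divergent
regions (two promoters) therefore carry twice the DSB mass of matched tandem
regions. Ablation variants 1–6 (DSB) and 1–3 (axis) drop individual factors
to measure their contribution.

Curves are reported in *normalized density* (1st percentile → 1, 99th → 99);
peaks are local maxima rising ≥ ε = 1 normalized unit above their flanking
minima.

## Worked example

Everything below runs offline on a seeded synthetic genome:

```sh
spore synth --n-chrom 1 --chrom-length 200000 \
            --gc blockwise:0.35,0.55:20000 --seed 11 --out demo
spore dsb   --genome demo/genome.fa --annotation demo/genes.tsv \
            --variant 6 --out demo/dsb.wig
spore axis  --genome demo/genome.fa --annotation demo/genes.tsv \
            --out demo/axis.wig
spore peaks --in demo/dsb.wig --out demo/dsb_peaks.bed
```

which prints

```
wrote demo/genome.fa and genes.tsv (96 genes, 1 chromosomes)
wrote demo/dsb.wig (IRL_max=1067 nt, GC_min=0.1721)
wrote demo/axis.wig (1 chromosomes)
wrote demo/dsb_peaks.bed (68 peaks)
```

`IRL_max` is the intergenic-length cap μ + σ computed on this genome (1067 nt
here; ~1.2 kb on budding yeast) and `GC_min` the GC floor μ − 3σ of the
smoothed GC track. The 96 genes yield 68 DSB peaks: convergent regions
produce no site, and nearby promoter sites merge under the σ = 250 nt kernel.
The WIG tracks load directly into any genome browser, and

```sh
spore evaluate --model demo/dsb.wig --experiment experiment.wig \
               --window 20000 --delta 1000
```

prints the four correlation coefficients and PPV/sensitivity at each Δ
(evaluating the model against itself gives 1.0 for every metric, a useful
smoke test). `spore run --config run.ini` executes the whole pipeline —
GC/axis/DSB tracks, peak BEDs, an ablation report TSV and a JSON summary —
into a run directory.

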