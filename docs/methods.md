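# Methods

## Coordinates, grids and smoothing

All coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
and WIG (1-based) are converted at the boundary. Model, GC and experimental
curves live on uniform grids with a default step of 10 nt — fine relative to
every kernel used (σ ≥ 250 nt for models, 1 kb for GC), and coarse enough
that a full yeast-sized genome fits comfortably in memory; step 1 is
available via configuration where exact integrals matter.

Smoothing convolves with a discrete Gaussian normalized to unit mass and
truncated at ±4σ (tail mass < 1e-4; results are stable to tighter
truncation). At chromosome ends the kernel mass falling outside the
chromosome is dropped, not renormalized, so densities decay toward telomeres
instead of being inflated there. The GC track is the exception: it is a
kernel-weighted *average* (ratio of two smoothed indicators), which
renormalizes automatically at ends and across N runs; N bases are excluded
from numerator and denominator, and runs of N wider than the kernel fall back
to the genome-mean GC. `place_gaussians` writes the model formula's
unnormalized bumps by default; model curves use the unit-area variant so that
the trapezoidal mass of a curve equals the summed site weights exactly — the
two differ only by a global scale, invisible to peaks, correlations and
normalized density.

## Axis model

Variant 3 (the full model) samples the per-gene ramp `(x − a)/(b − a)` on the
closed interval `[a, b]`, oriented by strand so it rises toward the stop
codon; overlapping genes sum (linearity; taking a maximum would break the
mass bookkeeping that makes the model testable). A `strand_naive` switch
reproduces the unoriented formula exactly for comparison. Variants 1–2 place
a single-sample impulse at each stop codon with value weight/step, making
impulse mass step-invariant. The trapezoidal integral of a gene's ramp at
step 1 is exactly length/2; after smoothing, interior genes conserve mass to
0.1%.

The optional noise floor adds the constant `c = (p99 − ratio·p1)/(ratio − 1)`
so the curve's 99th/1st-percentile ratio matches a target (3.5 emulates the
background of Red1 ChIP data); it is applied *after* smoothing because it
models background signal, not extra protein available for diffusion, and it
never moves peak positions. Negative `c` is clamped to 0.

## DSB model

Promoter sites: one per gene, in the intergenic region upstream of its start
codon. In the placement formula's interval `[a, b]`, `a` is the boundary
adjacent to the gene's own start codon, which is the only reading that puts
the two sites of a divergent region at 1/3 and 2/3 of it. Both genes of a
divergent region use the *full* region length as their `irl` (the length of
the region before the gene, not half of it). Border regions (chromosome end
to first/last gene) are treated like tandem regions: the single flanking gene
gets midpoint placement, preserving one promoter per gene. Genes with a
zero-length upstream region keep a degenerate site with `irl = 0` rather than
being dropped, so the one-site-per-gene invariant holds exactly. `gc(p_g)` is
read from the σ = 1 kb track by nearest-sample lookup (the grid step is two
orders of magnitude below σ, so interpolation is immaterial). Variant 5 uses
the same quadratic GC form as variant 6, with the IRL factor removed.

μ_IRL and σ_IRL are population moments of the lengths of interior (gene-to-
gene) intergenic regions; telomeric border gaps are excluded as they are not
intergenic in the model's sense. μ_GC/σ_GC are moments of the smoothed GC
curve over all grid points.

## Normalization, peaks and matching

Normalized density maps the genome-wide (all chromosomes pooled) 1st and 99th
percentiles — linear-interpolation order statistics — to 1 and 99. It is
invariant under positive affine transforms of the input, so the model-curve
scale convention never matters downstream.

A peak is a run-compressed local maximum exceeding its nearest flanking local
minima by ≥ ε on *both* sides (the stricter of the two possible readings);
chromosome ends count as minima, so an end maximum is never called. Plateaus
report their center sample. Candidate maxima failing the ε test do not merge
their neighbours' flanks: minima are defined on the raw landscape, which
keeps the rule local and lets a brute-force enumerator verify it exactly.

Matching predicted against reference peaks at tolerance Δ is independent per
peak, not one-to-one: sensitivity is the fraction of reference peaks with a
predicted peak within ±Δ, PPV the mirror image. Swapping the two lists swaps
the two metrics exactly.

## Correlations and baselines

Local correlation slides a 50 kb window by 10% of its size per chromosome,
correlating co-sampled points every 10 nt; the final value is the unweighted
mean over all windows of all chromosomes (window length would be an arbitrary
weight, and all interior windows are equal length anyway). Tail windows enter
iff at least half the window lies on the chromosome; zero-variance windows
are skipped and counted, since a correlation is undefined there.

The random baseline draws N positions uniformly — over the whole genome or
over the union of intergenic intervals — per simulation (default 1000),
scores each draw against the reference peaks, and reports best, mean, and the
95th percentile of the null (the "5% p-value" level). Everything is driven by
one `numpy.random.Generator` seed.

## Hotspot classification

Interval rule: hot iff the curve mean over the fragment is *strictly* greater
than the genome-wide curve mean. ORF-upstream rule: hot iff the mean over the
gene's upstream intergenic region is ≥ μ + σ (non-strict). The strict/
non-strict boundary semantics follow the respective rule definitions; on a
perfectly flat curve the first rule therefore calls nothing hot while the
second calls everything hot when σ = 0 — degenerate inputs documented rather
than special-cased. The GC-only predictor compares the maximum of the
smoothed GC curve over gene ∪ upstream region to μ_GC + σ_GC; a fixed 4 kb
window centered on the gene start is provided as a cross-check mode and
agrees on the test fixtures.

Coldspot sampling is rejection sampling with a cap of 10,000 attempts per
fragment (then a saturation error naming the chromosome): same chromosome and
length as the paired hotspot, exclusion-track signal ≤ `max_reads` (0, or 1
for genome-wide sampling where 0 is too stringent), and mutual disjointness.
ROC/AUC use all score thresholds and the trapezoid rule; AUC is checked in
tests against the Mann–Whitney U identity.

## Synthetic data

The generator emulates what the models consume: multi-chromosome genomes,
log-normal gene lengths (mean 1.5 kb, SD 0.8 kb), geometric intergenic gaps
whose mean follows the requested gene density (default 0.5 genes/kb → 500 nt
mean gap, loosely budding-yeast scale), strands i.i.d. Bernoulli or an
explicit orientation string, and uniform/blockwise/gradient GC profiles with
i.i.d. base draws. It does **not** emulate codon structure, binding motifs,
nucleosome patterning, chained gene overlaps or experimental artifacts
(probe-specific bias, mappability), so green tests certify the geometry and
arithmetic of the method, not its biological accuracy on real genomes — the
pinned external-data checks in `spore.external` exist for that, and require
downloading the genome releases. Pseudo-experimental tracks are model curves
plus white noise, optionally subsampled at exponentially spaced probe
positions to exercise the irregular-grid (Nadaraya–Watson) smoother, which is
flagged experimental because real tiling-array handling is data-specific.

Problem sizes in the test suite and acceptance script (2 × 300–500 kb
genomes, 1000-simulation baselines, 100-curve peak-calling sweeps) were
chosen so the full suite runs in well under a minute while keeping every
Monte-Carlo band at ≥ 3 SD; all are trivially scalable through the same APIs.

## Known limitations

- The models are annotation-geometric: species whose DSBs follow sequence
  motifs rather than promoter geometry will be predicted poorly by design.
- Peak positions are grid-resolution; no sub-grid interpolation.
- The WIG reader supports fixedStep only (variableStep raises), and BigWig is
  out of scope.
- `sample_coldspots` treats the exclusion track's sample values as read
  counts; fractional tracks work but make `max_reads` a density threshold.
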