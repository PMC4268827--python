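import numpy as np
import pytest

from spore.curves import DensityCurve
from spore.genome_io import GeneRecord, GeneSet, derive_intergenic_regions
from spore.synthetic_data import SyntheticGenomeSpec, generate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genes():
    """Five genes on one 20 kb chromosome covering all region classes."""
    recs = [
        GeneRecord("gA", "chr1", 1000, 2500, "+"),
        GeneRecord("gB", "chr1", 3500, 5000, "-"),   # gA/gB convergent
        GeneRecord("gC", "chr1", 6500, 8000, "+"),   # gB/gC divergent
        GeneRecord("gD", "chr1", 9000, 11000, "+"),  # gC/gD tandem
        GeneRecord("gE", "chr1", 13000, 15000, "-"), # gD/gE convergent
    ]
    return GeneSet(recs, {"chr1": 20000})


@pytest.fixture
def toy_regions(toy_genes):
    return derive_intergenic_regions(toy_genes)


@pytest.fixture
def random_curve(rng):
    return DensityCurve("chr1", 0, 10, rng.normal(5.0, 2.0, 1000))


@pytest.fixture(scope="session")
def small_genome():
    """Seeded 2×300 kb synthetic genome shared by slower tests."""
    spec = SyntheticGenomeSpec(n_chrom=2, chrom_length=300_000, seed=7)
    return generate_genome(spec)


def random_geneset(rng, n=50, chrom_length=200_000, chrom="chr1"):
    """Non-overlapping random genes for oracle comparisons."""
    starts = np.sort(rng.choice(np.arange(100, chrom_length - 3000, 200),
                                size=n, replace=False))
    recs = []
    prev_end = 0
    for i, s in enumerate(starts):
        s = max(int(s), prev_end + 10)
        length = int(rng.integers(200, 2500))
        e = min(s + length, chrom_length - 10)
        if e <= s:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        recs.append(GeneRecord(f"r{i}", chrom, s, e, strand))
        prev_end = e
    return GeneSet(recs, {chrom: chrom_length})
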