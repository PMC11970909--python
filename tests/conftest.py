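import numpy as np
import pytest

from cooccmap import GeneModel, GenomeAnnotation, Interval


def random_intervals(rng, n, n_chroms=2, span=10_000, max_len=400):
    """Uniform random intervals over a small genome (test helper)."""
    out = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(Interval(chrom, start, start + length))
    return out


def brute_force_pairs(set_a, set_b, min_bp=1):
    """All-pairs overlap oracle for intersect_sets."""
    from cooccmap import overlap_length

    return sorted(
        (i, j)
        for i, a in enumerate(set_a)
        for j, b in enumerate(set_b)
        if overlap_length(a, b) >= min_bp
    )


def make_gene(gene_id, chrom, strand, start, end, exons=()):
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        tx_start=start,
        tx_end=end,
        exons=[Interval(chrom, s, e) for s, e in exons],
    )


@pytest.fixture
def small_annotation():
    """Three genes on two chromosomes with exon structure."""
    genes = [
        make_gene("gA", "chr1", "+", 10_000, 20_000, [(10_000, 11_000), (15_000, 16_000)]),
        make_gene("gB", "chr1", "-", 40_000, 50_000, [(40_000, 42_000), (48_000, 50_000)]),
        make_gene("gC", "chr2", "+", 5_000, 9_000, [(5_000, 9_000)]),
    ]
    return GenomeAnnotation(
        genes=genes, chrom_sizes={"chr1": 100_000, "chr2": 50_000, "chr3": 10_000}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
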