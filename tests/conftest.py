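import numpy as np
import pytest

from grnprune.model import Gene, GenomicInterval, Peak


def brute_force_assign(peaks, genes, threshold):
    """All-pairs oracle for distance assignment: O(P x G), no indexing."""
    edges = set()
    for p in peaks:
        for g in genes:
            if g.chrom == p.interval.chrom and p.interval.distance_to(g.tss) <= threshold:
                edges.add((p.tf_id, g.gene_id))
    return edges


def random_assignment_fixture(seed, n_tfs=10, n_genes=100, n_peaks=500,
                              genome_size=200_000, n_chroms=2):
    """Random genes and peaks for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i+1}" for i in range(n_chroms)]
    genes = [
        Gene(
            f"g{i}", chroms[rng.integers(n_chroms)],
            "+" if rng.random() < 0.5 else "-",
            int(rng.integers(0, genome_size)),
        )
        for i in range(n_genes)
    ]
    peaks = []
    for _ in range(n_peaks):
        start = int(rng.integers(0, genome_size))
        width = int(rng.integers(50, 1000))
        tf = f"tf{rng.integers(n_tfs)}"
        peaks.append(Peak(GenomicInterval(chroms[rng.integers(n_chroms)], start,
                                          start + width), tf))
    return genes, peaks


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
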