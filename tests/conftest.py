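import numpy as np
import pytest

from flankscan.models import GeneModel
from flankscan.synthetic import SyntheticConfig, generate_annotation, generate_counts


@pytest.fixture(scope="session")
def small_cfg():
    """A small but complete cohort: a few lines of each allele class."""
    return SyntheticConfig(
        seed=11,
        n_chromosomes=2,
        chromosome_length=6_000_000,
        n_targets_del=4,
        n_targets_trap=3,
        n_tissues=2,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    genes, alleles = generate_annotation(small_cfg)
    counts, meta, pairs, truth = generate_counts(small_cfg, genes, alleles)
    return {
        "cfg": small_cfg,
        "genes": genes,
        "alleles": alleles,
        "counts": counts,
        "meta": meta,
        "pairs": pairs,
        "truth": truth,
    }


def random_gene(rng, chromosome="chr1", lo=1, hi=5_000_000, gene_id=None):
    start = int(rng.integers(lo, hi))
    length = int(rng.integers(1_000, 100_000))
    end = start + length
    n_ex = int(rng.integers(1, 6))
    bounds = np.sort(rng.choice(np.arange(start, end), size=2 * n_ex, replace=False))
    exons = tuple((int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_ex))
    exons = ((start, exons[0][1]),) + exons[1:-1] + ((exons[-1][0], end),) if n_ex > 1 else ((start, end),)
    return GeneModel(
        gene_id=gene_id or f"g{int(rng.integers(0, 10**9))}",
        chromosome=chromosome,
        start=start,
        end=end,
        strand="+" if rng.random() < 0.5 else "-",
        exons=exons,
        biotype="protein_coding",
    )
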