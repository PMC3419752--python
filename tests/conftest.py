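import numpy as np
import pytest

from tempopg.genepop import GenotypeTable, SampleSet


def sample_from_genotype_counts(
    pop: str,
    genotype_counts: dict[tuple[int, int], int],
    locus: str = "L1",
    era: str = "historical",
    years: tuple[int, int] = (2000, 2000),
) -> SampleSet:
    """Single-locus sample built from genotype -> count pairs."""
    calls = []
    for (a, b), k in genotype_counts.items():
        calls.extend([[[a, b]]] * k)
    calls = np.array(calls, dtype=np.int32)
    n = len(calls)
    table = GenotypeTable(
        [locus], [f"{pop}_{i}" for i in range(n)], [pop] * n, calls
    )
    return SampleSet(pop, era, years, table)


def hwe_sample(
    freqs: np.ndarray,
    n: int,
    seed: int,
    pop: str = "p",
    era: str = "historical",
    years: tuple[int, int] = (2000, 2000),
    locus_names: list[str] | None = None,
) -> SampleSet:
    """Multi-locus HWE sample from an (L, K) frequency array."""
    from tempopg.synthetic import sample_genotypes

    s = sample_genotypes(
        np.atleast_2d(freqs), n, seed=seed, population=pop, era=era,
        years=years, locus_names=locus_names,
    )
    return s


def random_table(
    rng: np.random.Generator,
    n_ind: int,
    n_loci: int,
    n_pops: int = 2,
    max_code: int = 99,
    missing_rate: float = 0.05,
) -> GenotypeTable:
    calls = rng.integers(1, max_code + 1, size=(n_ind, n_loci, 2)).astype(np.int32)
    mask = rng.random((n_ind, n_loci)) < missing_rate
    calls[mask] = -1
    bounds = np.sort(rng.choice(np.arange(1, n_ind), size=n_pops - 1, replace=False))
    labels = []
    pop = 0
    for i in range(n_ind):
        if pop < len(bounds) and i >= bounds[pop]:
            pop += 1
        labels.append(f"pop{pop + 1}")
    return GenotypeTable(
        [f"loc{j}" for j in range(n_loci)],
        [f"ind{i}" for i in range(n_ind)],
        labels,
        calls,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
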