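"""Synthetic temporal studies with farm-introgression structure.

The generator emulates the statistical shape of a country-wide riverine
study of an anadromous salmonid exposed to aquaculture escapees: ~21
hierarchically structured wild river populations genotyped at ~22
multiallelic microsatellite-like loci (global theta ~ 0.03-0.06), a handful
of genetically distinct domesticated "farm strains" created by founder
bottlenecks from mixtures of the wild gene pools, and per-river,
per-generation introgression fractions that blend a dynamic mixture of farm
strains into the wild allele frequencies.

Simulation is at the allele-frequency level: wild population frequencies
are Dirichlet draws around ancestral frequencies (a Balding-Nichols-style
F model), each generation applies binomial drift at the wild Ne followed by
deterministic admixture with the current farm mixture, and genotypes are
finally sampled under HWE at configured census years.  A truth record of
the per-river introgression fractions accompanies every study for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genepop import GenotypeTable, SampleSet, TemporalStudy, build_temporal_study

__all__ = [
    "ScenarioConfig",
    "make_wild_baseline",
    "make_farm_strains",
    "evolve_with_introgression",
    "sample_genotypes",
    "scenario_study",
]


@dataclass
class ScenarioConfig:
    """Study-scale defaults mirror the emulated survey design.

    ``introgression`` maps population index -> per-generation admixture
    fraction m (default 0 everywhere); ``era_years`` gives the sampling
    year per era; sample sizes are drawn uniformly from ``sample_size_range``
    unless ``sample_sizes`` pins them per (population index, era).
    """

    n_populations: int = 21
    n_loci: int = 22
    alleles_per_locus: tuple[int, int] = (5, 15)
    target_global_fst: float = 0.04
    n_farm_strains: int = 9
    farm_bottleneck_ne: int = 30
    farm_bottleneck_generations: int = 8
    wild_ne: int = 500
    introgression: Mapping[int, float] = field(default_factory=dict)
    era_years: Mapping[str, int] = field(
        default_factory=lambda: {"historical": 1980, "contemporary": 2010}
    )
    generation_years: int = 5
    sample_size_range: tuple[int, int] = (16, 106)
    sample_sizes: Mapping[tuple[int, str], int] | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 2:
            raise ValueError("need at least 2 loci")
        for m in self.introgression.values():
            if not 0 <= m <= 1:
                raise ValueError("introgression fractions must lie in [0, 1]")
        if self.sample_size_range[0] < 2:
            raise ValueError("sample sizes must be >= 2")


def _parametric_theta(freqs: np.ndarray) -> float:
    """Frequency-level F_ST: among-pop variance over pbar(1-pbar), pooled."""
    num = 0.0
    den = 0.0
    for j in range(freqs.shape[1]):
        p = freqs[:, j, :]
        p = p[:, ~np.isnan(p[0])] if np.isnan(p).any() else p
        pbar = p.mean(axis=0)
        num += (p.var(axis=0, ddof=0)).sum()
        den += (pbar * (1 - pbar)).sum()
    return num / den if den > 0 else float("nan")


def make_wild_baseline(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Per-population per-locus allele frequencies, (P, L, K_max).

    Ancestral frequencies per locus come from a symmetric Dirichlet over a
    random allele count in ``alleles_per_locus``; population frequencies
    from Dirichlet(ancestral * (1-F)/F).  F starts at the target theta and
    is rescaled (a few iterations) until the parametric global theta of the
    drawn frequencies lands within +-0.005 of ``target_global_fst``.
    Unused allele slots (loci with fewer alleles than K_max) are zero.
    """
    rng = rng or np.random.default_rng(config.seed)
    if not (0 < config.target_global_fst < 1):
        raise ValueError("target_global_fst must be in (0, 1)")
    kmin, kmax = config.alleles_per_locus
    k_per_locus = rng.integers(kmin, kmax + 1, size=config.n_loci)
    K = int(k_per_locus.max())
    ancestral = np.zeros((config.n_loci, K))
    for j, k in enumerate(k_per_locus):
        ancestral[j, :k] = rng.dirichlet(np.ones(k))
    f = config.target_global_fst
    if config.n_populations < 2:
        lam = (1 - f) / f
        freqs = np.zeros((1, config.n_loci, K))
        for j, k in enumerate(k_per_locus):
            alpha = np.maximum(ancestral[j, :k] * lam, 1e-6)
            freqs[:, j, :k] = rng.dirichlet(alpha, size=1)
        return freqs
    for _ in range(20):
        lam = (1 - f) / f
        freqs = np.zeros((config.n_populations, config.n_loci, K))
        for j, k in enumerate(k_per_locus):
            alpha = np.maximum(ancestral[j, :k] * lam, 1e-6)
            freqs[:, j, :k] = rng.dirichlet(alpha, size=config.n_populations)
        theta = _parametric_theta(freqs)
        if abs(theta - config.target_global_fst) <= 0.005:
            return freqs
        f = f * config.target_global_fst / theta
        if not 0 < f < 1:
            raise ValueError("target global F_ST unreachable")
    return freqs


def make_farm_strains(
    config: ScenarioConfig,
    wild: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Farm-strain frequencies (n_strains, L, K_max) via founder bottlenecks.

    Each strain starts from a random Dirichlet-weighted mixture of the wild
    baselines, then drifts ``farm_bottleneck_generations`` generations at
    the small ``farm_bottleneck_ne`` — founder effects make strains distinct
    from each other while keeping their alleles within the wild repertoire.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    P, L, K = wild.shape
    strains = np.zeros((config.n_farm_strains, L, K))
    two_n = 2 * config.farm_bottleneck_ne
    for s in range(config.n_farm_strains):
        w = rng.dirichlet(np.ones(P))
        p = np.einsum("p,plk->lk", w, wild)
        for _ in range(config.farm_bottleneck_generations):
            for j in range(L):
                tot = p[j].sum()
                if tot <= 0:
                    continue
                counts = rng.multinomial(two_n, p[j] / tot)
                p[j] = counts / two_n
        strains[s] = p
    return strains


def evolve_with_introgression(
    wild: np.ndarray,
    farms: np.ndarray,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Per-era frequency snapshots under drift plus farm admixture.

    Each generation every population first drifts (binomial resampling of
    2*wild_ne gene copies) and is then blended with the current farm
    mixture: p <- (1-m) p + m q, where q is the mean of a random subset of
    strains (the strain composition of escapees shifts through time).
    Snapshots are taken at the era years on a ``generation_years`` clock
    starting at the historical year.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    P, L, K = wild.shape
    years = dict(config.era_years)
    if "historical" not in years:
        raise ValueError("era_years must include 'historical'")
    y0 = years["historical"]
    horizon = max(years.values())
    n_gen = int(np.ceil((horizon - y0) / config.generation_years))
    snapshots: dict[str, np.ndarray] = {}
    p = wild.copy()
    for era, y in years.items():
        if y == y0:
            snapshots[era] = p.copy()
    two_n = 2 * config.wild_ne
    for g in range(1, n_gen + 1):
        # drift
        for i in range(P):
            m_i = config.introgression.get(i, 0.0)
            for j in range(L):
                tot = p[i, j].sum()
                if tot <= 0:
                    continue
                counts = rng.multinomial(two_n, p[i, j] / tot)
                p[i, j] = counts / two_n
            if m_i > 0:
                n_src = rng.integers(1, farms.shape[0] + 1)
                src = rng.choice(farms.shape[0], size=n_src, replace=False)
                q = farms[src].mean(axis=0)
                p[i] = (1 - m_i) * p[i] + m_i * q
        year_now = y0 + g * config.generation_years
        for era, y in years.items():
            if y0 + (g - 1) * config.generation_years < y <= year_now:
                snapshots[era] = p.copy()
    return snapshots


def sample_genotypes(
    frequencies: np.ndarray,
    n: int,
    seed: int | np.random.Generator = 0,
    population: str = "pop",
    era: str = "historical",
    years: tuple[int, int] | None = None,
    locus_names: Sequence[str] | None = None,
    missing_rate: float = 0.0,
) -> SampleSet:
    """Draw n diploid individuals under HWE from (L, K) frequencies.

    Allele codes are 1-based column indices (code = slot + 1) so tables
    round-trip through 2-digit GenePop when K <= 98.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    L, K = frequencies.shape
    names = list(locus_names) if locus_names is not None else [f"L{j+1:02d}" for j in range(L)]
    calls = np.zeros((n, L, 2), dtype=np.int32)
    for j in range(L):
        p = frequencies[j]
        tot = p.sum()
        if tot <= 0:
            raise ValueError(f"locus {j} has no frequency mass")
        draws = rng.choice(K, size=(n, 2), p=p / tot)
        calls[:, j, :] = draws + 1
    if missing_rate > 0:
        mask = rng.random((n, L)) < missing_rate
        calls[mask] = -1
    table = GenotypeTable(
        locus_names=names,
        individual_ids=[f"{population}_{era}_{i}" for i in range(n)],
        population_labels=[population] * n,
        calls=calls,
    )
    yr = years if years is not None else (2000, 2000)
    return SampleSet(population, era, yr, table)


@dataclass
class SyntheticTruth:
    introgression: dict[str, float]
    target_global_fst: float
    era_years: dict[str, int]


def scenario_study(
    config: ScenarioConfig | None = None,
) -> tuple[TemporalStudy, SyntheticTruth]:
    """End-to-end synthetic study plus its truth record."""
    config = config or ScenarioConfig()
    rng = np.random.default_rng(config.seed)
    wild = make_wild_baseline(config, rng)
    farms = make_farm_strains(config, wild, rng)
    snapshots = evolve_with_introgression(wild, farms, config, rng)
    locus_names = [f"L{j+1:02d}" for j in range(config.n_loci)]
    pops = [f"river{i+1:02d}" for i in range(config.n_populations)]
    samples = []
    for era, year in config.era_years.items():
        for i, pop in enumerate(pops):
            if config.sample_sizes is not None and (i, era) in config.sample_sizes:
                n = config.sample_sizes[(i, era)]
            else:
                n = int(rng.integers(config.sample_size_range[0], config.sample_size_range[1] + 1))
            samples.append(
                sample_genotypes(
                    snapshots[era][i],
                    n,
                    seed=rng,
                    population=pop,
                    era=era,
                    years=(year, year),
                    locus_names=locus_names,
                    missing_rate=config.missing_rate,
                )
            )
    truth = SyntheticTruth(
        introgression={pops[i]: config.introgression.get(i, 0.0) for i in range(len(pops))},
        target_global_fst=config.target_global_fst,
        era_years=dict(config.era_years),
    )
    return build_temporal_study(samples), truth
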