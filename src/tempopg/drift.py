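"""Gene-dropping drift null for observed temporal change.

The question answered here: could pure genetic drift, acting alone over the
generations separating a river's historical and contemporary samples,
plausibly have produced the temporal F_ST actually observed?  Starting from
the historical sample's allele frequencies, an idealised Wright–Fisher
population of ``Ne`` diploids (equal sex halves, random mating, discrete
generations, no migration/selection/mutation, unlinked loci) is dropped
forward G generations; a pseudo-sample the size of the contemporary one is
then drawn and its theta against the observed historical sample computed.
Repeating this over a grid of Ne values yields an exceedance p-value per
Ne: the fraction of simulated replicates whose theta is at least the
observed one.  Small p at a given Ne means drift of that strength cannot
explain the change.

The same machinery provides drift-conditioned distributions of the global
theta among a set of rivers and of rarefied allelic richness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._counts import LocusRegistry
from .diversity import _rarefy, rarefied_richness
from .fst import _theta_from_counts
from .genepop import GenotypeTable, SampleSet, TemporalStudy

__all__ = [
    "DriftConfig",
    "DriftResult",
    "generations_between",
    "gene_drop",
    "drift_pvalue",
    "drift_global_fst",
    "drift_allelic_richness",
]

DEFAULT_NE_GRID = (25, 50, 75, 100, 200, 300, 400, 500)


@dataclass
class DriftConfig:
    """Grid and replication settings for the drift null.

    ``generation_years`` converts calendar spans to generations (ceil rule,
    minimum one generation).  The population splits into equal sex halves;
    an odd Ne gets the extra individual on the male side.
    """

    ne_grid: tuple[int, ...] = DEFAULT_NE_GRID
    replicates: int = 1000
    generation_years: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for ne in self.ne_grid:
            if ne < 2:
                raise ValueError("every Ne must be >= 2")
        if self.replicates < 100:
            raise ValueError("need at least 100 replicates")


@dataclass
class DriftResult:
    population: str | None
    ne_grid: tuple[int, ...]
    observed: float
    simulated: dict[int, np.ndarray]       # Ne -> per-replicate statistic
    p_exceed: dict[int, float] | None = None
    generations: int | None = None

    def p_string(self, ne: int) -> str:
        """Table-style rendering: '<1/replicates' when no exceedances."""
        p = self.p_exceed[ne]
        n = len(self.simulated[ne])
        return f"<{1 / n:g}" if p == 0 else f"{p:.3g}"


def generations_between(
    hist_years: tuple[int, int],
    contemp_years: tuple[int, int],
    generation_years: int = 5,
) -> int:
    """ceil((contemporary midpoint - historical midpoint) / generation), >= 1.

    Multi-year sampling windows are reduced to midpoint years (rounded
    down).
    """
    h = (hist_years[0] + hist_years[1]) // 2
    c = (contemp_years[0] + contemp_years[1]) // 2
    if c < h:
        raise ValueError("contemporary sample predates historical sample")
    return max(1, math.ceil((c - h) / generation_years))


def _historical_freqs(
    historical: SampleSet, reg: LocusRegistry
) -> tuple[list[np.ndarray], list[int]]:
    """Per-locus frequency vectors; loci with no data dropped (warned)."""
    enc = reg.encode(historical.genotypes.calls)
    freqs = reg.frequencies(enc)
    keep = []
    dropped = []
    for j, f in enumerate(freqs):
        if np.isnan(f).any():
            dropped.append(reg.locus_names[j])
        else:
            keep.append(j)
    if dropped:
        warnings.warn(f"loci without historical data dropped: {dropped}", stacklevel=2)
    return [freqs[j] for j in keep], keep


def _drop_replicates(
    freqs: list[np.ndarray],
    ne: int,
    generations: int,
    out_n: int,
    replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate R replicates at once; returns (R, out_n, L, 2) allele indices.

    Founders draw alleles iid from the historical frequencies; each next
    generation samples a random mother from the first Ne/2 individuals and a
    random father from the rest, inheriting one uniformly chosen allele per
    parent per locus.  Final sampling is without replacement when
    ``out_n <= ne``, else with replacement.
    """
    L = len(freqs)
    R = replicates
    cur = np.empty((R, ne, L, 2), dtype=np.int16)
    for j, p in enumerate(freqs):
        cur[:, :, j, :] = rng.choice(len(p), size=(R, ne, 2), p=p)
    half = ne // 2
    ridx = np.arange(R)[:, None, None]
    lidx = np.arange(L)[None, None, :]
    for _ in range(generations):
        mothers = rng.integers(0, half, size=(R, ne))[:, :, None]
        fathers = rng.integers(half, ne, size=(R, ne))[:, :, None]
        mbit = rng.integers(0, 2, size=(R, ne, L))
        fbit = rng.integers(0, 2, size=(R, ne, L))
        nxt = np.empty_like(cur)
        nxt[:, :, :, 0] = cur[ridx, mothers, lidx, mbit]
        nxt[:, :, :, 1] = cur[ridx, fathers, lidx, fbit]
        cur = nxt
    if out_n <= ne:
        pick = np.argsort(rng.random((R, ne)), axis=1)[:, :out_n]
    else:
        pick = rng.integers(0, ne, size=(R, out_n))
    return np.take_along_axis(cur, pick[:, :, None, None], axis=1)


def gene_drop(
    historical: SampleSet,
    ne: int,
    generations: int,
    out_n: int,
    seed: int | np.random.Generator = 0,
) -> SampleSet:
    """One simulated contemporary sample after G generations of drift."""
    if ne < 2:
        raise ValueError("Ne must be >= 2")
    if out_n < 2:
        raise ValueError("out_n must be >= 2")
    rng = np.random.default_rng(seed)
    reg = LocusRegistry.from_tables([historical.genotypes])
    freqs, keep = _historical_freqs(historical, reg)
    sim = _drop_replicates(freqs, ne, generations, out_n, 1, rng)[0]
    codes = np.empty_like(sim, dtype=np.int32)
    for jj, j in enumerate(keep):
        codes[:, jj, :] = reg.alleles[j][sim[:, jj, :]]
    table = GenotypeTable(
        locus_names=[reg.locus_names[j] for j in keep],
        individual_ids=[f"sim{i}" for i in range(out_n)],
        population_labels=[historical.population] * out_n,
        calls=codes,
    )
    if out_n > ne:
        warnings.warn("out_n exceeds Ne; sampled with replacement", stacklevel=2)
    return SampleSet(historical.population, "contemporary", historical.years, table)


def _sim_counts(
    sim: np.ndarray, keep: list[int], reg: LocusRegistry
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Counts for one simulated sample, mapped onto the full registry axes."""
    out_n, Lk, _ = sim.shape
    n = np.zeros(len(reg.k), dtype=np.int64)
    ac = np.zeros(reg.total)
    hc = np.zeros(reg.total)
    for jj, j in enumerate(keep):
        off = reg.offsets[j]
        pair = sim[:, jj, :]
        ac[off : reg.offsets[j + 1]] = np.bincount(
            pair.ravel(), minlength=reg.k[j]
        )
        het = pair[:, 0] != pair[:, 1]
        hflat = pair[het].ravel()
        hc[off : reg.offsets[j + 1]] = np.bincount(hflat, minlength=reg.k[j])
        n[j] = out_n
    return n, ac, hc


def drift_pvalue(
    study: TemporalStudy,
    population: str,
    config: DriftConfig | None = None,
) -> DriftResult:
    """Exceedance p of the observed temporal theta under drift per Ne.

    For each Ne on the grid: gene-drop ``replicates`` contemporary samples
    of the observed contemporary size, compute theta between the observed
    historical sample and each, and report the fraction with simulated
    theta >= observed.
    """
    config = config or DriftConfig()
    hist = study.get(population, "historical")
    contemp = study.get(population, "contemporary")
    G = generations_between(hist.years, contemp.years, config.generation_years)
    reg = LocusRegistry.from_tables([hist.genotypes, contemp.genotypes])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        freqs, keep = _historical_freqs(hist, reg)
        henc = reg.encode(hist.genotypes.calls)
        hn, hac, hhc = reg.counts(henc)
        cenc = reg.encode(contemp.genotypes.calls)
        cn, cac, chc = reg.counts(cenc)
        observed = _theta_from_counts(
            np.stack([hn, cn]),
            np.stack([hac, cac]).astype(float),
            np.stack([hhc, chc]).astype(float),
            reg,
        )
    rng = np.random.default_rng(config.seed)
    simulated: dict[int, np.ndarray] = {}
    p_exceed: dict[int, float] = {}
    for ne in config.ne_grid:
        sims = _drop_replicates(freqs, ne, G, contemp.n, config.replicates, rng)
        thetas = np.empty(config.replicates)
        for r in range(config.replicates):
            sn, sac, shc = _sim_counts(sims[r], keep, reg)
            thetas[r] = _theta_from_counts(
                np.stack([hn, sn]),
                np.stack([hac, sac]).astype(float),
                np.stack([hhc, shc]).astype(float),
                reg,
            )
        simulated[ne] = thetas
        p_exceed[ne] = float((thetas >= observed).mean())
    return DriftResult(
        population, tuple(config.ne_grid), observed, simulated, p_exceed, G
    )


def drift_global_fst(
    study: TemporalStudy,
    populations: list[str],
    config: DriftConfig | None = None,
) -> tuple[dict[int, np.ndarray], float, float]:
    """Global theta among independently drifted rivers, per Ne.

    Each river is gene-dropped from its own historical sample for its own
    generation count; per replicate the global theta among the simulated
    contemporaries is computed.  Returns (per-Ne distributions, observed
    historical global theta, observed contemporary global theta).
    """
    if len(populations) < 2:
        raise ValueError("need at least two populations")
    config = config or DriftConfig()
    hists = [study.get(p, "historical") for p in populations]
    contemps = [study.get(p, "contemporary") for p in populations]
    reg = LocusRegistry.from_tables([s.genotypes for s in hists + contemps])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prep = []
        for h, c in zip(hists, contemps):
            freqs, keep = _historical_freqs(h, reg)
            G = generations_between(h.years, c.years, config.generation_years)
            prep.append((freqs, keep, G, c.n))

        def stack_theta(samples_counts):
            n = np.stack([x[0] for x in samples_counts])
            ac = np.stack([x[1] for x in samples_counts]).astype(float)
            hc = np.stack([x[2] for x in samples_counts]).astype(float)
            return _theta_from_counts(n, ac, hc, reg)

        obs_hist = stack_theta([reg.counts(reg.encode(s.genotypes.calls)) for s in hists])
        obs_contemp = stack_theta(
            [reg.counts(reg.encode(s.genotypes.calls)) for s in contemps]
        )
    rng = np.random.default_rng(config.seed)
    out: dict[int, np.ndarray] = {}
    for ne in config.ne_grid:
        per_pop_sims = [
            _drop_replicates(freqs, ne, G, out_n, config.replicates, rng)
            for freqs, keep, G, out_n in prep
        ]
        thetas = np.empty(config.replicates)
        for r in range(config.replicates):
            counts = [
                _sim_counts(per_pop_sims[i][r], prep[i][1], reg)
                for i in range(len(populations))
            ]
            thetas[r] = stack_theta(counts)
        out[ne] = thetas
    return out, obs_hist, obs_contemp


def drift_allelic_richness(
    study: TemporalStudy,
    population: str,
    config: DriftConfig | None = None,
    rarefaction_genes: int = 50,
) -> tuple[dict[int, np.ndarray], float, float]:
    """Distribution of simulated contemporary A_R totals per Ne.

    A_R uses the same hypergeometric rarefaction as the diversity module
    (default 50 gene copies = 25 diploids), summed over loci.  Returns
    (per-Ne distributions, observed historical total, observed contemporary
    total).
    """
    config = config or DriftConfig()
    hist = study.get(population, "historical")
    contemp = study.get(population, "contemporary")
    G = generations_between(hist.years, contemp.years, config.generation_years)
    reg = LocusRegistry.from_tables([hist.genotypes, contemp.genotypes])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        freqs, keep = _historical_freqs(hist, reg)

    def ar_total_from_sample(s: SampleSet) -> float:
        from .diversity import allele_counts

        act = allele_counts(s)
        ar = rarefied_richness(act, rarefaction_genes)
        return float(np.nansum(ar))

    obs_h = ar_total_from_sample(hist)
    obs_c = ar_total_from_sample(contemp)
    rng = np.random.default_rng(config.seed)
    out: dict[int, np.ndarray] = {}
    for ne in config.ne_grid:
        sims = _drop_replicates(freqs, ne, G, contemp.n, config.replicates, rng)
        totals = np.empty(config.replicates)
        for r in range(config.replicates):
            tot = 0.0
            for jj, j in enumerate(keep):
                cnt = np.bincount(sims[r, :, jj, :].ravel(), minlength=reg.k[j])
                cnt = cnt[cnt > 0]
                if cnt.sum() >= rarefaction_genes:
                    tot += _rarefy(cnt, rarefaction_genes)
            totals[r] = tot
        out[ne] = totals
    return out, obs_h, obs_c
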