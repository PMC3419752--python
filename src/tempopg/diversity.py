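"""Within-sample diversity statistics and exact tests.

Covers allele counting, observed/expected heterozygosity, F_IS, rarefied
allelic richness, the Guo–Thompson Markov-chain exact test for Hardy–Weinberg
proportions and a conditional exact test for genotypic linkage
disequilibrium.

Allelic richness uses hypergeometric rarefaction: the expected number of
distinct alleles in a random subsample of ``g`` gene copies,

    A_R = sum_a [ 1 - C(n - c_a, g) / C(n, g) ],

which standardises allele counts across unequal sample sizes.  Expected
heterozygosity uses the small-sample-unbiased estimator
``(n/(n-1)) * (1 - sum p^2)`` on gene copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .genepop import MISSING, SampleSet

__all__ = [
    "AlleleCountTable",
    "DiversitySummary",
    "ExactTestResult",
    "allele_counts",
    "diversity_summary",
    "rarefied_richness",
    "hwe_exact_mc",
    "ld_exact_mc",
]

#: default exact-test chain: (dememorisation, batches, iterations per batch)
DEFAULT_CHAIN = (10000, 1000, 10000)


@dataclass
class AlleleCountTable:
    """Per-locus gene-copy counts (missing calls excluded)."""

    locus_names: list[str]
    counts: list[dict[int, int]]
    n_genes: np.ndarray

    def frequencies(self, locus: int) -> dict[int, float]:
        n = self.n_genes[locus]
        if n == 0:
            return {}
        return {a: c / n for a, c in self.counts[locus].items()}


@dataclass
class DiversitySummary:
    locus_names: list[str]
    ho: np.ndarray
    he: np.ndarray
    fis: np.ndarray
    a_obs: np.ndarray
    a_r: np.ndarray
    rarefaction_genes: int
    a_r_qualifies: np.ndarray

    @property
    def a_r_total(self) -> float:
        """Sum of per-locus rarefied richness over qualifying loci."""
        return float(np.nansum(np.where(self.a_r_qualifies, self.a_r, np.nan)))


@dataclass
class ExactTestResult:
    p_value: float
    mc_se: float
    chain: tuple[int, int, int]
    applicable: bool = True


def allele_counts(sample: SampleSet) -> AlleleCountTable:
    """Tally gene copies per allele per locus, excluding missing calls.

    A locus with zero non-missing copies is kept with an empty count map
    (frequency undefined there, flagged by ``n_genes == 0``).
    """
    calls = sample.genotypes.calls
    if calls.shape[0] < 1:
        raise ValueError("sample has no individuals")
    loci = sample.genotypes.locus_names
    counts: list[dict[int, int]] = []
    n_genes = np.zeros(len(loci), dtype=np.int64)
    for j in range(len(loci)):
        col = calls[:, j, :].ravel()
        col = col[col != MISSING]
        vals, cnt = np.unique(col, return_counts=True)
        counts.append({int(v): int(c) for v, c in zip(vals, cnt)})
        n_genes[j] = col.size
    return AlleleCountTable(list(loci), counts, n_genes)


def _rarefy(counts: np.ndarray, g: int) -> float:
    """Expected distinct alleles in a subsample of g gene copies."""
    n = counts.sum()
    if g > n:
        return float("nan")
    # log C(n-c, g) - log C(n, g), guarding c > n - g (term contributes 1)
    def logcomb(a: np.ndarray, b: int) -> np.ndarray:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    rest = n - counts
    keep = rest >= g
    out = np.ones(len(counts))
    if keep.any():
        ratio = np.exp(logcomb(rest[keep].astype(float), g) - logcomb(float(n), g))
        out[keep] = 1.0 - ratio
    return float(out.sum())


def rarefied_richness(table: AlleleCountTable, g_genes: int) -> np.ndarray:
    """Per-locus hypergeometric rarefaction at ``g_genes`` gene copies."""
    if g_genes < 2:
        raise ValueError("rarefaction size must be at least 2 gene copies")
    out = np.full(len(table.locus_names), np.nan)
    for j, cmap in enumerate(table.counts):
        if not cmap:
            continue
        out[j] = _rarefy(np.array(list(cmap.values()), dtype=np.int64), g_genes)
    return out


def diversity_summary(
    sample: SampleSet,
    rarefaction_g: int = 25,
    rarefaction_unit: str = "individuals",
) -> DiversitySummary:
    """Ho, He (unbiased), F_IS, observed and rarefied allele counts.

    ``rarefaction_g`` follows the MSA-style convention of counting diploid
    *individuals* by default (25 individuals = 50 gene copies); pass
    ``rarefaction_unit="genes"`` to interpret it as gene copies directly.
    Loci whose non-missing gene-copy count is below the rarefaction size get
    ``a_r_qualifies = False`` and NaN richness.
    """
    if rarefaction_unit not in ("individuals", "genes"):
        raise ValueError("rarefaction_unit must be 'individuals' or 'genes'")
    g_genes = 2 * rarefaction_g if rarefaction_unit == "individuals" else rarefaction_g
    if g_genes < 2:
        raise ValueError("rarefaction size must be at least 2 gene copies")

    act = allele_counts(sample)
    calls = sample.genotypes.calls
    L = len(act.locus_names)
    ho = np.full(L, np.nan)
    he = np.full(L, np.nan)
    fis = np.full(L, np.nan)
    a_obs = np.zeros(L, dtype=np.int64)
    for j in range(L):
        cmap = act.counts[j]
        a_obs[j] = len(cmap)
        n = act.n_genes[j]
        if n == 0:
            continue
        col = calls[:, j, :]
        ok = col[:, 0] != MISSING
        ho[j] = float((col[ok, 0] != col[ok, 1]).mean()) if ok.any() else np.nan
        p = np.array(list(cmap.values()), dtype=float) / n
        if n > 1:
            he[j] = (n / (n - 1)) * (1.0 - float((p**2).sum()))
        if he[j] and he[j] > 0:
            fis[j] = 1.0 - ho[j] / he[j]
    a_r = rarefied_richness(act, g_genes)
    qualifies = act.n_genes >= g_genes
    return DiversitySummary(
        list(act.locus_names), ho, he, fis, a_obs, a_r, g_genes, qualifies
    )


# ---------------------------------------------------------------------------
# Guo & Thompson Markov-chain exact test for Hardy-Weinberg proportions


def _hwe_log_prob_terms(counts: dict[tuple[int, int], int]) -> tuple[float, int]:
    """(sum log n_uv!, number of heterozygotes) for a genotype count table."""
    s = 0.0
    het = 0
    for (u, v), c in counts.items():
        s += math.lgamma(c + 1)
        if u != v:
            het += c
    return s, het

_LOG2 = math.log(2.0)


def hwe_exact_mc(
    sample: SampleSet,
    locus: str,
    chain: tuple[int, int, int] = DEFAULT_CHAIN,
    seed: int | np.random.Generator = 0,
) -> ExactTestResult:
    """Markov-chain exact test of Hardy–Weinberg proportions at one locus.

    The null fixes the observed allele counts; conditionally on them, every
    arrangement of the 2n gene copies into n ordered pairs is equally likely
    under random union of gametes.  The chain therefore swaps two uniformly
    chosen gene-copy positions per step — a symmetric proposal whose
    stationary law is exactly that uniform arrangement distribution, and
    whose induced genotype-table law is the exact-test null
    P(T) = n! 2^H prod_u(n_u!) / (prod_uv(n_uv!) (2n)!).  The p-value is the
    stationary probability of tables no more probable than the observed one
    (probability-ordering criterion).  ``chain = (dememorisation, batches,
    iterations per batch)``; the Monte-Carlo standard error comes from the
    batch means.
    """
    rng = np.random.default_rng(seed)
    j = sample.genotypes.locus_names.index(locus)
    col = sample.genotypes.calls[:, j, :]
    col = col[col[:, 0] != MISSING]
    copies = col.ravel().tolist()
    alleles = set(copies)
    if len(alleles) < 2:
        return ExactTestResult(float("nan"), 0.0, chain, applicable=False)

    counts: dict[tuple[int, int], int] = {}
    for i in range(0, len(copies), 2):
        g = (copies[i], copies[i + 1]) if copies[i] <= copies[i + 1] else (
            copies[i + 1], copies[i]
        )
        counts[g] = counts.get(g, 0) + 1
    # log pi(T) = H log2 - sum log n_uv! + const; track relative to observed
    log_rel = 0.0
    two_n = len(copies)
    demem, n_batches, iters = chain

    def cell(p1: int) -> tuple[int, int]:
        base = (p1 // 2) * 2
        a, b = copies[base], copies[base + 1]
        return (a, b) if a <= b else (b, a)

    def step() -> float:
        nonlocal log_rel
        p1 = int(rng.integers(two_n))
        p2 = int(rng.integers(two_n - 1))
        if p2 >= p1:
            p2 += 1
        if copies[p1] == copies[p2] or p1 // 2 == p2 // 2:
            if p1 // 2 == p2 // 2:
                copies[p1], copies[p2] = copies[p2], copies[p1]
            return log_rel
        old1, old2 = cell(p1), cell(p2)
        copies[p1], copies[p2] = copies[p2], copies[p1]
        new1, new2 = cell(p1), cell(p2)
        delta = 0.0
        for g in (old1, old2):
            c = counts[g]
            delta += math.log(c)
            if g[0] != g[1]:
                delta -= _LOG2
            counts[g] = c - 1
            if counts[g] == 0:
                del counts[g]
        for g in (new1, new2):
            c = counts.get(g, 0)
            delta -= math.log(c + 1)
            if g[0] != g[1]:
                delta += _LOG2
            counts[g] = c + 1
        log_rel += delta
        return log_rel

    for _ in range(demem):
        step()
    batch_means = np.empty(n_batches)
    for b in range(n_batches):
        hits = 0
        for _ in range(iters):
            if step() <= 1e-9:
                hits += 1
        batch_means[b] = hits / iters
    p = float(batch_means.mean())
    se = float(batch_means.std(ddof=1) / math.sqrt(n_batches)) if n_batches > 1 else 0.0
    return ExactTestResult(p, se, chain)


def enumerate_hwe_exact(n_a: int, n_b: int, n_ab_obs: int) -> float:
    """Exact HWE p for a biallelic locus by full table enumeration.

    Enumerates every genotype table compatible with allele counts
    ``(n_a, n_b)`` and sums the conditional probabilities of tables no more
    probable than the observed one.  Oracle for :func:`hwe_exact_mc`.
    """
    n = (n_a + n_b) // 2
    probs = []
    for h in range(n_a % 2, min(n_a, n_b) + 1, 2):
        naa = (n_a - h) // 2
        nbb = (n_b - h) // 2
        if naa < 0 or nbb < 0 or naa + nbb + h != n:
            continue
        logp = (
            math.lgamma(n + 1)
            - math.lgamma(naa + 1)
            - math.lgamma(h + 1)
            - math.lgamma(nbb + 1)
            + h * _LOG2
            + math.lgamma(n_a + 1)
            + math.lgamma(n_b + 1)
            - math.lgamma(2 * n + 1)
        )
        probs.append((h, math.exp(logp)))
    p_obs = dict(probs)[n_ab_obs]
    return sum(p for _, p in probs if p <= p_obs * (1 + 1e-12))


# ---------------------------------------------------------------------------
# genotypic linkage-disequilibrium exact test


def _g_statistic(table: np.ndarray) -> float:
    tot = table.sum()
    if tot == 0:
        return 0.0
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / tot
    mask = table > 0
    return float(2.0 * (table[mask] * np.log(table[mask] / exp[mask])).sum())


def ld_exact_mc(
    sample: SampleSet,
    locus_pair: tuple[str, str],
    chain: tuple[int, int, int] = DEFAULT_CHAIN,
    seed: int | np.random.Generator = 0,
) -> ExactTestResult:
    """Conditional exact test of genotypic association between two loci.

    Individuals missing either locus are dropped pairwise.  The statistic is
    the G log-likelihood ratio of the genotype-by-genotype contingency
    table; the null distribution over tables with fixed margins is sampled
    by random permutation of one locus's genotype column (``batches *
    iterations`` permutations; the dememorisation entry of ``chain`` is
    unused by this sampler).  p carries the +1/(N+1) correction.
    """
    rng = np.random.default_rng(seed)
    names = sample.genotypes.locus_names
    j1, j2 = names.index(locus_pair[0]), names.index(locus_pair[1])
    calls = sample.genotypes.calls
    ok = (calls[:, j1, 0] != MISSING) & (calls[:, j2, 0] != MISSING)
    g1 = np.sort(calls[ok][:, j1, :], axis=1)
    g2 = np.sort(calls[ok][:, j2, :], axis=1)
    _, i1 = np.unique(g1, axis=0, return_inverse=True)
    _, i2 = np.unique(g2, axis=0, return_inverse=True)
    k1, k2 = i1.max(initial=-1) + 1, i2.max(initial=-1) + 1
    if k1 < 2 or k2 < 2:
        return ExactTestResult(float("nan"), 0.0, chain, applicable=False)

    def table_of(perm_i2: np.ndarray) -> np.ndarray:
        return np.bincount(i1 * k2 + perm_i2, minlength=k1 * k2).reshape(k1, k2)

    g_obs = _g_statistic(table_of(i2))
    _, n_batches, iters = chain
    batch_means = np.empty(n_batches)
    hits_total = 0
    for b in range(n_batches):
        hits = 0
        for _ in range(iters):
            if _g_statistic(table_of(rng.permutation(i2))) >= g_obs - 1e-9:
                hits += 1
        hits_total += hits
        batch_means[b] = hits / iters
    n_perm = n_batches * iters
    p = (hits_total + 1) / (n_perm + 1)
    se = float(batch_means.std(ddof=1) / math.sqrt(n_batches)) if n_batches > 1 else 0.0
    return ExactTestResult(float(p), se, chain)


def enumerate_ld_2x2(table: np.ndarray) -> float:
    """Exact conditional p for a 2x2 genotype contingency table.

    Full enumeration over the hypergeometric support with the same
    G-statistic ordering as :func:`ld_exact_mc`.  Oracle for small cases.
    """
    from scipy.stats import hypergeom

    table = np.asarray(table)
    r, c, n = table.sum(axis=1), table.sum(axis=0), table.sum()
    g_obs = _g_statistic(table)
    p = 0.0
    for k in range(max(0, r[0] + c[0] - n), min(r[0], c[0]) + 1):
        t = np.array([[k, r[0] - k], [c[0] - k, n - r[0] - c[0] + k]])
        if _g_statistic(t) >= g_obs - 1e-9:
            p += hypergeom.pmf(k, n, r[0], c[0])
    return float(p)
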