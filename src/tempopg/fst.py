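"""Among-sample differentiation: Weir & Cockerham F-statistics and tests.

The estimator throughout is the Weir & Cockerham (1984) variance-component
theta.  Per locus and allele class u the among-population (a), among-
individual-within-population (b) and within-individual (c) components are

    a = (nbar/nc) [ s2 - (1/(nbar-1)) ( pbar(1-pbar) - ((r-1)/r) s2 - hbar/4 ) ]
    b = (nbar/(nbar-1)) [ pbar(1-pbar) - ((r-1)/r) s2 - ((2 nbar - 1)/(4 nbar)) hbar ]
    c = hbar / 2

with r populations, per-population sample sizes n_i (individuals with data
at the locus), nbar their mean, nc the variance-corrected size, pbar the
weighted mean allele frequency, s2 the weighted among-population variance of
frequencies, and hbar the weighted mean frequency of heterozygotes carrying
u.  Theta per locus sums components over alleles; the multilocus estimate is
the ratio of summed components (never a mean of ratios).  Negative estimates
are reported as computed.

Also here: permutation p-values for pairwise and temporal theta, the
bootstrap test for a temporal decline in global theta (re-sampling a fixed
fraction of individuals per population and a random marker subset per
replicate), the Mantel test, and a small OLS helper for covariate-vs-theta
regressions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._counts import LocusRegistry
from .genepop import SampleSet, TemporalStudy

__all__ = [
    "FstComponents",
    "BootstrapResult",
    "wc_components",
    "pairwise_fst_matrix",
    "temporal_fst",
    "bootstrap_global_fst_difference",
    "mantel_test",
    "ols_r2",
]


@dataclass
class FstComponents:
    locus_names: list[str]
    a: np.ndarray            # per-locus sum over alleles
    b: np.ndarray
    c: np.ndarray
    theta_locus: np.ndarray
    theta_multilocus: float
    populations: list[tuple[str, str]]
    excluded_loci: list[str]


@dataclass
class BootstrapResult:
    replicates: int
    deltas: np.ndarray       # per replicate theta_hist - theta_contemp
    p_one_sided: float
    theta_hist: float
    theta_contemp: float


def _wc_from_counts(
    n: np.ndarray, ac: np.ndarray, hc: np.ndarray, reg: LocusRegistry
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus W&C component sums from stacked per-population counts.

    Parameters: ``n`` (P, L) individuals with data; ``ac``/``hc`` (P, total)
    flattened allele and heterozygote-carrier counts.  Returns per-locus
    (a, b, c, usable) where ``usable`` marks loci with data in >= 2
    populations and at least one segregating allele.
    """
    P, L = n.shape
    seg = reg.segment
    present = n > 0                       # (P, L)
    r = present.sum(axis=0).astype(float)  # (L,)
    usable = r >= 2
    nf = n.astype(float)
    s1 = nf.sum(axis=0)                   # sum n_i
    s2s = (nf**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = s1 / r
        nc = (s1 - s2s / s1) / (r - 1)
    # frequencies per pop per slot
    n_slot = nf[:, seg]                   # (P, total)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_slot > 0, ac / (2 * n_slot), 0.0)
    w = n_slot                            # weights n_i
    s1_slot = s1[seg]
    r_slot = r[seg]
    nbar_slot = nbar[seg]
    with np.errstate(divide="ignore", invalid="ignore"):
        pbar = (w * p).sum(axis=0) / s1_slot
        s2 = (w * (p - pbar) ** 2).sum(axis=0) / ((r_slot - 1) * nbar_slot)
        hbar = hc.sum(axis=0) / s1_slot
    pq = pbar * (1 - pbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (r_slot - 1) / r_slot
        a_u = (nbar_slot / nc[seg]) * (
            s2 - (pq - frac * s2 - hbar / 4) / (nbar_slot - 1)
        )
        b_u = (nbar_slot / (nbar_slot - 1)) * (
            pq - frac * s2 - ((2 * nbar_slot - 1) / (4 * nbar_slot)) * hbar
        )
    c_u = hbar / 2
    bad = ~np.isfinite(a_u) | ~np.isfinite(b_u)
    a_u = np.where(bad, 0.0, a_u)
    b_u = np.where(bad, 0.0, b_u)
    c_u = np.where(bad, 0.0, c_u)
    a = np.bincount(seg, weights=a_u, minlength=L)
    b = np.bincount(seg, weights=b_u, minlength=L)
    c = np.bincount(seg, weights=c_u, minlength=L)
    # a locus fixed for one allele everywhere contributes nothing
    usable = usable & ((a + b + c) != 0)
    return a, b, c, usable


def _theta_from_counts(n, ac, hc, reg) -> float:
    a, b, c, ok = _wc_from_counts(n, ac, hc, reg)
    denom = (a + b + c)[ok].sum()
    if denom == 0:
        return float("nan")
    return float(a[ok].sum() / denom)


def wc_components(
    samples: list[SampleSet],
    loci: list[str] | None = None,
    registry: LocusRegistry | None = None,
) -> FstComponents:
    """Weir & Cockerham components and theta over >= 2 samples.

    Loci with non-missing data in fewer than two samples, or monomorphic
    across all samples, are excluded from the multilocus ratio and listed in
    ``excluded_loci`` (with a warning).
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    tables = [s.genotypes for s in samples]
    if loci is not None:
        tables = [t.restrict_loci(loci) for t in tables]
    reg = registry if (registry is not None and loci is None) else LocusRegistry.from_tables(tables)
    encs = [reg.encode(t.calls) for t in tables]
    stacked = [reg.counts(e) for e in encs]
    n = np.stack([s[0] for s in stacked])
    ac = np.stack([s[1] for s in stacked]).astype(float)
    hc = np.stack([s[2] for s in stacked]).astype(float)
    a, b, c, usable = _wc_from_counts(n, ac, hc, reg)
    theta_locus = np.full(len(reg.locus_names), np.nan)
    tot = a + b + c
    nz = usable & (tot != 0)
    theta_locus[nz] = a[nz] / tot[nz]
    denom = tot[usable].sum()
    theta_multi = float(a[usable].sum() / denom) if denom != 0 else float("nan")
    excluded = [reg.locus_names[j] for j in np.nonzero(~usable)[0]]
    if excluded:
        warnings.warn(f"loci excluded from theta: {excluded}", stacklevel=2)
    return FstComponents(
        list(reg.locus_names), a, b, c, theta_locus, theta_multi,
        [(s.population, s.era) for s in samples], excluded,
    )


def _pair_theta_perm(
    s1: SampleSet,
    s2: SampleSet,
    permutations: int,
    rng: np.random.Generator,
    loci: list[str] | None = None,
) -> tuple[float, float]:
    """Observed theta between two samples and its permutation p-value.

    Null: individuals exchangeable between the two samples; p = proportion
    of shuffled datasets with theta >= observed, with +1/(N+1) correction.
    """
    t1, t2 = s1.genotypes, s2.genotypes
    if loci is not None:
        t1, t2 = t1.restrict_loci(loci), t2.restrict_loci(loci)
    reg = LocusRegistry.from_tables([t1, t2])
    e1, e2 = reg.encode(t1.calls), reg.encode(t2.calls)
    pool = np.concatenate([e1, e2])
    n1 = e1.shape[0]

    def theta_of(rows1: np.ndarray, rows2: np.ndarray) -> float:
        c1 = reg.counts(pool, rows1)
        c2 = reg.counts(pool, rows2)
        n = np.stack([c1[0], c2[0]])
        ac = np.stack([c1[1], c2[1]]).astype(float)
        hc = np.stack([c1[2], c2[2]]).astype(float)
        return _theta_from_counts(n, ac, hc, reg)

    all_rows = np.arange(pool.shape[0])
    obs = theta_of(all_rows[:n1], all_rows[n1:])
    if permutations <= 0:
        return obs, float("nan")
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(pool.shape[0])
        t = theta_of(perm[:n1], perm[n1:])
        if not math.isnan(t) and t >= obs - 1e-12:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return obs, p


def pairwise_fst_matrix(
    study: TemporalStudy,
    era: str,
    permutations: int = 0,
    seed: int | np.random.Generator = 0,
    loci: list[str] | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Pairwise theta matrix (and permutation p-values) for one era.

    Populations lacking the era are omitted.  Returns (populations, theta
    matrix, p matrix); both matrices are symmetric with zero/NaN diagonals.
    """
    rng = np.random.default_rng(seed)
    samples = study.era_samples(era)
    if len(samples) < 2:
        raise ValueError(f"fewer than two populations sampled in era {era!r}")
    pops = [s.population for s in samples]
    P = len(samples)
    theta = np.zeros((P, P))
    pvals = np.full((P, P), np.nan)
    for i in range(P):
        for j in range(i + 1, P):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t, p = _pair_theta_perm(samples[i], samples[j], permutations, rng, loci)
            theta[i, j] = theta[j, i] = t
            pvals[i, j] = pvals[j, i] = p
    return pops, theta, pvals


def temporal_fst(
    study: TemporalStudy,
    population: str,
    loci: list[str] | None = None,
    permutations: int = 0,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Theta between one river's historical and contemporary samples."""
    for era in ("historical", "contemporary"):
        if not study.has(population, era):
            raise ValueError(f"population {population!r} lacks a {era} sample")
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _pair_theta_perm(
            study.get(population, "historical"),
            study.get(population, "contemporary"),
            permutations,
            rng,
            loci,
        )


def global_theta(samples: list[SampleSet], loci: list[str] | None = None) -> float:
    """Multilocus global theta among a set of samples."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return wc_components(samples, loci=loci).theta_multilocus


def bootstrap_global_fst_difference(
    study: TemporalStudy,
    frac_individuals: float = 0.30,
    n_markers: int = 7,
    replicates: int = 10000,
    seed: int | np.random.Generator = 0,
    populations: list[str] | None = None,
    loci: list[str] | None = None,
) -> BootstrapResult:
    """Bootstrap test of H1: global theta(historical) > theta(contemporary).

    Per replicate a random marker subset of ``n_markers`` loci (shared by
    both eras within the replicate) and a random ``frac_individuals``
    subsample of each population (drawn without replacement, independently
    per era; rounded half-up, minimum 2) are used to recompute the two
    global theta values; the one-sided p is the proportion of replicates
    whose difference (historical - contemporary) is <= 0, with the
    +1/(N+1) correction.
    """
    pops = populations if populations is not None else study.populations()
    locus_names = loci if loci is not None else study.locus_names
    if n_markers > len(locus_names):
        raise ValueError("n_markers exceeds the number of loci")
    pairs = []
    for pop in pops:
        for era in ("historical", "contemporary"):
            if not study.has(pop, era):
                raise ValueError(f"population {pop!r} lacks a {era} sample")
        pairs.append((study.get(pop, "historical"), study.get(pop, "contemporary")))
    for pop, (h, c) in zip(pops, pairs):
        for s in (h, c):
            m = int(math.floor(frac_individuals * s.n + 0.5))
            if m < 2:
                raise ValueError(
                    f"subsample of {s.era} {pop!r} would have {m} individuals"
                )

    tables = [s.genotypes.restrict_loci(locus_names) for pair in pairs for s in pair]
    reg = LocusRegistry.from_tables(tables)
    encs = [reg.encode(t.calls) for t in tables]  # order: pop0 H, pop0 C, pop1 H, ...
    L = len(locus_names)
    rng = np.random.default_rng(seed)

    def global_theta_counts(rows_list, locus_mask):
        n = []
        ac = []
        hc = []
        for e, rows in rows_list:
            cn, ca, ch = reg.counts(e, rows)
            n.append(cn)
            ac.append(ca)
            hc.append(ch)
        n = np.stack(n).astype(float)
        ac = np.stack(ac).astype(float)
        hc = np.stack(hc).astype(float)
        n = n * locus_mask            # zero out unselected loci
        slot_mask = locus_mask[reg.segment]
        ac = ac * slot_mask
        hc = hc * slot_mask
        return _theta_from_counts(n.astype(int), ac, hc, reg)

    full_mask = np.ones(L)
    th = global_theta_counts([(encs[2 * i], None) for i in range(len(pops))], full_mask)
    tc = global_theta_counts([(encs[2 * i + 1], None) for i in range(len(pops))], full_mask)

    deltas = np.empty(replicates)
    sizes = [e.shape[0] for e in encs]
    subs = [int(math.floor(frac_individuals * n + 0.5)) for n in sizes]
    for rep in range(replicates):
        locus_mask = np.zeros(L)
        locus_mask[rng.choice(L, size=n_markers, replace=False)] = 1.0
        rows = [rng.choice(sizes[i], size=subs[i], replace=False) for i in range(len(encs))]
        dh = global_theta_counts(
            [(encs[2 * i], rows[2 * i]) for i in range(len(pops))], locus_mask
        )
        dc = global_theta_counts(
            [(encs[2 * i + 1], rows[2 * i + 1]) for i in range(len(pops))], locus_mask
        )
        deltas[rep] = dh - dc
    p = (int((deltas <= 0).sum()) + 1) / (replicates + 1)
    return BootstrapResult(replicates, deltas, float(p), th, tc)


def mantel_test(
    d1: np.ndarray,
    d2: np.ndarray,
    permutations: int = 10000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation over lower-triangle entries; p is two-sided
    from joint row/column permutations of one matrix, +1/(N+1) corrected.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape or d1.ndim != 2 or d1.shape[0] != d1.shape[1]:
        raise ValueError("matrices must be square and of matching dimensions")
    for d in (d1, d2):
        if not np.allclose(d, d.T):
            raise ValueError("matrices must be symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("matrices must have zero diagonals")
    n = d1.shape[0]
    il = np.tril_indices(n, -1)
    x = d1[il]
    rng = np.random.default_rng(seed)
    r_obs = float(np.corrcoef(x, d2[il])[0, 1])
    if permutations <= 0:
        return r_obs, float("nan")
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        r = float(np.corrcoef(x, d2[np.ix_(perm, perm)][il])[0, 1])
        if abs(r) >= abs(r_obs) - 1e-12:
            hits += 1
    return r_obs, (hits + 1) / (permutations + 1)


def ols_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: (R^2, slope, two-sided slope p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D vectors, n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.allclose(x, x[0]):
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return float(res.rvalue**2), float(res.slope), float(res.pvalue)
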