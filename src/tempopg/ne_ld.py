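"""Single-sample effective population size from linkage disequilibrium.

In a closed Wright–Fisher population, drift generates an equilibrium level
of association between unlinked loci of roughly E[r^2] = 1/(3Ne); a finite
sample of S diploids adds sampling disequilibrium of roughly 1/S.  The
estimator measures the Burrows composite disequilibrium between every
qualifying pair of alleles at every pair of loci, subtracts the S-dependent
sampling expectation (second-order formulas, separate branches for S >= 30
and S < 30), and inverts the drift component to Ne:

    random mating:  Ne = (1/3 + sqrt(1/9 - 2.76 r2'))/(2 r2')
    monogamy:       Ne = (2/3 + sqrt(4/9 - 7.2  r2'))/(2 r2')

where r2' = mean r^2 - E[r^2 | S].  A non-positive drift component means
the observed disequilibrium is fully attributable to sampling: Ne is then
reported as infinite (the "relatively large population" convention).  A
harmonic-mean sample size below 30 flags the estimate as untrustworthy.

Confidence intervals: a jackknife over locus pairs and the parametric
chi-square interval on the mean r^2 are both computed; the headline 95% CI
is their wider envelope.  Negative bounds (sampling error exceeding the
observed variance) are rendered infinite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from ._counts import LocusRegistry
from .genepop import MISSING, SampleSet

__all__ = ["NeEstimate", "burrows_r2", "ldne_estimate"]


@dataclass
class NeEstimate:
    ne_point: float                  # may be math.inf
    ci_low: float
    ci_high: float
    mean_r2: float
    expected_sample_r2: float
    n_pairwise_comparisons: int
    harmonic_mean_s: float
    low_sample_flag: bool
    ci_jackknife: tuple[float, float] | None = None
    ci_parametric: tuple[float, float] | None = None


def _expected_sample_r2(s: float) -> float:
    """Second-order expectation of r^2 from sampling S diploids alone."""
    if s >= 30:
        return 1.0 / s + 3.19 / s**2
    return 0.0018 + 0.907 / s + 4.44 / s**2


def _invert_ne(r2_drift: float, s: float, mating: str) -> float:
    if r2_drift <= 0:
        return math.inf
    if mating == "random":
        if s >= 30:
            disc = max(1.0 / 9.0 - 2.76 * r2_drift, 0.0)
            return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2_drift)
        disc = max(0.308**2 - 2.08 * r2_drift, 0.0)
        return (0.308 + math.sqrt(disc)) / (2.0 * r2_drift)
    if mating == "monogamy":
        disc = max(4.0 / 9.0 - 7.2 * r2_drift, 0.0)
        return (2.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2_drift)
    raise ValueError("mating must be 'random' or 'monogamy'")


def burrows_r2(
    sample: SampleSet, pcrit: float = 0.02
) -> tuple[float, list[tuple[int, int, float, int, int]], float]:
    """Mean Burrows composite r^2 over locus pairs.

    Alleles with frequency below ``pcrit`` are excluded from comparisons.
    For each retained allele pair (u at locus i, v at locus j) the composite
    disequilibrium is half the (bias-corrected) covariance of allele
    dosages; r^2 normalises by p(1-p)q(1-q).  Individuals missing either
    locus are dropped pairwise; S per pair is the count retained.

    Returns (mean r^2 over all comparisons, per-pair records
    ``(i, j, mean r^2 of the pair, n_comparisons, S)``, harmonic mean S).
    """
    calls = sample.genotypes.calls
    L = calls.shape[1]
    reg = LocusRegistry.from_tables([sample.genotypes])
    # dosage matrix per locus over retained alleles
    dosages: list[np.ndarray | None] = []
    observed: list[np.ndarray] = []
    for j in range(L):
        col = calls[:, j, :]
        ok = col[:, 0] != MISSING
        observed.append(ok)
        alleles = reg.alleles[j]
        if ok.sum() == 0 or len(alleles) < 2:
            dosages.append(None)
            continue
        dos = (col[:, 0, None] == alleles[None, :]).astype(float) + (
            col[:, 1, None] == alleles[None, :]
        ).astype(float)
        freq = dos[ok].sum(axis=0) / (2 * ok.sum())
        keep = freq >= pcrit
        keep &= freq <= 1 - pcrit
        if keep.sum() < 1 or (freq[keep] > 0).sum() < 1:
            dosages.append(None)
            continue
        dosages.append(dos[:, keep])
    records: list[tuple[int, int, float, int, int]] = []
    total_r2 = 0.0
    total_n = 0
    s_list: list[int] = []
    for i, j in itertools.combinations(range(L), 2):
        if dosages[i] is None or dosages[j] is None:
            continue
        both = observed[i] & observed[j]
        s = int(both.sum())
        if s < 3:
            continue
        X = dosages[i][both]
        Y = dosages[j][both]
        # drop alleles monomorphic within the pairwise-complete subset
        px = X.mean(axis=0) / 2
        py = Y.mean(axis=0) / 2
        kx = (px > 0) & (px < 1)
        ky = (py > 0) & (py < 1)
        if not kx.any() or not ky.any():
            continue
        X, px = X[:, kx], px[kx]
        Y, py = Y[:, ky], py[ky]
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        cov = Xc.T @ Yc / (s - 1)
        delta = cov / 2.0
        denom = np.outer(px * (1 - px), py * (1 - py))
        r2 = delta**2 / denom
        n_cmp = r2.size
        records.append((i, j, float(r2.mean()), n_cmp, s))
        total_r2 += float(r2.sum())
        total_n += n_cmp
        s_list.append(s)
    if total_n == 0:
        raise ValueError("no qualifying locus pairs")
    mean_r2 = total_r2 / total_n
    harm_s = len(s_list) / sum(1.0 / s for s in s_list)
    return mean_r2, records, harm_s


def ldne_estimate(
    sample: SampleSet, pcrit: float = 0.02, mating: str = "random"
) -> NeEstimate:
    """Bias-corrected LD estimate of effective population size."""
    n_total = sample.genotypes.calls.shape[0]
    if n_total < 10:
        raise ValueError("sample too small for LD-based Ne (S < 10)")
    mean_r2, records, harm_s = burrows_r2(sample, pcrit)
    exp_r2 = _expected_sample_r2(harm_s)
    n_cmp = sum(rec[3] for rec in records)
    r2_drift = mean_r2 - exp_r2
    ne_point = _invert_ne(r2_drift, harm_s, mating)

    def ne_of_r2(r2: float) -> float:
        return _invert_ne(r2 - exp_r2, harm_s, mating)

    # jackknife over locus pairs on the weighted mean r^2
    ci_jk: tuple[float, float] | None = None
    if len(records) > 2:
        tot = sum(r[2] * r[3] for r in records)
        totn = n_cmp
        jk = np.array(
            [(tot - r[2] * r[3]) / (totn - r[3]) for r in records if totn > r[3]]
        )
        J = len(jk)
        var = (J - 1) / J * float(((jk - jk.mean()) ** 2).sum())
        half = 1.96 * math.sqrt(var)
        ci_jk = (ne_of_r2(mean_r2 - half), ne_of_r2(mean_r2 + half))
    # parametric chi-square interval treating comparisons as independent
    lo_r2 = mean_r2 * n_cmp / chi2.ppf(0.975, n_cmp)
    hi_r2 = mean_r2 * n_cmp / chi2.ppf(0.025, n_cmp)
    ci_par = (ne_of_r2(lo_r2), ne_of_r2(hi_r2))

    # Ne is decreasing in r^2: the lower r^2 bound gives the upper Ne bound
    def order(ci: tuple[float, float]) -> tuple[float, float]:
        return (min(ci), max(ci))

    candidates = [order(ci_par)] + ([order(ci_jk)] if ci_jk else [])
    ci_low = min(c[0] for c in candidates)
    ci_high = max(c[1] for c in candidates)
    # negative bounds mean sampling error swallows the signal
    if ci_low < 0:
        ci_low = math.inf
    if ci_high < 0:
        ci_high = math.inf
    if ci_low is math.inf and ci_high is not math.inf:
        ci_low, ci_high = ci_high, math.inf
    return NeEstimate(
        ne_point=ne_point,
        ci_low=ci_low,
        ci_high=ci_high,
        mean_r2=mean_r2,
        expected_sample_r2=exp_r2,
        n_pairwise_comparisons=n_cmp,
        harmonic_mean_s=harm_s,
        low_sample_flag=harm_s < 30,
        ci_jackknife=ci_jk,
        ci_parametric=ci_par,
    )


def format_ne(est: NeEstimate) -> str:
    """Table-style rendering with the Inf and low-sample conventions."""
    def f(x: float) -> str:
        return "Inf" if math.isinf(x) else f"{x:.0f}"

    mark = "#" if est.low_sample_flag else ""
    return f"{f(est.ne_point)}{mark} ({f(est.ci_low)}-{f(est.ci_high)})"
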