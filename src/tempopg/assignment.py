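"""Bayesian genetic assignment and Monte-Carlo exclusion.

Individuals are scored against reference samples with the Rannala & Mountain
criterion: the probability of the observed multilocus genotype under each
baseline's Dirichlet-multinomial posterior predictive.  At a locus with k
distinct alleles (registered study-wide, so alleles unseen in a baseline
remain scoreable) the prior puts mass 1/k on each allele class; for a
genotype (u, v) drawn sequentially from a baseline with gene-copy counts c
and total n,

    P(u, v) = [2 if u != v] * (c_u + 1/k)/(n + 1) * (c_v + d_uv + 1/k)/(n + 2)

with d_uv = 1 when the genotype is homozygous.  Scores are summed as log10
over the individual's observed loci.

Exclusion follows the Geneclass decoupling of criterion and simulation: the
null distribution of scores is built from genotypes simulated under HWE from
the baseline's observed allele frequencies, and a query is excluded when its
score falls below the alpha quantile of the null computed over exactly the
loci the query has observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._counts import LocusRegistry
from .genepop import MISSING, SampleSet, TemporalStudy

__all__ = [
    "AssignmentScores",
    "rm_log_likelihood",
    "self_assignment",
    "exclusion_test",
]


@dataclass
class AssignmentScores:
    query_ids: list[str]
    reference_keys: list[str]
    scores: np.ndarray          # (n_queries, n_refs) log10 likelihoods
    assigned_to: list[str]
    exclusion_p: np.ndarray | None = None   # (n_queries, n_refs)
    excluded: np.ndarray | None = None      # boolean, same shape
    percent_excluded: float | None = None


def _baseline_counts(
    baseline: SampleSet, reg: LocusRegistry
) -> tuple[np.ndarray, np.ndarray]:
    """(flattened gene-copy counts, per-locus totals) for a baseline."""
    enc = reg.encode(baseline.genotypes.calls)
    _, ac, _ = reg.counts(enc)
    totals = np.bincount(reg.segment, weights=ac, minlength=len(reg.k))
    return ac.astype(float), totals


def _score_genotypes(
    enc: np.ndarray,
    ac: np.ndarray,
    totals: np.ndarray,
    reg: LocusRegistry,
    loo_rows: np.ndarray | None = None,
) -> np.ndarray:
    """Per-individual per-locus log10 RM scores; NaN at missing loci.

    ``loo_rows`` marks individuals whose own alleles must be removed from
    the baseline counts before scoring (leave-one-out).
    """
    n_ind, L, _ = enc.shape
    prior = 1.0 / reg.k[reg.segment]            # tau_u per slot
    out = np.full((n_ind, L), np.nan)
    u, v = enc[:, :, 0], enc[:, :, 1]
    ok = u >= 0
    cu = np.where(ok, ac[np.clip(u, 0, None)], 0.0)
    cv = np.where(ok, ac[np.clip(v, 0, None)], 0.0)
    n_l = np.broadcast_to(totals[reg.segment[np.clip(u, 0, None)]], u.shape).copy()
    if loo_rows is not None:
        # remove the individual's own two copies
        cu = cu.copy()
        cv = cv.copy()
        cu[loo_rows] -= 1
        cv[loo_rows] -= 1
        hom = u == v
        cu[loo_rows & hom] -= 1
        cv[loo_rows & hom] -= 1
        n_l[loo_rows] -= 2
    tau_u = np.where(ok, prior[np.clip(u, 0, None)], 0.0)
    tau_v = np.where(ok, prior[np.clip(v, 0, None)], 0.0)
    d = (u == v).astype(float)
    het = (u != v) & ok
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = (
            np.log10(cu + tau_u)
            - np.log10(n_l + 1.0)
            + np.log10(cv + d + tau_v)
            - np.log10(n_l + 2.0)
            + het * np.log10(2.0)
        )
    out[ok] = logp[ok]
    return out


def rm_log_likelihood(
    individual: np.ndarray,
    baseline: SampleSet,
    leave_one_out: bool = False,
    registry: LocusRegistry | None = None,
    member_row: int | None = None,
) -> float:
    """Total log10 RM assignment likelihood of one genotype row.

    ``individual`` is an ``(L, 2)`` allele-code array sharing the baseline's
    locus list; missing loci are skipped.  With ``leave_one_out`` the
    individual's own alleles are removed from the baseline counts — the
    caller identifies the individual's row via ``member_row`` (or, if
    omitted, by matching the genotype against baseline rows).
    """
    individual = np.asarray(individual, dtype=np.int32)
    if (individual == MISSING).all():
        raise ValueError("individual has no scored loci")
    reg = registry or LocusRegistry.from_tables([baseline.genotypes])
    # ensure the query's alleles are registered
    tmp = individual[None, :, :]
    try:
        enc = reg.encode(tmp)
    except ValueError:
        merged = LocusRegistry(
            reg.locus_names,
            [
                np.unique(
                    np.concatenate(
                        [reg.alleles[j], individual[j][individual[j] != MISSING]]
                    )
                )
                for j in range(len(reg.locus_names))
            ],
        )
        reg = merged
        enc = reg.encode(tmp)
    ac, totals = _baseline_counts(baseline, reg)
    loo = None
    if leave_one_out:
        loo = np.ones((1, len(reg.locus_names)), dtype=bool)
        loo &= enc[:, :, 0] >= 0
    per_locus = _score_genotypes(enc, ac, totals, reg, loo_rows=loo)
    return float(np.nansum(per_locus))


def self_assignment(
    study: TemporalStudy, era: str, loci: list[str] | None = None
) -> tuple[float, dict[str, float], AssignmentScores]:
    """Leave-one-out self-assignment among the populations of one era.

    Every individual is scored against every population of the era, with
    leave-one-out applied to its own population, and assigned to the argmax
    (ties broken by reference order).  Returns (overall % correct,
    per-population % correct, full score object).
    """
    samples = study.era_samples(era)
    if len(samples) < 2:
        raise ValueError("self-assignment needs at least two populations")
    tables = [s.genotypes if loci is None else s.genotypes.restrict_loci(loci) for s in samples]
    reg = LocusRegistry.from_tables(tables)
    encs = [reg.encode(t.calls) for t in tables]
    counts = []
    for e in encs:
        _, ac, _ = reg.counts(e)
        totals = np.bincount(reg.segment, weights=ac, minlength=len(reg.k))
        counts.append((ac.astype(float), totals.astype(float)))

    pops = [s.population for s in samples]
    all_scores = []
    ids: list[str] = []
    truth: list[int] = []
    for qi, e in enumerate(encs):
        ids.extend(samples[qi].genotypes.individual_ids)
        truth.extend([qi] * e.shape[0])
        cols = []
        observed = e[:, :, 0] >= 0
        for ri, (ac, totals) in enumerate(counts):
            loo = observed if ri == qi else None
            per_locus = _score_genotypes(e, ac, totals, reg, loo_rows=loo)
            cols.append(np.nansum(per_locus, axis=1))
        all_scores.append(np.stack(cols, axis=1))
    scores = np.concatenate(all_scores, axis=0)
    assigned = np.argmax(scores, axis=1)
    truth_arr = np.array(truth)
    overall = float((assigned == truth_arr).mean() * 100)
    per_pop = {
        pops[i]: float((assigned[truth_arr == i] == i).mean() * 100)
        for i in range(len(pops))
    }
    result = AssignmentScores(
        query_ids=ids,
        reference_keys=pops,
        scores=scores,
        assigned_to=[pops[i] for i in assigned],
    )
    return overall, per_pop, result


def exclusion_test(
    queries: SampleSet,
    baseline: SampleSet,
    alpha: float = 0.001,
    n_sim: int = 10000,
    seed: int | np.random.Generator = 0,
    loci: list[str] | None = None,
) -> AssignmentScores:
    """Monte-Carlo exclusion of query genotypes from a baseline profile.

    ``n_sim`` multilocus genotypes are simulated under HWE from the
    baseline's observed allele frequencies and scored with the RM criterion
    (no leave-one-out).  Each query is scored over exactly its observed
    loci; the simulated null is re-totalled on that same locus subset, and
    the query is excluded when its score is below the alpha quantile.
    """
    if not (0 < alpha < 0.5):
        raise ValueError("alpha must be in (0, 0.5)")
    if n_sim < 1000:
        raise ValueError("n_sim must be at least 1000")
    rng = np.random.default_rng(seed)
    qt = queries.genotypes if loci is None else queries.genotypes.restrict_loci(loci)
    bt = baseline.genotypes if loci is None else baseline.genotypes.restrict_loci(loci)
    if qt.locus_names != bt.locus_names:
        raise ValueError("queries and baseline must share the locus list")
    reg = LocusRegistry.from_tables([qt, bt])
    L = len(reg.locus_names)
    ac, totals = _baseline_counts(
        SampleSet(baseline.population, baseline.era, baseline.years, bt), reg
    )

    # simulate null genotypes per locus from baseline frequencies
    sim = np.full((n_sim, L, 2), -1, dtype=np.int64)
    for j in range(L):
        seg = slice(reg.offsets[j], reg.offsets[j + 1])
        freqs = ac[seg]
        tot = freqs.sum()
        if tot == 0:
            continue
        p = freqs / tot
        draws = rng.choice(len(p), size=(n_sim, 2), p=p)
        sim[:, j, :] = draws + reg.offsets[j]
    sim_per_locus = _score_genotypes(sim, ac, totals, reg)     # (n_sim, L)
    sim_per_locus = np.nan_to_num(sim_per_locus, nan=0.0)

    qenc = reg.encode(qt.calls)
    q_per_locus = _score_genotypes(qenc, ac, totals, reg)      # (nq, L)
    # loci with no baseline data cannot be scored against it
    observed = (qenc[:, :, 0] >= 0) & (totals > 0)[None, :]
    q_scores = np.nansum(np.where(observed, q_per_locus, 0.0), axis=1)

    nq = qenc.shape[0]
    pvals = np.empty(nq)
    excluded = np.zeros(nq, dtype=bool)
    # group queries by observed-locus pattern so the null is re-totalled once
    patterns: dict[bytes, np.ndarray] = {}
    for i in range(nq):
        key = observed[i].tobytes()
        if key not in patterns:
            patterns[key] = sim_per_locus[:, observed[i]].sum(axis=1)
        null = patterns[key]
        pvals[i] = float((null <= q_scores[i]).mean())
        excluded[i] = q_scores[i] < np.quantile(null, alpha)
    return AssignmentScores(
        query_ids=list(qt.individual_ids),
        reference_keys=[baseline.population],
        scores=q_scores[:, None],
        assigned_to=[baseline.population] * nq,
        exclusion_p=pvals[:, None],
        excluded=excluded[:, None],
        percent_excluded=float(excluded.mean() * 100),
    )
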