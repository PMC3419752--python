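# Methods

This note documents the models, estimators and design choices behind
`tempopg`, the assumptions each one makes, and what the synthetic-data
tests do and do not demonstrate about real data.

## Data model

Genotypes are unordered diploid allele-code pairs over a fixed locus list;
missing calls use an explicit sentinel distinct from any code (never code
0, so downstream counts cannot silently include missing data).  Allele
codes are opaque labels — no repeat-length or size semantics are assumed
anywhere.  A `TemporalStudy` keys per-river samples by era (historical /
intermediate / contemporary) with inclusive sampling-year ranges;
multi-year windows are reduced to midpoint years, rounded down.
Missing-data policy throughout is pairwise deletion per locus (per locus
pair for LD); nothing is imputed.

## Within-sample statistics

Expected heterozygosity uses the small-sample-unbiased estimator
`(n/(n−1))(1 − Σp²)` on gene copies, appropriate because sample sizes vary
several-fold across rivers.  F_IS = 1 − Ho/He, flagged undefined when
He = 0.  Allelic richness is hypergeometric rarefaction to `g` gene
copies; the conventional "re-sample size 25" is interpreted as 25 diploid
individuals (50 gene copies) by default, with a `genes` unit switch, since
the convention is ambiguous in the field's tooling.  Per-sample totals are
*sums* of per-locus A_R over qualifying loci; loci with fewer than `g`
non-missing copies are flagged unqualified rather than extrapolated.  When
comparing A_R between two samples of very different size, rarefy both at a
size both support — the analysis drivers and acceptance checks do this,
capping at the standard 50 copies.

### Exact tests

The Hardy–Weinberg test conditions on observed allele counts.  Under
random union of gametes every arrangement of the 2n gene copies into n
ordered pairs is equally likely, so the chain swaps two uniformly chosen
gene-copy positions per step — a symmetric proposal whose stationary
genotype-table law is exactly the conditional null
`P(T) = n! 2^H Π_u n_u! / (Π_{uv} n_uv! (2n)!)`.  The p-value follows the
probability-ordering criterion (mass of tables no more probable than the
observed one); the Monte-Carlo standard error comes from batch means.  The
default chain is (10000 dememorisation, 1000 batches, 10000 iterations per
batch); tests and analysis drivers use much shorter chains, which is a
pure precision trade-off — correctness is anchored by full enumeration on
biallelic cases and by null-uniformity calibration.

The LD test is a conditional exact test of the genotype-by-genotype
contingency table with the G log-likelihood-ratio statistic; the null with
fixed margins is sampled by permuting one locus's genotype column.  p
carries the +1/(N+1) correction so zero is never reported.  The chain
triple is reinterpreted as batches × iterations permutations
(dememorisation unused by this sampler).

## Differentiation

All F_ST quantities are Weir & Cockerham (1984) variance-component θ with
the heterozygosity correction, combined across alleles and loci as ratio
of summed components — never a mean of ratios.  Negative estimates are
reported as computed.  Loci with data in fewer than two samples, or
monomorphic across all samples, are excluded and listed.  Permutation
p-values (individuals shuffled between samples) use the +1/(N+1)
correction.

The temporal-decline bootstrap draws, per replicate, one random marker
subset (default 7 of 22) *shared by both eras within the replicate* — the
shared subset removes locus-sampling variance from the difference, a
choice the emulated design leaves open — and an independent 30% subsample
of individuals per population per era, without replacement (minimum 2,
rounded half-up).  One-sided p is the fraction of replicates in which the
historical global θ did not exceed the contemporary one.

Mantel r is the Pearson correlation over lower-triangle entries with joint
row/column permutation; its two-sided p uses |r| ordering.  OLS utilities
delegate to `scipy.stats.linregress`.

## Assignment and exclusion

Scores are Rannala–Mountain Dirichlet-multinomial posterior predictives
with total prior mass 1 per locus split equally over the *study-wide*
allele registry (k classes), so alleles absent from a baseline remain
scoreable:
`P(u,v) = [2 if u≠v] (c_u + 1/k)/(n+1) · (c_v + δ_uv + 1/k)/(n+2)`,
summed as log10 over the individual's observed loci.  Self-assignment is
leave-one-out (own alleles removed from own baseline counts), argmax over
references, ties broken by reference order.

Exclusion decouples criterion and simulation: null genotypes are drawn
under HWE from the baseline's observed frequencies, scored with the RM
criterion without leave-one-out, and a query is excluded below the alpha
quantile of the null re-totalled over exactly the query's observed loci —
recomputing the null per missing-data pattern keeps the test calibrated
per query.  Calibration holds for queries drawn from the baseline profile
itself; queries drawn from the *true* underlying frequencies are excluded
somewhat above the nominal rate because baseline sampling noise is not
modelled — the known caveat of this test family, and the reason absolute
exclusion percentages are implementation-dependent.

## Drift null

Gene dropping simulates the only-drift hypothesis: founders draw alleles
iid from the historical sample's observed frequencies (the
least-assumption bridge from a sample of size n to a population of size
Ne), then each generation Ne offspring choose a random mother from the
female half and a random father from the male half (odd Ne puts the extra
individual on the male side) and inherit one uniformly chosen allele per
parent per locus; loci are unlinked, generations discrete, no mutation,
migration or selection.  Generations between samples use
`ceil(Δyears / 5)`, minimum 1.  After G generations a pseudo-sample of the
contemporary size is drawn (without replacement when it fits, else with
replacement, flagged).

Per Ne on the grid, the exceedance p is the fraction of replicates whose
θ against the observed historical sample reaches the observed temporal θ;
small p at a given Ne excludes drift of that strength.  A zero count is
rendered `<1/replicates`.  The module's correctness anchor is
heterozygosity decay: the unbiased He of the simulated population matches
`He₀ (1 − 1/(2Ne))^G` to well under a percent.  The accumulated
frequency variance matches `p₀q₀ (1 − (1 − 1/(2Ne))^(G+1))` — the
founding draw counts as one binomial round.  Note that the pairwise
sample-θ between ancestor and descendant is *not* the accumulated drift F:
θ measures variance about the pair mean net of sampling corrections
(roughly F/2 minus terms of order 1/n), which is why the anchor is stated
on He and frequency variance rather than on θ itself.  Intermediate-era
samples are ignored by drift tests.

## LD-based Ne

Burrows composite disequilibrium per allele pair is half the
bias-corrected dosage covariance; r² normalises by `p(1−p)q(1−q)`.  All
alleles with frequency within [pcrit, 1−pcrit] participate (pcrit default
0.02); a locus never pairs with itself; individuals missing either locus
drop pairwise, and S per pair is the retained count.  The sampling
expectation uses the second-order formulas (separate branches for S ≥ 30
and S < 30); the drift component `mean r² − E[r²|S]` inverts through the
quadratic for the mating system (random by default — the emulated species
is promiscuous; monogamy uses the same sampling expectation with its own
inversion).  Non-positive drift components report Ne = ∞, negative
interval bounds render as ∞ (sampling error swallows the signal), and a
harmonic-mean S below 30 sets the untrustworthy flag.  Both a jackknife
CI over locus pairs and the parametric chi-square CI are computed; the
headline interval is their wider envelope.  In forward-simulation
recovery at true Ne = 100 (S = 50, 22 loci) the median estimate lands
mildly high (≈1.4–1.7× truth) — a residual positive bias of this
estimator class at S/Ne = 0.5 that the published corrections do not fully
remove; the acceptance band accounts for it.

## Synthetic-data generator

Simulation is at the allele-frequency level (binomial drift on
frequencies), which is sufficient because only HWE-sampled genotypes are
consumed downstream; individual-level gene dropping is reserved for the
drift module where the null requires it.  Wild baselines follow a
Balding–Nichols-style F-model: per-locus ancestral frequencies from a
symmetric Dirichlet (5–15 alleles per locus), population frequencies from
`Dirichlet(ancestral·(1−F)/F)` with F iteratively rescaled until the
parametric global θ of the draw is within ±0.005 of the 0.04 target.
Farm strains are founder bottlenecks: a Dirichlet-weighted mixture of
wild baselines drifted 8 generations at Ne = 30, making strains mutually
distinct yet confined to the wild allele repertoire.  Introgression
blends `p ← (1−m)·p_drifted + m·q` each generation, with q the mean of a
random strain subset (escapee composition shifts through time).  Scale
defaults mirror the emulated survey: 21 rivers, 22 loci, sample sizes
uniform on [16, 106], historical 1980 and contemporary 2010 on a 5-year
generation clock, wild Ne 500.

What passing tests show: the full pipeline detects the qualitative
signature of multi-source introgression — significant temporal θ and
richness gain in exposed rivers, loss of among-river structure, high
exclusion from historical baselines — and stays quiet on unexposed
rivers.  What they do not show: realism of any particular river's
trajectory.  Real farm-strain frequency histories are unreconstructable,
real populations violate the discrete-generation and closed-population
assumptions, genotyping error and allele-binning drift between eras are
not simulated, and frequency-level drift generates no background LD (so
generator samples mostly yield infinite LD-Ne, unlike real rivers).

## Problem sizes and numerical conventions

Test and driver runs use deliberately modest Monte-Carlo sizes chosen as
the package's own defaults for desk-scale work: exact-test chains of a
few thousand steps, 199–1999 permutations, 500–2000 bootstrap replicates,
300–1000 drift replicates, 50–60 LD-Ne recovery replicates, and 12 seeded
end-to-end runs; production defaults (10000-step chains, 10000 bootstrap
replicates, 1000 drift replicates) remain the function defaults.  All
randomness flows through `numpy.random.Generator` objects seeded
explicitly; every pipeline output is reproducible from (inputs, config,
seed).  Ties in permutation and exceedance counts are resolved
conservatively with 1e-9–1e-12 guards; permutation p-values never report
zero.

## Known limitations

No hierarchical F-statistics or molecular-variance decomposition; no
outlier-locus detection (a user-declared neutral subset is accepted
instead); no temporal-method or sibship Ne; exclusion percentages are
calibrated but not numerically portable across assignment software
families; the LD-Ne recovery band, not point parity, is the supported
claim.
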