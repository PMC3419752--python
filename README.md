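# tempopg

Spatio-temporal population-genetic analysis of multilocus diploid genotypes,
built around the question conservation geneticists ask about wild salmonid
rivers exposed to decades of aquaculture escapees: *have the populations
changed genetically between a historical and a contemporary sample, and can
genetic drift be excluded as the cause?*

The package provides, as composable library modules plus numbered analysis
drivers:

- **GenePop I/O** (`tempopg.genepop`) — 2- and 3-digit dialects, a metadata
  sidecar attaching river/era/year labels, and the `TemporalStudy` container
  of per-river, per-era samples.
- **Within-sample diversity** (`tempopg.diversity`) — observed and unbiased
  expected heterozygosity, F_IS, rarefied allelic richness
  `A_R = Σ_a [1 − C(n−c_a, g)/C(n, g)]`, a Markov-chain exact test of
  Hardy–Weinberg proportions and a conditional exact test of genotypic
  linkage disequilibrium.
- **Differentiation** (`tempopg.fst`) — Weir & Cockerham variance-component
  θ (per locus, pairwise, temporal, global; ratio-of-sums multilocus
  combination; negative estimates reported as computed), permutation
  p-values, a bootstrap test of temporal decline in global θ (per replicate:
  30% of individuals per population, 7 of 22 markers), Mantel tests and OLS
  utilities.
- **Assignment/exclusion** (`tempopg.assignment`) — Rannala–Mountain
  Dirichlet-posterior genotype likelihoods, leave-one-out self-assignment,
  and Monte-Carlo exclusion of contemporary fish from historical baselines.
- **Drift null** (`tempopg.drift`) — gene-dropping Wright–Fisher simulation
  from the observed historical sample over an Ne grid
  {25, 50, 75, 100, 200, 300, 400, 500}, 5-year generations, with
  exceedance p-values for the observed temporal θ, drift-conditioned global
  θ and allelic-richness distributions.
- **Effective size** (`tempopg.ne_ld`) — single-sample LD-based Ne from
  Burrows composite r², with the bias-corrected sampling expectation, the
  infinity convention for non-positive drift signal and jackknife +
  parametric confidence intervals.
- **Synthetic studies** (`tempopg.synthetic`) — a generator emulating a
  21-river, 22-locus microsatellite survey with hierarchical wild structure
  (global θ ≈ 0.04), nine bottleneck-founded farm strains, and per-river
  introgression schedules, with a truth record for recovery tests.

## Worked example

```python
import tempopg as t

cfg = t.ScenarioConfig(seed=0, introgression={i: 0.3 for i in range(6)})
study, truth = t.scenario_study(cfg)         # 21 rivers, 2 eras, 22 loci

theta, p = t.temporal_fst(study, "river01", permutations=199, seed=1)
print(theta, p)                              # 0.0222  0.005

intro = [pop for pop, m in truth.introgression.items() if m > 0]
gh = t.global_theta([study.get(p, "historical") for p in intro])
gc = t.global_theta([study.get(p, "contemporary") for p in intro])
boot = t.bootstrap_global_fst_difference(study, replicates=500, seed=2,
                                         populations=intro)
print(gh, gc, boot.p_one_sided)              # 0.042  0.005  0.002
```

The six introgressed rivers show a large, significant temporal θ and the
global θ among them collapses from ≈0.04 to ≈0.005 — the bootstrap
one-sided p of 0.002 says historical structure exceeded contemporary
structure in essentially every resample.  The fifteen quiet rivers show
neither signal.

The same sequence on the synthetic study, plus the drift null, Ne
estimation and the packaged-table regressions, is scripted under
`analysis/01_simulate_study.py` … `analysis/07_fixture_tables.py`; each
writes its tables under `results/`.

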