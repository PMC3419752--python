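import numpy as np
import pytest

from tempopg.drift import (
    DriftConfig,
    _drop_replicates,
    drift_allelic_richness,
    drift_global_fst,
    drift_pvalue,
    gene_drop,
    generations_between,
)
from tempopg.genepop import SampleSet, build_temporal_study
from tempopg.synthetic import ScenarioConfig, sample_genotypes, scenario_study

from conftest import sample_from_genotype_counts


class TestGenerations:
    @pytest.mark.parametrize(
        "hist, contemp, expect",
        [
            ((1980, 1980), (2008, 2008), 6),   # ceil(28/5)
            ((2000, 2000), (2003, 2003), 1),   # floor at one generation
            ((1971, 1973), (2010, 2010), 8),   # midpoints 1972 -> 2010
        ],
    )
    def test_ceil_rule(self, hist, contemp, expect):
        assert generations_between(hist, contemp) == expect

    def test_negative_interval_rejected(self):
        with pytest.raises(ValueError):
            generations_between((2010, 2010), (1980, 1980))


def _hist_sample(freqs, n=60, seed=1):
    return sample_genotypes(
        np.atleast_2d(freqs), n, seed=seed, population="r",
        era="historical", years=(1980, 1980),
    )


class TestGeneDrop:
    def test_zero_generations_preserves_mean_frequencies(self):
        freqs = [np.array([0.6, 0.3, 0.1])]
        rng = np.random.default_rng(2)
        sims = _drop_replicates(freqs, 50, 0, 50, 500, rng)
        counts = np.bincount(sims.ravel(), minlength=3)
        p_hat = counts / counts.sum()
        se = np.sqrt(freqs[0] * (1 - freqs[0]) / counts.sum())
        assert np.all(np.abs(p_hat - freqs[0]) < 4 * se + 1e-9)

    def test_tiny_ne_fixes_biallelic_locus(self):
        # a single breeding pair loses heterozygosity by ~0.809/generation
        # (full-sib line), so 30 generations push fixation past 99%
        freqs = [np.array([0.5, 0.5])]
        rng = np.random.default_rng(3)
        sims = _drop_replicates(freqs, 2, 30, 2, 300, rng)
        fixed = 0
        for r in range(300):
            if len(np.unique(sims[r])) == 1:
                fixed += 1
        assert fixed >= 297

    def test_drift_variance_matches_wright_fisher(self):
        """E[(p_G - p0)^2] = p0 q0 (1 - (1-1/(2Ne))^(G+1)), founding included."""
        p0 = 0.5
        ne, G = 100, 6
        rng = np.random.default_rng(4)
        sims = _drop_replicates([np.array([p0, 1 - p0])], ne, G, ne, 2000, rng)
        p_g = (sims == 0).mean(axis=(1, 2, 3))
        var = float(((p_g - p0) ** 2).mean())
        expect = p0 * (1 - p0) * (1 - (1 - 1 / (2 * ne)) ** (G + 1))
        assert var == pytest.approx(expect, rel=0.15)

    def test_heterozygosity_decay_closed_form(self):
        """Unbiased He after G generations ~ He0 (1-1/(2Ne))^G."""
        rng = np.random.default_rng(5)
        freqs = [rng.dirichlet(np.ones(8)) for _ in range(10)]
        he0 = np.mean([1 - (p**2).sum() for p in freqs])
        for ne, G in [(25, 6), (100, 2)]:
            sims = _drop_replicates(freqs, ne, G, ne, 400,
                                    np.random.default_rng(ne + G))
            he = []
            for r in range(400):
                tot = 0.0
                for j in range(10):
                    cnt = np.bincount(sims[r, :, j, :].ravel(), minlength=8)
                    n = cnt.sum()
                    p = cnt / n
                    tot += (n / (n - 1)) * (1 - (p**2).sum())
                he.append(tot / 10)
            expect = he0 * (1 - 1 / (2 * ne)) ** G
            assert np.mean(he) == pytest.approx(expect, rel=0.02)

    def test_gene_drop_returns_valid_sample(self):
        hist = _hist_sample(np.stack([[0.5, 0.5], [0.3, 0.7]]))
        sim = gene_drop(hist, ne=50, generations=3, out_n=40, seed=1)
        assert sim.n == 40
        assert sim.genotypes.locus_names == hist.genotypes.locus_names
        assert sim.population == "r"


def _temporal_study(m=0.0, seed=2, n=60, n_pops=2):
    cfg = ScenarioConfig(
        n_populations=n_pops, n_loci=22, seed=seed,
        introgression={0: m} if m else {},
        sample_sizes={(i, e): n for i in range(n_pops)
                      for e in ("historical", "contemporary")},
    )
    study, _ = scenario_study(cfg)
    return study


class TestDriftPvalue:
    def test_default_grid_and_replicates(self):
        cfg = DriftConfig()
        assert cfg.ne_grid == (25, 50, 75, 100, 200, 300, 400, 500)
        assert cfg.replicates == 1000

    def test_identical_eras_never_exceeded(self):
        h = sample_from_genotype_counts(
            "r", {(1, 1): 20, (1, 2): 15, (2, 2): 10}, era="historical",
            years=(1980, 1980))
        c = SampleSet("r", "contemporary", (2010, 2010), type(h.genotypes)(
            h.genotypes.locus_names,
            [f"c{i}" for i in range(h.n)],
            ["r"] * h.n,
            h.genotypes.calls.copy(),
        ))
        study = build_temporal_study([h, c])
        res = drift_pvalue(study, "r",
                           DriftConfig(ne_grid=(50, 200), replicates=200, seed=1))
        for ne in (50, 200):
            assert res.p_exceed[ne] > 0.9

    def test_p_nonincreasing_in_ne_for_real_signal(self):
        study = _temporal_study(m=0.2, seed=7)
        res = drift_pvalue(
            study, "river01",
            DriftConfig(ne_grid=(25, 75, 200, 500), replicates=300, seed=2),
        )
        ps = [res.p_exceed[ne] for ne in (25, 75, 200, 500)]
        assert all(b <= a + 0.05 for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 0.05  # drift at large Ne cannot explain admixture

    def test_mean_simulated_theta_decreasing_in_ne(self):
        study = _temporal_study(seed=8)
        res = drift_pvalue(
            study, "river01",
            DriftConfig(ne_grid=(25, 100, 500), replicates=300, seed=3),
        )
        means = [res.simulated[ne].mean() for ne in (25, 100, 500)]
        assert means[0] > means[1] > means[2]

    def test_reproducible_under_same_seed(self):
        study = _temporal_study(seed=9)
        cfg = DriftConfig(ne_grid=(50,), replicates=150, seed=4)
        r1 = drift_pvalue(study, "river01", cfg)
        r2 = drift_pvalue(study, "river01", cfg)
        np.testing.assert_array_equal(r1.simulated[50], r2.simulated[50])
        assert r1.p_exceed == r2.p_exceed

    def test_p_string_convention(self):
        study = _temporal_study(m=0.3, seed=10)
        res = drift_pvalue(study, "river01",
                           DriftConfig(ne_grid=(500,), replicates=200, seed=5))
        if res.p_exceed[500] == 0:
            assert res.p_string(500).startswith("<")


class TestDriftGlobalAndRichness:
    def test_global_theta_increases_as_ne_decreases(self):
        study = _temporal_study(seed=11, n_pops=3)
        cfg = DriftConfig(ne_grid=(25, 100, 500), replicates=200, seed=6)
        sims, obs_h, _ = drift_global_fst(
            study, ["river01", "river02", "river03"], cfg)
        means = [sims[ne].mean() for ne in (25, 100, 500)]
        assert means[0] > means[1] > means[2]
        # drift never systematically erodes among-population structure
        for ne in (25, 100, 500):
            assert sims[ne].mean() >= obs_h - 0.01

    def test_large_ne_approaches_observed_historical(self):
        study = _temporal_study(seed=12, n_pops=3)
        cfg = DriftConfig(ne_grid=(5000,), replicates=150, seed=7)
        sims, obs_h, _ = drift_global_fst(
            study, ["river01", "river02", "river03"], cfg)
        assert sims[5000].mean() == pytest.approx(obs_h, abs=0.01)

    def test_simulated_richness_never_exceeds_historical(self):
        study = _temporal_study(seed=13)
        cfg = DriftConfig(ne_grid=(25, 500), replicates=200, seed=8)
        sims, obs_h, _ = drift_allelic_richness(study, "river01", cfg)
        assert sims[25].mean() < sims[500].mean()   # stronger drift loses more
        for ne in (25, 500):
            assert sims[ne].mean() <= obs_h + 0.5

    def test_admixed_contemporary_flagged_drift_incompatible(self):
        """Farm admixture raises observed A_R above the simulated null."""
        study = _temporal_study(m=0.3, seed=14)
        cfg = DriftConfig(ne_grid=(500,), replicates=200, seed=9)
        sims, obs_h, obs_c = drift_allelic_richness(study, "river01", cfg)
        q99 = np.quantile(sims[500], 0.99)
        assert obs_c > q99
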