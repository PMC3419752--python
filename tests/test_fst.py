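import math
import warnings

import numpy as np
import pytest

from tempopg.fst import (
    bootstrap_global_fst_difference,
    global_theta,
    mantel_test,
    ols_r2,
    pairwise_fst_matrix,
    temporal_fst,
    wc_components,
)
from tempopg.genepop import GenotypeTable, SampleSet, build_temporal_study
from tempopg.synthetic import ScenarioConfig, sample_genotypes, scenario_study

from conftest import hwe_sample, sample_from_genotype_counts


def wc_hand_biallelic(p_list, h_list, n_list):
    """Independent textbook evaluation of the 1984 estimator (both alleles)."""
    r = len(n_list)
    nbar = sum(n_list) / r
    nc = (sum(n_list) - sum(x * x for x in n_list) / sum(n_list)) / (r - 1)
    a = b = c = 0.0
    for u in range(2):
        pbar = sum(n * p[u] for n, p in zip(n_list, p_list)) / (r * nbar)
        s2 = sum(n * (p[u] - pbar) ** 2 for n, p in zip(n_list, p_list)) / (
            (r - 1) * nbar
        )
        hbar = sum(n * h[u] for n, h in zip(n_list, h_list)) / (r * nbar)
        a += (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b += (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c += hbar / 2
    return a / (a + b + c)


class TestWcComponents:
    def test_hand_evaluated_two_pop_case(self):
        s1 = sample_from_genotype_counts("p1", {(1, 1): 8, (1, 2): 2})
        s2 = sample_from_genotype_counts("p2", {(1, 1): 2, (1, 2): 2, (2, 2): 6})
        comp = wc_components([s1, s2])
        hand = wc_hand_biallelic(
            [(0.9, 0.1), (0.3, 0.7)],
            [(0.2, 0.2), (0.2, 0.2)],
            [10, 10],
        )
        assert comp.theta_multilocus == pytest.approx(hand, abs=1e-12)

    @pytest.mark.parametrize("counts", [
        {(1, 1): 6, (1, 2): 6, (2, 2): 3},
        {(1, 1): 12, (2, 2): 4},
        {(1, 2): 10, (2, 2): 10},
    ])
    def test_hand_evaluation_across_fixtures(self, counts):
        s1 = sample_from_genotype_counts("p1", counts)
        s2 = sample_from_genotype_counts("p2", {(1, 1): 5, (1, 2): 5, (2, 2): 5})

        def stats(s):
            col = s.genotypes.calls[:, 0, :]
            n = len(col)
            p1 = (col == 1).sum() / (2 * n)
            het = (col[:, 0] != col[:, 1])
            h1 = het.sum() / n
            return (p1, 1 - p1), (h1, h1), n

        (p_a, h_a, n_a), (p_b, h_b, n_b) = stats(s1), stats(s2)
        hand = wc_hand_biallelic([p_a, p_b], [h_a, h_b], [n_a, n_b])
        got = wc_components([s1, s2]).theta_multilocus
        assert got == pytest.approx(hand, abs=1e-12)

    def test_fixed_difference_theta_one(self):
        s1 = sample_from_genotype_counts("p1", {(1, 1): 20})
        s2 = sample_from_genotype_counts("p2", {(2, 2): 20})
        assert wc_components([s1, s2]).theta_multilocus == pytest.approx(1.0)

    def test_identical_samples_nonpositive(self):
        s1 = sample_from_genotype_counts("p1", {(1, 1): 20, (1, 2): 8, (2, 2): 2})
        s2 = sample_from_genotype_counts("p2", {(1, 1): 20, (1, 2): 8, (2, 2): 2})
        assert wc_components([s1, s2]).theta_multilocus <= 0

    def test_monomorphic_locus_leaves_theta_unchanged(self, rng):
        f1 = np.array([[0.7, 0.3], [0.2, 0.8]])
        f2 = np.array([[0.3, 0.7], [0.6, 0.4]])
        s1 = sample_genotypes(f1, 40, seed=1, population="p1")
        s2 = sample_genotypes(f2, 40, seed=2, population="p2")
        base = wc_components([s1, s2]).theta_multilocus

        def with_mono(s, pop):
            calls = np.concatenate(
                [s.genotypes.calls, np.full((40, 1, 2), 5, dtype=np.int32)], axis=1
            )
            g = GenotypeTable(["L01", "L02", "MONO"],
                              s.genotypes.individual_ids, [pop] * 40, calls)
            return SampleSet(pop, "historical", (2000, 2000), g)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aug = wc_components([with_mono(s1, "p1"), with_mono(s2, "p2")])
        assert aug.theta_multilocus == pytest.approx(base, abs=1e-12)
        assert "MONO" in aug.excluded_loci

    def test_requires_two_samples(self):
        s1 = sample_from_genotype_counts("p1", {(1, 2): 5})
        with pytest.raises(ValueError):
            wc_components([s1])


class TestPairwiseAndTemporal:
    def _study(self, seed=0, n_pops=4):
        cfg = ScenarioConfig(
            n_populations=n_pops, n_loci=10, seed=seed,
            sample_sizes={(i, e): 40 for i in range(n_pops)
                          for e in ("historical", "contemporary")},
        )
        study, _ = scenario_study(cfg)
        return study

    def test_matrix_symmetric_consistent_with_pairwise_calls(self):
        study = self._study()
        pops, theta, _ = pairwise_fst_matrix(study, "historical")
        assert np.allclose(theta, theta.T)
        assert np.allclose(np.diag(theta), 0)
        samples = study.era_samples("historical")
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                direct = wc_components([samples[i], samples[j]]).theta_multilocus
                assert theta[i, j] == pytest.approx(direct, abs=1e-12)

    def test_temporal_theta_of_identical_eras_nonpositive(self):
        h = sample_from_genotype_counts("r", {(1, 1): 15, (1, 2): 10, (2, 2): 5},
                                        era="historical")
        c = sample_from_genotype_counts("r", {(1, 1): 15, (1, 2): 10, (2, 2): 5},
                                        era="contemporary")
        study = build_temporal_study([h, c])
        theta, _ = temporal_fst(study, "r")
        assert theta <= 0

    def test_temporal_order_invariance(self, rng):
        study = self._study(seed=3, n_pops=2)
        t1, _ = temporal_fst(study, "river01")
        s = study.get("river01", "historical")
        perm = rng.permutation(s.n)
        g = GenotypeTable(
            s.genotypes.locus_names,
            [s.genotypes.individual_ids[i] for i in perm],
            ["river01"] * s.n,
            s.genotypes.calls[perm],
        )
        study.samples[("river01", "historical")] = SampleSet(
            "river01", "historical", s.years, g
        )
        t2, _ = temporal_fst(study, "river01")
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_missing_era_errors_with_population_name(self):
        h = sample_from_genotype_counts("lonely", {(1, 2): 5}, era="historical")
        study = build_temporal_study([h])
        with pytest.raises(ValueError, match="lonely"):
            temporal_fst(study, "lonely")

    def test_admixture_detected_at_strict_alpha(self):
        """A 30%-per-generation introgressed river shows significant theta."""
        cfg = ScenarioConfig(
            n_populations=2, n_loci=22, seed=11, introgression={0: 0.3},
            sample_sizes={(i, e): 80 for i in range(2)
                          for e in ("historical", "contemporary")},
        )
        study, _ = scenario_study(cfg)
        theta, p = temporal_fst(study, "river01", permutations=1999, seed=5)
        assert theta > 0.01
        assert p < 0.001


class TestBootstrap:
    def _null_study(self, seed):
        rng = np.random.default_rng(seed)
        samples = []
        for i in range(5):
            freqs = np.stack([rng.dirichlet(np.ones(6)) for _ in range(22)])
            for era in ("historical", "contemporary"):
                samples.append(
                    sample_genotypes(freqs, 40, seed=rng, population=f"r{i}",
                                     era=era, years=(1980, 1980))
                )
        return build_temporal_study(samples)

    def test_exchangeable_null_p_near_half(self):
        study = self._null_study(1)
        res = bootstrap_global_fst_difference(study, replicates=400, seed=2)
        assert 0.1 < res.p_one_sided < 0.9
        assert len(res.deltas) == 400

    def test_defaults_follow_design(self):
        import inspect

        sig = inspect.signature(bootstrap_global_fst_difference)
        assert sig.parameters["replicates"].default == 10000
        assert sig.parameters["frac_individuals"].default == 0.30
        assert sig.parameters["n_markers"].default == 7

    def test_decline_detected_in_admixed_scenario(self):
        cfg = ScenarioConfig(
            seed=21, introgression={i: 0.3 for i in range(6)},
            sample_sizes={(i, e): 50 for i in range(21)
                          for e in ("historical", "contemporary")},
        )
        study, _ = scenario_study(cfg)
        changed = study.populations()[:6]
        res = bootstrap_global_fst_difference(
            study, replicates=500, seed=3, populations=changed
        )
        assert res.theta_hist > res.theta_contemp
        assert res.p_one_sided < 0.05

    def test_tiny_sample_rejected(self):
        study = self._null_study(2)
        with pytest.raises(ValueError, match="r0"):
            bootstrap_global_fst_difference(study, frac_individuals=0.02,
                                            replicates=100)


class TestMantel:
    def test_perfect_correlation(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        r, _ = mantel_test(d, 2 * d, permutations=99, seed=1)
        assert r == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self, rng):
        import itertools

        def sym(rng):
            m = np.zeros((4, 4))
            iu = np.triu_indices(4, 1)
            m[iu] = rng.random(6)
            return m + m.T

        d1, d2 = sym(rng), sym(rng)
        il = np.tril_indices(4, -1)
        r_obs = np.corrcoef(d1[il], d2[il])[0, 1]
        hits = 0
        count = 0
        for perm in itertools.permutations(range(4)):
            p = np.array(perm)
            r = np.corrcoef(d1[il], d2[np.ix_(p, p)][il])[0, 1]
            count += 1
            if abs(r) >= abs(r_obs) - 1e-12:
                hits += 1
        exact = hits / count
        _, p_mc = mantel_test(d1, d2, permutations=5000, seed=4)
        assert p_mc == pytest.approx(exact, abs=0.03)

    def test_cross_check_against_skbio(self, rng):
        from skbio.stats.distance import DistanceMatrix, mantel

        n = 8
        a = rng.random((n, n))
        d1 = (a + a.T) / 2
        np.fill_diagonal(d1, 0)
        b = d1 + 0.3 * rng.random((n, n))
        d2 = (b + b.T) / 2
        np.fill_diagonal(d2, 0)
        r_ours, _ = mantel_test(d1, d2, permutations=0)
        res = mantel(DistanceMatrix(d1), DistanceMatrix(d2), permutations=0)
        r_skbio = res[0] if isinstance(res, tuple) else res.statistic
        assert r_ours == pytest.approx(float(r_skbio), abs=1e-10)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            mantel_test(np.zeros((3, 3)), np.zeros((4, 4)))


class TestOls:
    def test_identity_line(self):
        x = np.arange(10.0)
        r2, slope, p = ols_r2(x, x)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_matches_normal_equations(self, rng):
        x = rng.random(15)
        y = 2 * x + rng.random(15)
        r2, slope, p = ols_r2(x, y)
        X = np.stack([np.ones(15), x], axis=1)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert slope == pytest.approx(beta[1], abs=1e-10)
        assert r2 == pytest.approx(1 - (resid**2).sum() / ss_tot, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ols_r2(np.ones(5), np.arange(5.0))
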