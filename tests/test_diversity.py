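import itertools
import math

import numpy as np
import pytest

from tempopg.diversity import (
    DEFAULT_CHAIN,
    allele_counts,
    diversity_summary,
    enumerate_hwe_exact,
    enumerate_ld_2x2,
    hwe_exact_mc,
    ld_exact_mc,
    rarefied_richness,
)
from tempopg.genepop import GenotypeTable, SampleSet

from conftest import hwe_sample, random_table, sample_from_genotype_counts


class TestAlleleCounts:
    def test_homozygous_sample(self):
        s = sample_from_genotype_counts("p", {(1, 1): 10})
        act = allele_counts(s)
        assert act.counts[0] == {1: 20}
        assert act.n_genes[0] == 20

    def test_missing_excluded(self):
        calls = np.array([[[1, 2]], [[-1, -1]]], dtype=np.int32)
        g = GenotypeTable(["L1"], ["a", "b"], ["p", "p"], calls)
        act = allele_counts(SampleSet("p", "historical", (2000, 2000), g))
        assert act.counts[0] == {1: 1, 2: 1}
        assert act.n_genes[0] == 2

    def test_matches_brute_force_tally(self, rng):
        t = random_table(rng, 50, 6, n_pops=1, max_code=9, missing_rate=0.1)
        s = SampleSet("pop1", "historical", (2000, 2000), t)
        act = allele_counts(s)
        for j in range(6):
            tally: dict[int, int] = {}
            for i in range(50):
                for a in t.calls[i, j]:
                    if a != -1:
                        tally[a] = tally.get(a, 0) + 1
            assert act.counts[j] == tally


class TestRarefaction:
    def test_worked_example(self):
        # counts {A:3, B:1}, g=2: 2 - C(1,2)/C(4,2) - C(3,2)/C(4,2) = 1.5
        s = sample_from_genotype_counts("p", {(1, 1): 1, (1, 2): 1})
        ar = rarefied_richness(allele_counts(s), 2)
        assert ar[0] == pytest.approx(1.5)

    def test_monomorphic_locus(self):
        s = sample_from_genotype_counts("p", {(1, 1): 10})
        summ = diversity_summary(s, rarefaction_g=5)
        assert summ.a_r[0] == pytest.approx(1.0)
        assert summ.he[0] == pytest.approx(0.0)
        assert math.isnan(summ.fis[0])

    def test_full_sample_identity(self):
        s = sample_from_genotype_counts("p", {(1, 2): 3, (3, 4): 2})
        act = allele_counts(s)
        ar = rarefied_richness(act, int(act.n_genes[0]))
        assert ar[0] == pytest.approx(4.0)

    def test_closed_form_equals_enumeration(self, rng):
        """Hypergeometric formula vs exhaustive subsampling, n_genes <= 8."""
        for _ in range(30):
            n = int(rng.integers(3, 9))
            g = int(rng.integers(2, n + 1))
            genes = rng.integers(1, 5, size=n)
            vals, cnts = np.unique(genes, return_counts=True)
            from tempopg.diversity import _rarefy

            closed = _rarefy(cnts, g)
            brute = np.mean(
                [len(set(c)) for c in itertools.combinations(genes, g)]
            )
            assert closed == pytest.approx(brute, abs=1e-10)

    def test_monotone_in_g(self):
        s = sample_from_genotype_counts("p", {(1, 2): 4, (3, 3): 2, (4, 1): 2})
        act = allele_counts(s)
        values = [rarefied_richness(act, g)[0] for g in range(2, 17)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_rejects_tiny_g(self):
        s = sample_from_genotype_counts("p", {(1, 2): 4})
        with pytest.raises(ValueError):
            rarefied_richness(allele_counts(s), 1)


class TestDiversitySummary:
    def test_he_invariant_under_relabeling(self):
        s1 = sample_from_genotype_counts("p", {(1, 1): 3, (1, 2): 4, (2, 2): 3})
        s2 = sample_from_genotype_counts("p", {(7, 7): 3, (7, 9): 4, (9, 9): 3})
        d1 = diversity_summary(s1, 5)
        d2 = diversity_summary(s2, 5)
        assert d1.he[0] == pytest.approx(d2.he[0])
        assert d1.ho[0] == pytest.approx(d2.ho[0])

    def test_unbiased_he_small_sample(self):
        # one het individual: Ho=1, naive He=0.5, unbiased (2/1)*0.5=1
        s = sample_from_genotype_counts("p", {(1, 2): 1})
        d = diversity_summary(s, rarefaction_g=2, rarefaction_unit="genes")
        assert d.he[0] == pytest.approx(1.0)

    def test_order_invariance(self, rng):
        t = random_table(rng, 30, 4, n_pops=1, max_code=9, missing_rate=0.05)
        s = SampleSet("pop1", "historical", (2000, 2000), t)
        perm = rng.permutation(30)
        t2 = GenotypeTable(
            t.locus_names,
            [t.individual_ids[i] for i in perm],
            ["pop1"] * 30,
            t.calls[perm],
        )
        s2 = SampleSet("pop1", "historical", (2000, 2000), t2)
        d1, d2 = diversity_summary(s, 10), diversity_summary(s2, 10)
        np.testing.assert_allclose(d1.he, d2.he)
        np.testing.assert_allclose(d1.a_r, d2.a_r)


class TestHweExact:
    def test_default_chain_parameters(self):
        assert DEFAULT_CHAIN == (10000, 1000, 10000)

    def test_matches_full_enumeration(self):
        s = sample_from_genotype_counts("p", {(1, 1): 3, (2, 2): 3})
        res = hwe_exact_mc(s, "L1", chain=(2000, 50, 400), seed=1)
        exact = enumerate_hwe_exact(6, 6, 0)
        assert abs(res.p_value - exact) <= 3 * max(res.mc_se, 1e-3)

    def test_monomorphic_not_applicable(self):
        s = sample_from_genotype_counts("p", {(1, 1): 10})
        res = hwe_exact_mc(s, "L1", chain=(100, 5, 20), seed=1)
        assert not res.applicable

    def test_equilibrium_data_not_rejected(self):
        """Samples drawn under HWE should rarely give small p."""
        hits = 0
        for seed in range(20):
            s = hwe_sample(np.array([[0.5, 0.3, 0.2]]), 100, seed)
            res = hwe_exact_mc(s, "L01", chain=(500, 20, 100), seed=seed)
            if res.p_value > 0.05:
                hits += 1
        assert hits >= 17

    def test_null_pvalues_roughly_uniform(self):
        """KS sanity check of the p-value distribution under the null."""
        from scipy.stats import kstest

        ps = []
        for seed in range(60):
            s = hwe_sample(np.array([[0.6, 0.4]]), 60, seed + 100)
            res = hwe_exact_mc(s, "L01", chain=(500, 20, 100), seed=seed)
            ps.append(res.p_value)
        # discrete support makes exact uniformity unattainable; only guard
        # against gross miscalibration
        stat, _ = kstest(ps, "uniform")
        assert stat < 0.35


class TestLdExact:
    def test_duplicated_locus_detected(self, rng):
        base = hwe_sample(np.array([[0.4, 0.3, 0.3]]), 50, 7)
        calls = np.concatenate([base.genotypes.calls] * 2, axis=1)
        g = GenotypeTable(["A", "B"], base.genotypes.individual_ids,
                          ["p"] * 50, calls)
        s = SampleSet("p", "historical", (2000, 2000), g)
        res = ld_exact_mc(s, ("A", "B"), chain=(0, 30, 100), seed=2)
        assert res.p_value < 0.001

    def test_2x2_matches_enumeration(self, rng):
        g1 = rng.integers(0, 2, 30)
        g2 = (g1 ^ (rng.random(30) < 0.4)).astype(int)
        calls = np.zeros((30, 2, 2), dtype=np.int32)
        calls[:, 0, :] = (1 + g1)[:, None]
        calls[:, 1, :] = (1 + g2)[:, None]
        g = GenotypeTable(["A", "B"], [f"i{k}" for k in range(30)], ["p"] * 30, calls)
        s = SampleSet("p", "historical", (2000, 2000), g)
        res = ld_exact_mc(s, ("A", "B"), chain=(0, 50, 200), seed=3)
        tab = np.zeros((2, 2), dtype=int)
        for a, b in zip(g1, g2):
            tab[a, b] += 1
        exact = enumerate_ld_2x2(tab)
        assert abs(res.p_value - exact) <= 3 * max(res.mc_se, 2e-3) + 1e-4

    def test_independent_loci_rejection_rate(self):
        """Type-I error close to alpha for independent loci."""
        rejections = 0
        n_rep = 120
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            freqs = np.stack([rng.dirichlet(np.ones(3)) for _ in range(2)])
            s = hwe_sample(freqs, 40, seed + 1000)
            res = ld_exact_mc(s, ("L01", "L02"), chain=(0, 20, 50), seed=seed)
            if res.applicable and res.p_value < 0.05:
                rejections += 1
        # binomial 99% band around 0.05 with n=120: [0, 12]
        assert rejections <= 12

    def test_degenerate_locus_not_applicable(self):
        s = sample_from_genotype_counts("p", {(1, 1): 10})
        calls = np.concatenate([s.genotypes.calls, s.genotypes.calls], axis=1)
        g = GenotypeTable(["A", "B"], s.genotypes.individual_ids, ["p"] * 10, calls)
        s2 = SampleSet("p", "historical", (2000, 2000), g)
        res = ld_exact_mc(s2, ("A", "B"), chain=(0, 5, 20), seed=1)
        assert not res.applicable
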