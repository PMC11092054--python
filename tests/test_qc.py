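import numpy as np
import pytest
from scipy.stats import chi2

from ibdpd.qc import (
    covariate_table,
    flag_het_outliers,
    genotype_counts,
    hwe_enumeration_probs,
    hwe_exact_p,
    ld_prune,
    ld_r2,
    mac_filter,
    pca,
    select_common,
)
from ibdpd.simulate import SimulationConfig, simulate_cohort


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_p(100, 0, 0) == 1.0

    def test_small_count_enumeration_oracle(self):
        # (3,0,3): rare allele count 6, het in {0,2,4,6}; multinomial weights
        # 20, 360, 480, 64 (sum 924); p = P(het=0) = 20/924
        assert hwe_exact_p(3, 0, 3) == pytest.approx(20 / 924)
        hets, probs = hwe_enumeration_probs(3, 0, 3)
        np.testing.assert_array_equal(hets, [0, 2, 4, 6])
        np.testing.assert_allclose(probs, np.array([20, 360, 480, 64]) / 924)

    def test_enumeration_probs_sum_to_one(self):
        for counts in [(3, 0, 3), (50, 20, 5), (10, 10, 10), (1, 1, 0)]:
            _, probs = hwe_enumeration_probs(*counts)
            assert probs.sum() == pytest.approx(1.0)

    def test_large_sample_matches_chisq(self):
        # moderate deviation, large n: exact and asymptotic p agree within 10%
        n_AA, n_Aa, n_aa = 260, 360, 80
        n = n_AA + n_Aa + n_aa
        p = (2 * n_AA + n_Aa) / (2 * n)
        exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
        obs = np.array([n_AA, n_Aa, n_aa])
        stat = ((obs - exp) ** 2 / exp).sum()
        asym = chi2.sf(stat, 1)
        assert hwe_exact_p(n_AA, n_Aa, n_aa) == pytest.approx(asym, rel=0.10)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)


class TestSelectCommon:
    def test_maf_and_hwe_filters(self, null_cohort):
        _, bundle, truth = null_cohort
        kept = select_common(bundle, maf_min=0.05, hwe_alpha=1e-6)
        for j in kept:
            assert bundle.variants[j].cohort_maf > 0.05
            counts = genotype_counts(bundle.genotypes[:, j])
            assert hwe_exact_p(*counts) >= 1e-6
        # gene-panel variants enter only when genuinely common and in HWE
        # (drifted variants can violate HWE via the Wahlund effect)
        rare = set(truth.index[truth["model"] != "common"])
        for j in rare - set(kept):
            if bundle.variants[j].cohort_maf > 0.05:
                counts = genotype_counts(bundle.genotypes[:, j])
                assert hwe_exact_p(*counts) < 1e-6


class TestLd:
    def test_identical_and_opposite_vectors(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        assert ld_r2(x, x) == pytest.approx(1.0)
        assert ld_r2(x, 1 - x) == pytest.approx(1.0)  # perfect negative corr

    def test_zero_variance_is_nan(self):
        x = np.array([1.0, 1.0, 1.0, 1.0])
        y = np.array([0.0, 1.0, 2.0, 0.0])
        assert np.isnan(ld_r2(x, y))

    def test_prune_removes_duplicates(self, null_cohort):
        _, bundle, _ = null_cohort
        # triplicate one common column; only one copy survives
        from ibdpd.types import CohortBundle, recompute_cohort_freqs
        import copy

        common = select_common(bundle)
        j = common[0]
        G = np.column_stack([bundle.genotypes[:, j]] * 3)
        variants = [copy.deepcopy(bundle.variants[j]) for _ in range(3)]
        for k, v in enumerate(variants):
            v.pos = v.pos + k
        b = CohortBundle(
            samples=bundle.samples, variants=variants, genotypes=G,
            gene_annotations=bundle.gene_annotations,
        )
        recompute_cohort_freqs(b)
        kept = ld_prune(b, [0, 1, 2], r2_max=0.2)
        assert kept == [0]

    def test_pruned_set_has_no_high_ld_pair(self, null_cohort):
        _, bundle, _ = null_cohort
        common = select_common(bundle)
        kept = ld_prune(bundle, common, r2_max=0.2, window=None)
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                r2 = ld_r2(bundle.genotypes[:, kept[a]], bundle.genotypes[:, kept[b]])
                assert np.isnan(r2) or r2 <= 0.2 + 1e-12


class TestPca:
    def test_separates_drifted_subpopulations(self):
        cfg = SimulationConfig(
            n_cases=100, n_controls=300, n_genes=10, n_common_variants=500,
            fst=0.1, seed=3,
        )
        bundle, _ = simulate_cohort(cfg)
        kept = ld_prune(bundle, select_common(bundle), r2_max=0.2)
        res = pca(bundle, kept, k=2)
        pop = np.array([s.ancestry_label == "POP2" for s in bundle.samples], float)
        r = abs(np.corrcoef(res.scores[:, 0], pop)[0, 1])
        assert r > 0.9
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)  # descending

    def test_identical_samples_zero_eigenvalues(self, toy_bundle):
        import copy

        from ibdpd.types import CohortBundle

        G = np.ones((4, 3))
        b = CohortBundle(
            samples=toy_bundle.samples,
            variants=[copy.deepcopy(v) for v in toy_bundle.variants],
            genotypes=G,
            gene_annotations=toy_bundle.gene_annotations,
        )
        res = pca(b, [0, 1, 2], k=2)
        assert np.allclose(res.eigenvalues, 0.0)

    def test_sign_convention_reproducible(self, null_cohort):
        _, bundle, _ = null_cohort
        kept = select_common(bundle)
        s1 = pca(bundle, kept, k=2).scores
        s2 = pca(bundle, kept, k=2).scores
        np.testing.assert_allclose(s1, s2)

    def test_k_beyond_rank_rejected(self, toy_bundle):
        with pytest.raises(ValueError):
            pca(toy_bundle, [0, 1, 2], k=4)


class TestMacFilter:
    case_mask = np.array([True, True, False, False, False])

    def test_low_total_mac_rejected(self):
        col = np.array([1.0, 0, 1, 0, 0])  # MAC 2
        assert not mac_filter(col, self.case_mask)

    def test_zero_case_mac_rejected(self):
        col = np.array([0.0, 0, 2, 2, 1])  # MAC 5 but no case alleles
        assert not mac_filter(col, self.case_mask)

    def test_boundary_accepted(self):
        col = np.array([1.0, 0, 1, 1, 0])  # MAC 3, case MAC 1
        assert mac_filter(col, self.case_mask)


class TestHetOutliers:
    def test_equal_counts_not_flagged(self, null_cohort):
        _, bundle, _ = null_cohort
        import copy

        from ibdpd.types import CohortBundle

        G = np.ones((bundle.n_samples, 4))
        b = CohortBundle(
            samples=bundle.samples,
            variants=[copy.deepcopy(v) for v in bundle.variants[:4]],
            genotypes=G,
            gene_annotations=bundle.gene_annotations,
        )
        assert flag_het_outliers(b, [0, 1, 2, 3]) == []

    def test_extreme_sample_flagged(self, null_cohort):
        _, bundle, _ = null_cohort
        G = bundle.genotypes.copy()
        G[0, :200] = 1.0  # one sample heterozygous at 200 sites
        from ibdpd.types import CohortBundle

        b = CohortBundle(
            samples=bundle.samples, variants=bundle.variants, genotypes=G,
            gene_annotations=bundle.gene_annotations,
        )
        flagged = flag_het_outliers(b, list(range(bundle.n_variants)), z_max=4.0)
        assert bundle.sample_ids[0] in flagged

    def test_infinite_threshold_flags_nothing(self, null_cohort):
        _, bundle, _ = null_cohort
        assert flag_het_outliers(
            bundle, list(range(bundle.n_variants)), z_max=np.inf
        ) == []

    def test_too_few_samples_rejected(self, toy_bundle):
        small = toy_bundle.subset_samples(np.array([0, 1]))
        with pytest.raises(ValueError):
            flag_het_outliers(small, [0], z_max=4.0)


def test_covariate_table_columns(null_cohort):
    _, bundle, _ = null_cohort
    kept = select_common(bundle)
    res = pca(bundle, kept, k=2)
    tab = covariate_table(bundle, res, n_pcs=2)
    assert list(tab.columns) == ["sample_id", "sex", "age", "PC1", "PC2"]
    assert set(tab["sex"]) <= {0.0, 1.0}


def test_high_missingness_sample_flagged(null_cohort):
    from ibdpd.qc import flag_high_missingness_samples
    from ibdpd.types import CohortBundle

    _, bundle, _ = null_cohort
    G = bundle.genotypes.copy()
    G[0, : int(0.2 * bundle.n_variants)] = np.nan
    b = CohortBundle(
        samples=bundle.samples, variants=bundle.variants, genotypes=G,
        gene_annotations=bundle.gene_annotations,
    )
    flagged = flag_high_missingness_samples(b, max_frac=0.05)
    assert flagged == [bundle.sample_ids[0]]
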