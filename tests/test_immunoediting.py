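"""Correlation machinery, length adjustment, clustering and embedding."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from msiedit import (
    CmsLocus,
    SimulationConfig,
    build_feature_matrix,
    cluster_cms,
    gels_mutation_correlation,
    hla_restricted_correlation,
    kernel_pca_embed,
    pearson_with_ci,
    relative_mutation_frequency,
    simulate_cohort,
    simulate_gels,
    simulate_loci,
)
from msiedit.immunoediting import CmsFeatureMatrix
from msiedit.simulate import calibrate_beta


class TestPearsonWithCI:
    def test_perfect_anticorrelation(self):
        res = pearson_with_ci([1, 2, 3], [3, 2, 1])
        assert res.r == pytest.approx(-1.0)

    def test_perfect_correlation(self):
        res = pearson_with_ci([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.r == pytest.approx(1.0)

    def test_constant_input_error(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_ci([1, 1, 1], [1, 2, 3])

    def test_null_distribution_at_n41(self):
        """|r| of independent data at n=41 rarely exceeds the 5% bound 0.308."""
        rng = np.random.default_rng(0)
        exceed = sum(
            abs(pearson_with_ci(rng.uniform(size=41), rng.uniform(size=41)).r) > 0.308
            for _ in range(400)
        )
        assert exceed / 400 < 0.10

    def test_fisher_ci_coverage(self):
        """The 95% Fisher-z interval covers the true correlation ~95% of the time."""
        rng = np.random.default_rng(1)
        rho, n, covered = 0.4, 41, 0
        cov = np.array([[1, rho], [rho, 1]])
        for _ in range(1000):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            res = pearson_with_ci(xy[:, 0], xy[:, 1])
            covered += res.ci_low <= rho <= res.ci_high
        assert 0.93 <= covered / 1000 <= 0.97

    def test_ci_brackets_r(self):
        rng = np.random.default_rng(2)
        res = pearson_with_ci(rng.normal(size=30), rng.normal(size=30))
        assert res.ci_low <= res.r <= res.ci_high


class TestGelsMutationCorrelation:
    def test_planted_editing_detected(self):
        cfg = SimulationConfig(seed=3)
        rng = np.random.default_rng(3)
        loci = simulate_loci(cfg, rng)
        gels = dict(zip([l.locus_id for l in loci], simulate_gels(len(loci), rng)))
        beta = calibrate_beta(loci, gels, cfg, target_r=-0.4)
        cfg = SimulationConfig(seed=3, beta=beta)
        cohort, _ = simulate_cohort(cfg, gels=gels, loci=loci)
        res = gels_mutation_correlation(cohort, gels, stratum="b2m_wt")
        assert res.r < 0 and res.p_value < 0.05

    def test_null_gives_small_correlation(self):
        rs = []
        for seed in range(10):
            cfg = SimulationConfig(seed=100 + seed, beta=0.0)
            cohort, truth = simulate_cohort(cfg)
            rs.append(gels_mutation_correlation(cohort, truth["gels"], stratum="b2m_wt").r)
        assert abs(np.mean(rs)) < 0.15

    def test_constant_gels_error(self):
        cfg = SimulationConfig(seed=5, beta=0.0)
        cohort, truth = simulate_cohort(cfg)
        flat = {l: 0.5 for l in truth["gels"]}
        with pytest.raises(ValueError, match="constant"):
            gels_mutation_correlation(cohort, flat, stratum="b2m_wt")

    def test_empty_stratum_error(self):
        cfg = SimulationConfig(seed=6, b2m_mutant_fraction=0.0)
        cohort, truth = simulate_cohort(cfg)
        with pytest.raises(ValueError, match="no tumors"):
            gels_mutation_correlation(cohort, truth["gels"], stratum="b2m_mut")


class TestRelativeMutationFrequency:
    LOCI = {
        "L1": CmsLocus("L1", "G1", "A", 10, 120),
        "L2": CmsLocus("L2", "G2", "A", 10, 120),
        "L3": CmsLocus("L3", "G3", "A", 14, 120),
    }

    def test_centering_within_length_bin(self):
        adj = relative_mutation_frequency({"L1": 0.5, "L2": 0.7, "L3": 0.3}, self.LOCI)
        assert adj["L1"] == pytest.approx(-0.1)
        assert adj["L2"] == pytest.approx(+0.1)

    def test_single_cms_bin_is_zero(self):
        adj = relative_mutation_frequency({"L1": 0.5, "L2": 0.7, "L3": 0.3}, self.LOCI)
        assert adj["L3"] == pytest.approx(0.0)

    def test_mean_zero_per_bin(self):
        rng = np.random.default_rng(0)
        loci = {
            f"L{i}": CmsLocus(f"L{i}", f"G{i}", "A", int(rng.integers(8, 15)), 120)
            for i in range(30)
        }
        freqs = {k: float(rng.uniform()) for k in loci}
        adj = relative_mutation_frequency(freqs, loci)
        lengths = pd.Series({k: loci[k].repeat_length for k in loci})
        for _, grp in adj.groupby(lengths):
            assert grp.mean() == pytest.approx(0.0, abs=1e-12)


class TestHlaRestrictedCorrelation:
    def test_binding_score_monotone_in_count(self):
        s = lambda k, p=0.5: 1 - (1 - p) ** k
        assert s(0) == 0.0
        assert s(1) < s(2) < s(5)

    def test_allele_restricted_editing_only_in_positive_group(self):
        cfg = SimulationConfig(seed=7, allele_restricted=True, b2m_mutant_fraction=0.0, n_tumors=160)
        rng = np.random.default_rng(7)
        loci = simulate_loci(cfg, rng)
        gels = dict(zip([l.locus_id for l in loci], simulate_gels(len(loci), rng)))
        beta = calibrate_beta(loci, gels, cfg, target_r=-0.5)
        cfg = SimulationConfig(
            seed=7, allele_restricted=True, b2m_mutant_fraction=0.0, n_tumors=160, beta=beta
        )
        cohort, _ = simulate_cohort(cfg, gels=gels, loci=loci)
        # epitope counts whose binding score reproduces the planted GELS ordering
        counts = {l: int(round(10 * gels[l])) for l in gels}
        res = hla_restricted_correlation(cohort, counts, p_binding=0.5)
        assert res["positive"].r < 0 and res["positive"].p_value < 0.05
        assert res["negative"].p_value > 0.05 or res["negative"].r > res["positive"].r

    def test_small_group_error(self):
        cfg = SimulationConfig(seed=8, hla_positive_fraction=0.0)
        cohort, truth = simulate_cohort(cfg)
        counts = {l: 1 for l in truth["gels"]}
        with pytest.raises(ValueError, match="fewer than"):
            hla_restricted_correlation(cohort, counts)

    def test_pair_unit_mode_runs(self):
        cfg = SimulationConfig(seed=9)
        cohort, truth = simulate_cohort(cfg)
        counts = {l: int(round(5 * truth["gels"][l])) for l in truth["gels"]}
        res = hla_restricted_correlation(cohort, counts, unit="pair")
        assert res["positive"].n > len(cohort.loci)  # pair-level n >> candidate-level n


class TestFeatureMatrix:
    def test_no_missing_equals_raw_values(self):
        cfg = SimulationConfig(seed=10, missing_rate=0.0, n_tumors=12, n_loci=6)
        cohort, _ = simulate_cohort(cfg)
        fm = build_feature_matrix(cohort, group_by="cms")
        assert not fm.mask.any()
        key = (cohort.samples[0], cohort.loci[0])
        fs = cohort.frames[key]
        np.testing.assert_allclose(fm.values[0, :3], [fs.m2_fraction, fs.m1_fraction, fs.m0_fraction])

    def test_missing_cell_imputed_with_column_mean(self):
        cfg = SimulationConfig(seed=11, missing_rate=0.15, n_tumors=15, n_loci=6)
        cohort, _ = simulate_cohort(cfg)
        fm = build_feature_matrix(cohort, group_by="cms")
        assert fm.mask.any()
        i, j = np.argwhere(fm.mask)[0]
        observed = fm.values[~fm.mask[:, j], j]
        assert fm.values[i, j] == pytest.approx(observed.mean())

    def test_tumor_grouping_transposes(self):
        cfg = SimulationConfig(seed=12, missing_rate=0.0, n_tumors=10, n_loci=5)
        cohort, _ = simulate_cohort(cfg)
        by_cms = build_feature_matrix(cohort, group_by="cms")
        by_tumor = build_feature_matrix(cohort, group_by="tumor")
        assert by_cms.values.shape == (5, 30)
        assert by_tumor.values.shape == (10, 15)


def blobs(seed=0):
    rng = np.random.default_rng(seed)
    centers = np.array([[0.0, 0.0, 1.0], [0.8, 0.1, 0.1], [0.1, 0.8, 0.1]])
    rows, labels = [], []
    for k, c in enumerate(centers):
        for _ in range(8):
            rows.append(np.clip(c + rng.normal(0, 0.02, 3), 0, 1))
            labels.append(k)
    X = np.array(rows)
    fm = CmsFeatureMatrix(
        values=X, mask=np.zeros_like(X, bool),
        row_labels=[f"R{i}" for i in range(len(X))], col_labels=["M2", "M1", "wt"],
    )
    return fm, np.array(labels)


class TestClustering:
    def test_three_blobs_recovered_exactly(self):
        fm, truth = blobs()
        _, labels = cluster_cms(fm, n_clusters=3)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_identical_rows_merge_at_height_zero(self):
        X = np.tile([0.2, 0.3, 0.5], (4, 1))
        fm = CmsFeatureMatrix(X, np.zeros_like(X, bool), list("abcd"), ["M2", "M1", "wt"])
        linkage, _ = cluster_cms(fm, n_clusters=2)
        assert linkage[:, 2].max() == pytest.approx(0.0)

    def test_row_permutation_invariance(self):
        fm, truth = blobs()
        perm = np.random.default_rng(3).permutation(fm.n_rows)
        fm2 = CmsFeatureMatrix(fm.values[perm], fm.mask[perm],
                               [fm.row_labels[i] for i in perm], fm.col_labels)
        _, l1 = cluster_cms(fm, 3)
        _, l2 = cluster_cms(fm2, 3)
        assert adjusted_rand_score(l1[perm], l2) == 1.0

    def test_ward_heights_nondecreasing(self):
        fm, _ = blobs(5)
        linkage, _ = cluster_cms(fm, 3)
        assert np.all(np.diff(linkage[:, 2]) >= -1e-12)

    def test_threshold_cut_mode(self):
        fm, _ = blobs()
        linkage, labels = cluster_cms(fm, dissimilarity_threshold=1e9)
        assert len(set(labels)) == 1  # no clustering at a huge threshold

    def test_too_few_rows_error(self):
        X = np.zeros((2, 3))
        fm = CmsFeatureMatrix(X, np.zeros_like(X, bool), ["a", "b"], ["M2", "M1", "wt"])
        with pytest.raises(ValueError, match="clusters"):
            cluster_cms(fm, n_clusters=3)


class TestKernelPca:
    def test_identical_rows_zero_embedding(self):
        X = np.tile([0.2, 0.3, 0.5], (5, 1))
        fm = CmsFeatureMatrix(X, np.zeros_like(X, bool), list("abcde"), ["M2", "M1", "wt"])
        with pytest.warns(UserWarning, match="identical"):
            emb = kernel_pca_embed(fm)
        assert np.all(emb == 0.0)

    def test_duplicated_rows_get_identical_coordinates(self):
        fm, _ = blobs()
        X2 = np.vstack([fm.values, fm.values[:1]])
        fm2 = CmsFeatureMatrix(X2, np.zeros_like(X2, bool),
                               fm.row_labels + ["dup"], fm.col_labels)
        emb = kernel_pca_embed(fm2)
        np.testing.assert_allclose(emb[-1], emb[0], atol=1e-9)

    def test_separated_clusters_stay_separated(self):
        fm, truth = blobs()
        emb = kernel_pca_embed(fm)
        assert silhouette_score(emb, truth) > 0.5

    def test_sign_convention_deterministic(self):
        fm, _ = blobs()
        e1 = kernel_pca_embed(fm)
        e2 = kernel_pca_embed(fm)
        np.testing.assert_array_equal(e1, e2)
        for k in range(e1.shape[1]):
            assert e1[np.argmax(np.abs(e1[:, k])), k] > 0
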