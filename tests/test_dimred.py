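import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA as SkPCA

from olivescan.dimred import (
    CardinalitySparsePCA,
    FeatureStandardizer,
    GAConfig,
    ReductionResult,
    VarianceCutoffPCA,
    fit_pca,
    fit_spca,
    ga_fitness,
    ga_select_nnzl,
    select_variables,
)
from olivescan.reference import published_loadings

from conftest import standardize


def match_up_to_sign(A, B, atol):
    sign = np.sign((A * B).sum(axis=0))
    sign[sign == 0] = 1.0
    np.testing.assert_allclose(A, B * sign, atol=atol)


class TestStandardizer:
    def test_training_data_becomes_zero_mean_unit_sd(self, rng):
        X = pd.DataFrame(rng.normal(2.0, 5.0, size=(40, 6)))
        z = FeatureStandardizer().fit(X).transform(X)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_constant_column_dropped_with_warning(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20), "b": np.full(20, 7.0)})
        with pytest.warns(UserWarning, match="constant"):
            std = FeatureStandardizer().fit(X)
        assert std.constant_columns_ == ["b"]
        assert list(std.transform(X).columns) == ["a"]

    def test_test_split_keeps_training_statistics(self, rng):
        train = pd.DataFrame(rng.normal(size=(30, 3)))
        test = pd.DataFrame(rng.normal(10.0, 1.0, size=(10, 3)))
        std = FeatureStandardizer().fit(train)
        z = std.transform(test)
        manual = (test - train.mean()) / train.std(ddof=1)
        np.testing.assert_allclose(z.to_numpy(), manual.to_numpy())


class TestPCA:
    def test_single_direction_data(self, rng):
        direction = rng.normal(size=4)
        X = np.outer(rng.normal(size=12), direction)
        res = fit_pca(X, variance_cutoff=0.85)
        assert res.k_retained == 1
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_cutoff_selects_smallest_sufficient_k(self, rng):
        # construct data whose variance fractions are exactly (.60,.26,.10,.04)
        fracs = np.array([0.60, 0.26, 0.10, 0.04])
        q, _ = np.linalg.qr(rng.normal(size=(8, 4)))
        X = q * np.sqrt(fracs * 7)
        res = fit_pca(X, variance_cutoff=0.85)
        np.testing.assert_allclose(res.explained_variance_fraction, fracs[:2], atol=1e-12)
        assert res.k_retained == 2

    def test_matches_independent_eigendecomposition(self, rng):
        X = standardize(rng.normal(size=(6, 4)))
        mine = fit_pca(X, variance_cutoff=1.0)
        oracle = SkPCA().fit(X)
        np.testing.assert_allclose(
            mine.explained_variance_fraction,
            oracle.explained_variance_ratio_[: mine.k_retained],
            atol=1e-8,
        )
        match_up_to_sign(
            mine.loadings.to_numpy(), oracle.components_.T[:, : mine.k_retained], 1e-8
        )

    def test_total_variance_sums_to_one(self, rng):
        X = standardize(rng.normal(size=(15, 5)))
        res = fit_pca(X, variance_cutoff=1.0)
        assert res.explained_variance_fraction.sum() == pytest.approx(1.0, abs=1e-8)

    def test_nan_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            fit_pca(X)

    def test_projection_uses_training_loadings_only(self, rng):
        train = standardize(rng.normal(size=(20, 4)))
        est = VarianceCutoffPCA().fit(train)
        loadings_before = est.loadings_.copy()
        est.transform(rng.normal(size=(5, 4)))
        np.testing.assert_array_equal(est.loadings_, loadings_before)


class TestSparsePCA:
    def test_full_cardinality_vanishing_ridge_reduces_to_pca(self, rng):
        X = standardize(rng.normal(size=(20, 5)))
        pca = fit_pca(X, variance_cutoff=1.0)
        spca = fit_spca(X, nnzl=[5, 5, 5, 5, 5], ridge_penalty=1e-12)
        match_up_to_sign(spca.loadings.to_numpy(), pca.loadings.to_numpy(), 1e-6)

    def test_cardinality_constraints_always_satisfied(self, rng):
        X = standardize(rng.normal(size=(30, 8)))
        for nnzl in ([1, 1], [3, 5], [8, 2, 4]):
            res = fit_spca(X, nnzl=nnzl)
            counts = (res.loadings.to_numpy() != 0).sum(axis=0)
            assert (counts <= np.asarray(nnzl)).all()
            norms = np.linalg.norm(res.loadings.to_numpy(), axis=0)
            np.testing.assert_allclose(norms, 1.0, atol=1e-12)

    def test_dominant_variable_recovered_by_brute_force(self, rng):
        X = rng.normal(size=(50, 5))
        X[:, 2] *= 10.0
        res = fit_spca(X, nnzl=[1])
        # brute-force oracle: the single variable maximizing explained variance
        best = max(range(5), key=lambda j: np.var(X[:, j]))
        expected = np.zeros(5)
        expected[best] = 1.0
        np.testing.assert_allclose(np.abs(res.loadings.to_numpy().ravel()), expected)

    def test_apev_bounded_by_pca_variance(self, rng):
        X = standardize(rng.normal(size=(25, 6)))
        cpv = fit_pca(X, variance_cutoff=1.0).explained_variance_fraction[:2].sum()
        for nnzl in ([2, 2], [4, 3], [6, 6]):
            apev = fit_spca(X, nnzl=nnzl).explained_variance_fraction.sum()
            assert apev <= cpv + 1e-8

    def test_bad_nnzl_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="nnzl"):
            fit_spca(X, nnzl=[0, 2])
        with pytest.raises(ValueError, match="nnzl"):
            fit_spca(X, nnzl=[5, 2])


class TestSelectVariables:
    def test_published_loading_table_keeps_28_indexes(self):
        table = published_loadings()
        result = ReductionResult(
            loadings=table[["SPC1", "SPC2"]],
            scores=np.zeros((1, 2)),
            explained_variance_fraction=np.zeros(2),
            k_retained=2,
        )
        retained = select_variables(result)
        assert len(retained) == 28
        discarded = set(table.index) - set(retained)
        assert discarded == {"NR", "NG", "NB", "SCI", "NGRDI", "VARI", "RI"}

    def test_all_zero_and_all_nonzero_loadings(self):
        zero = ReductionResult(
            loadings=pd.DataFrame(np.zeros((35, 2))),
            scores=np.zeros((1, 2)),
            explained_variance_fraction=np.zeros(2),
            k_retained=2,
        )
        assert select_variables(zero) == ()
        dense = ReductionResult(
            loadings=pd.DataFrame(np.ones((35, 2))),
            scores=np.zeros((1, 2)),
            explained_variance_fraction=np.zeros(2),
            k_retained=2,
        )
        assert len(select_variables(dense)) == 35


class TestGA:
    def test_zero_sparsity_weight_prefers_full_cardinality(self, rng):
        X = standardize(rng.normal(size=(25, 4)))
        cfg = GAConfig(sparsity_weight=0.0, seed=5)
        best = ga_select_nnzl(X, k=2, config=cfg)
        np.testing.assert_array_equal(best, [4, 4])

    def test_matches_exhaustive_enumeration_at_small_p(self, rng):
        X = standardize(rng.normal(size=(20, 3)))
        pca = fit_pca(X)
        k = pca.k_retained
        cpv = float(pca.explained_variance_fraction.sum())
        grid = list(itertools.product(range(1, 4), repeat=k))
        w = 0.5
        brute = max(grid, key=lambda c: ga_fitness(X, c, cpv, w))
        got = ga_select_nnzl(X, k, GAConfig(sparsity_weight=w, seed=0))
        assert ga_fitness(X, got, cpv, w) == pytest.approx(
            ga_fitness(X, brute, cpv, w), abs=1e-12
        )

    def test_deterministic_under_seed(self, rng):
        X = standardize(rng.normal(size=(20, 5)))
        a = ga_select_nnzl(X, 2, GAConfig(seed=9, n_generations=10))
        b = ga_select_nnzl(X, 2, GAConfig(seed=9, n_generations=10))
        np.testing.assert_array_equal(a, b)

    def test_returned_fitness_dominates_initial_population(self, rng):
        X = standardize(rng.normal(size=(20, 5)))
        cfg = GAConfig(seed=3, n_generations=8)
        pca = fit_pca(X, variance_cutoff=1.1)
        cpv = float(np.sort(pca.explained_variance_fraction)[::-1][:2].sum())
        best = ga_select_nnzl(X, 2, cfg)
        init = np.random.default_rng(cfg.seed).integers(1, 6, size=(cfg.population_size, 2))
        best_fit = ga_fitness(X, best, cpv, cfg.sparsity_weight)
        for chrom in init:
            assert best_fit >= ga_fitness(X, chrom, cpv, cfg.sparsity_weight) - 1e-12

    def test_k_larger_than_p_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            ga_select_nnzl(rng.normal(size=(10, 3)), 4, GAConfig(seed=0))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=1)
        with pytest.raises(ValueError):
            GAConfig(mutation_prob=1.5)
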