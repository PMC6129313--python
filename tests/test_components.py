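"""Effect-size laws, covariates and the five component constructions."""

import numpy as np
import pytest
from scipy import stats

from phenosim.components import (
    build_trait_covariance,
    correlated_noise_component,
    covariate_component,
    genetic_variant_component,
    infinitesimal_component,
    kinship_factor,
    make_independent_effect_sizes,
    make_shared_effect_sizes,
    matrix_normal_sample,
    observational_noise_component,
    simulate_covariates,
    validate_trait_covariance,
)
from phenosim.genotypes import GenotypeData, Kinship, simulate_genotypes


def _pairwise_abs_corr(values: np.ndarray) -> np.ndarray:
    c = np.corrcoef(values, rowvar=False)
    return np.abs(c[np.triu_indices_from(c, k=1)])


def _identity_kinship(n: int) -> Kinship:
    return Kinship(matrix=np.eye(n), sample_ids=[f"i{k}" for k in range(n)])


class TestSharedEffectSizes:
    @pytest.mark.parametrize(
        "law,params", [("normal", (0.0, 1.0)), ("uniform", (0.1, 0.5))]
    )
    def test_columns_perfectly_correlated(self, law, params):
        eff = make_shared_effect_sizes(3, 4, law, params, seed=0)
        corr = np.corrcoef(eff.values, rowvar=False)
        assert np.allclose(np.abs(corr), 1.0)

    def test_normal_law_is_rank_one(self):
        eff = make_shared_effect_sizes(5, 4, "normal", (0.0, 1.0), seed=1)
        assert np.linalg.matrix_rank(eff.values) <= 1

    def test_single_trait_reduces_to_column_vector(self):
        eff = make_shared_effect_sizes(3, 1, "normal", (0.0, 1.0), seed=2)
        assert eff.values.shape == (3, 1)

    def test_uniform_entries_follow_uniform_law(self):
        """KS check: repeated single-entry draws against Uniform(0.1, 0.5)."""
        rng = np.random.default_rng(3)
        draws = np.array([
            make_shared_effect_sizes(1, 1, "uniform", (0.1, 0.5), seed=rng)
            .values[0, 0]
            for _ in range(10_000)
        ])
        ks = stats.kstest(draws, "uniform", args=(0.1, 0.4))
        # 1% critical value of the two-sided KS statistic at n = 10 000
        assert ks.statistic < 1.63 / np.sqrt(10_000)
        assert draws.min() >= 0.1 and draws.max() <= 0.5

    def test_invalid_law_parameters_rejected(self):
        with pytest.raises(ValueError, match="sd > 0"):
            make_shared_effect_sizes(2, 2, "normal", (0.0, 0.0), seed=0)
        with pytest.raises(ValueError, match="low < high"):
            make_shared_effect_sizes(2, 2, "uniform", (0.5, 0.1), seed=0)
        with pytest.raises(ValueError, match="unknown effect-size law"):
            make_shared_effect_sizes(2, 2, "lognormal", (0, 1), seed=0)


class TestIndependentEffectSizes:
    def test_all_traits_affected_leaves_no_zero_column(self):
        eff = make_independent_effect_sizes(4, 5, 5, seed=0)
        assert not np.any(np.all(eff.values == 0, axis=0))

    def test_unaffected_traits_are_zeroed(self):
        eff = make_independent_effect_sizes(4, 5, 2, seed=1)
        zero_cols = np.all(eff.values == 0, axis=0)
        assert zero_cols.sum() == 3
        assert sorted(np.where(~zero_cols)[0]) == sorted(eff.affected_traits)

    def test_trait_selection_deterministic_under_seed(self):
        a = make_independent_effect_sizes(4, 6, 3, seed=42)
        b = make_independent_effect_sizes(4, 6, 3, seed=42)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.affected_traits, b.affected_traits)

    def test_p_ind_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="P_ind"):
            make_independent_effect_sizes(3, 4, 0, seed=0)
        with pytest.raises(ValueError, match="P_ind"):
            make_independent_effect_sizes(3, 4, 5, seed=0)

    def test_per_row_masking_keeps_row_support(self):
        eff = make_independent_effect_sizes(50, 5, 2, seed=3, per_row=True)
        assert np.all((eff.values != 0).sum(axis=1) <= 2)


class TestGeneticVariantComponent:
    def test_zero_effects_give_zero_component(self, small_panel):
        shared, ind = small_panel.subset_snps([0, 1]), small_panel.subset_snps([2])
        B_s = make_shared_effect_sizes(2, 3, seed=0)
        B_s.values[:] = 0.0
        B_i = make_independent_effect_sizes(1, 3, 1, seed=0)
        comp_s, _ = genetic_variant_component(shared, ind, B_s, B_i)
        assert np.array_equal(comp_s.values, np.zeros((5, 3)))

    def test_hand_multiplied_two_trait_effect(self, small_panel):
        # one SNP, b_s = (2), b_p = (1, -1): trait 2 is the negative of trait 1
        shared = small_panel.subset_snps([0])
        ind = small_panel.subset_snps([])
        B_s = make_shared_effect_sizes(1, 2, seed=0)
        B_s.values = np.array([[2.0, -2.0]])
        B_i = make_independent_effect_sizes(0, 2, 2, seed=0)
        comp_s, comp_i = genetic_variant_component(shared, ind, B_s, B_i)
        x = small_panel.dosages[:, 0]
        assert np.array_equal(comp_s.values[:, 0], 2.0 * x)
        assert np.array_equal(comp_s.values[:, 1], -comp_s.values[:, 0])
        assert np.array_equal(comp_i.values, np.zeros((5, 2)))

    def test_independent_support_restricted_to_affected_traits(self):
        g = simulate_genotypes(50, 10, seed=0)
        shared, ind = g.subset_snps([]), g.subset_snps(list(range(10)))
        B_s = make_shared_effect_sizes(0, 3, seed=0)
        B_i = make_independent_effect_sizes(10, 3, 1, seed=1)
        _, comp_i = genetic_variant_component(shared, ind, B_s, B_i)
        nonzero_cols = ~np.all(comp_i.values == 0, axis=0)
        assert nonzero_cols.sum() == 1

    def test_dimension_mismatch_rejected(self, small_panel):
        B_s = make_shared_effect_sizes(2, 3, seed=0)  # 2 rows vs 3 SNPs
        B_i = make_independent_effect_sizes(0, 3, 3, seed=0)
        with pytest.raises(ValueError, match="shared"):
            genetic_variant_component(
                small_panel, small_panel.subset_snps([]), B_s, B_i
            )


class TestCovariates:
    def test_degenerate_bernoulli_is_all_ones(self):
        cs = simulate_covariates(50, [{"dist": "binomial", "p": 1.0}], 1.0, seed=0)
        assert np.array_equal(cs.values[:, 0], np.ones(50))

    def test_normal_covariate_mean_recovered(self):
        cs = simulate_covariates(
            10_000, [{"dist": "normal", "mean": 50.0, "sd": 5.0}], 1.0, seed=1
        )
        assert abs(cs.values.mean() - 50.0) < 3 * 5.0 / 100.0

    def test_categorical_level_frequencies_recovered(self):
        probs = np.array([0.2, 0.3, 0.5])
        cs = simulate_covariates(
            10_000, [{"dist": "categorical", "probs": probs.tolist()}], 1.0, seed=2
        )
        counts = np.bincount(cs.values[:, 0].astype(int), minlength=3) / 10_000
        se = np.sqrt(probs * (1 - probs) / 10_000)
        assert np.all(np.abs(counts - probs) < 3 * se)

    def test_uniform_covariate_moments(self):
        cs = simulate_covariates(
            10_000, [{"dist": "uniform", "low": 20.0, "high": 60.0}], 1.0, seed=3
        )
        x = cs.values[:, 0]
        assert abs(x.mean() - 40.0) < 4 * np.sqrt(40.0**2 / 12 / 10_000)
        assert x.min() >= 20.0 and x.max() <= 60.0

    def test_gamma_partition_sizes(self):
        specs = [{"dist": "normal", "mean": 0, "sd": 1}] * 5
        cs = simulate_covariates(10, specs, 0.5, seed=0)
        assert len(cs.shared_cols) == 3  # round-half-away(0.5 * 5)
        assert len(cs.independent_cols) == 2
        assert set(cs.shared_cols).isdisjoint(cs.independent_cols)

    def test_malformed_specs_rejected(self):
        with pytest.raises(ValueError, match="unknown covariate"):
            simulate_covariates(5, [{"dist": "poisson"}], 1.0, seed=0)
        with pytest.raises(ValueError, match="sum to"):
            simulate_covariates(
                5, [{"dist": "categorical", "probs": [0.5, 0.4]}], 1.0, seed=0
            )
        with pytest.raises(ValueError, match="gamma"):
            simulate_covariates(5, [], 1.5, seed=0)

    def test_all_shared_gives_zero_independent_component(self):
        cs = simulate_covariates(
            20, [{"dist": "normal", "mean": 0, "sd": 1}] * 2, 1.0, seed=4
        )
        A_s = make_shared_effect_sizes(2, 3, seed=0)
        A_i = make_independent_effect_sizes(0, 3, 3, seed=0)
        comp_s, comp_i = covariate_component(cs, A_s, A_i)
        assert np.array_equal(comp_i.values, np.zeros((20, 3)))
        assert comp_s.values.shape == (20, 3)

    def test_rank_one_effects_propagate_to_component(self):
        cs = simulate_covariates(
            100, [{"dist": "normal", "mean": 0, "sd": 1}], 1.0, seed=5
        )
        A_s = make_shared_effect_sizes(1, 2, seed=1)
        A_i = make_independent_effect_sizes(0, 2, 2, seed=0)
        comp_s, _ = covariate_component(cs, A_s, A_i)
        assert np.allclose(_pairwise_abs_corr(comp_s.values), 1.0)


class TestKinshipFactor:
    def test_identity_kinship_reconstructs(self):
        B = kinship_factor(_identity_kinship(4))
        assert np.allclose(B @ B.T, np.eye(4), atol=1e-10)

    def test_rank_one_kinship_gives_single_column_factor(self):
        k = Kinship(matrix=np.ones((2, 2)) / 2, sample_ids=["a", "b"])
        B = kinship_factor(k)
        assert B.shape == (2, 1)
        assert np.allclose(B @ B.T, np.ones((2, 2)) / 2, atol=1e-12)

    def test_random_psd_reconstruction(self, rng):
        X = rng.normal(size=(50, 30))
        K = X @ X.T
        K /= np.mean(np.diag(K))
        k = Kinship(matrix=(K + K.T) / 2, sample_ids=[f"i{j}" for j in range(50)])
        B = kinship_factor(k)
        rel = np.linalg.norm(B @ B.T - k.matrix) / np.linalg.norm(k.matrix)
        assert rel < 1e-8

    def test_negative_eigenvalue_reported(self):
        m = np.diag([1.0, 1.5, -0.5])
        k = Kinship(matrix=m, sample_ids=list("abc"))
        with pytest.raises(ValueError, match="eigenvalue"):
            kinship_factor(k)


class TestInfinitesimal:
    def test_shared_design_forces_perfect_trait_correlation(self):
        B = kinship_factor(_identity_kinship(500))
        comp = infinitesimal_component(B, 3, "shared", seed=0)
        assert np.all(_pairwise_abs_corr(comp.values) >= 0.999)

    def test_independent_design_traits_uncorrelated(self):
        n = 10_000
        B = kinship_factor(_identity_kinship(n))
        comp = infinitesimal_component(B, 2, "independent", seed=1)
        assert np.all(_pairwise_abs_corr(comp.values) < 4 / np.sqrt(n))

    def test_unknown_design_rejected(self):
        B = kinship_factor(_identity_kinship(5))
        with pytest.raises(ValueError, match="design"):
            infinitesimal_component(B, 2, "mixed", seed=0)

    def test_vec_covariance_matches_kronecker_product(self):
        """Monte-Carlo oracle: cov(vec(B Z A^T)) == (A A^T) (x) (B B^T)."""
        K = np.array([[1.0, 0.5, 0.4], [0.5, 1.0, 0.6], [0.4, 0.6, 1.0]])
        kin = Kinship(matrix=K, sample_ids=list("abc"))
        B = kinship_factor(kin)
        A = np.array([[1.0, 0.0], [0.8, 0.6]])  # C = A A^T, unit diagonal
        C = A @ A.T
        reps = 150_000
        U = matrix_normal_sample(B, A, seed=7, size=reps)
        vecs = U.transpose(0, 2, 1).reshape(reps, -1)  # column-stacked vec
        emp = np.cov(vecs, rowvar=False)
        expected = np.kron(C, K)
        mask = np.abs(expected) > 0.05
        rel = np.abs(emp[mask] - expected[mask]) / np.abs(expected[mask])
        assert rel.max() < 0.05


class TestTraitCovariance:
    def test_exponential_decay_entries_exact(self):
        cov = build_trait_covariance(3, 0.5)
        expected = np.array([[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]])
        assert np.array_equal(cov.matrix, expected)

    def test_zero_r_gives_identity(self):
        assert np.array_equal(build_trait_covariance(4, 0.0).matrix, np.eye(4))

    def test_log_off_diagonals_decay_linearly(self):
        P, r = 7, 0.6
        cov = build_trait_covariance(P, r)
        for d in range(1, P):
            diag = np.diagonal(cov.matrix, offset=d)
            assert np.allclose(np.log(diag), d * np.log(r))

    @pytest.mark.parametrize("P,r", [(6, 0.8), (20, 0.95), (5, -0.7)])
    def test_positive_definite_for_abs_r_below_one(self, P, r):
        cov = build_trait_covariance(P, r)
        assert np.linalg.eigvalsh(cov.matrix).min() > 0

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.2])
    def test_unit_or_larger_r_rejected(self, r):
        with pytest.raises(ValueError, match="r"):
            build_trait_covariance(4, r)

    def test_user_supplied_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            validate_trait_covariance(np.array([[1.0, 0.5], [0.1, 1.0]]))
        with pytest.raises(ValueError, match="PSD"):
            validate_trait_covariance(np.array([[1.0, 2.0], [2.0, 1.0]]))
        ok = validate_trait_covariance(np.eye(3))
        assert ok.origin == "user_supplied"


class TestCorrelatedNoise:
    def test_identity_covariance_gives_uncorrelated_traits(self):
        n = 10_000
        comp = correlated_noise_component(
            n, validate_trait_covariance(np.eye(3)), seed=0
        )
        assert np.all(_pairwise_abs_corr(comp.values) < 4 / np.sqrt(n))

    def test_exponential_decay_correlation_recovered(self):
        n = 50_000
        comp = correlated_noise_component(n, build_trait_covariance(4, 0.7), seed=1)
        corr = np.corrcoef(comp.values, rowvar=False)
        d1 = np.diagonal(corr, offset=1)
        assert np.all(np.abs(d1 - 0.7) < 0.02)

    def test_univariate_variance_matches(self):
        n = 10_000
        cov = validate_trait_covariance(np.array([[2.0]]))
        comp = correlated_noise_component(n, cov, seed=2)
        se = np.sqrt(2 * 2.0**2 / (n - 1))  # SE of the sample variance
        assert abs(comp.values.var(ddof=1) - 2.0) < 3 * se


class TestObservationalNoise:
    def test_shared_design_perfect_correlation(self):
        comp = observational_noise_component(500, 3, "shared", seed=0)
        assert np.all(_pairwise_abs_corr(comp.values) >= 0.999)

    def test_independent_design_uncorrelated(self):
        n = 10_000
        comp = observational_noise_component(n, 3, "independent", seed=1)
        assert np.all(_pairwise_abs_corr(comp.values) < 4 / np.sqrt(n))

    @pytest.mark.parametrize("design", ["shared", "independent"])
    def test_single_trait_reduces_to_scaled_normal_column(self, design):
        n = 20_000
        comp = observational_noise_component(n, 1, design, seed=2)
        a = comp.extras["trait_loadings"][0, 0]
        z = comp.values[:, 0] / a
        assert abs(z.mean()) < 4 / np.sqrt(n)
        assert abs(z.var(ddof=1) - 1.0) < 4 * np.sqrt(2.0 / n)

    def test_determinism_under_fixed_seed(self):
        a = observational_noise_component(100, 4, "shared", seed=9)
        b = observational_noise_component(100, 4, "shared", seed=9)
        assert np.array_equal(a.values, b.values)
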