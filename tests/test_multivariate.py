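"""Multivariate stages: Cholesky adjustment arithmetic and recovery,
equivalence of the path and direct-symmetric parametrisations, shared
factor nesting, and covariance-equality tests."""

import numpy as np
import pytest

from twinpaths.data import TwinDataset
from twinpaths.multivariate_twin import (
    CholeskyModel,
    adjusted_heritability,
    fit_cholesky,
    fit_distinct_factors,
    fit_shared_factor,
    test_covariance_equality as covariance_equality_lrt,
)
from twinpaths.multivariate_twin import (
    test_cross_path as cross_path_lrt,
    unique_genetic_fraction,
)
from twinpaths.sem_core import BiometricCov, CholeskyCov, MeanStructure, TwinModel, fit, lrt
from twinpaths.synthetic_data import (
    STUDY_CHOLESKY_PATHS,
    SimConfig,
    facet_study_config,
    simulate_twins,
    trivariate_study_config,
)

TRAITS3 = ["SMDT", "BASRR", "BMRQ"]
FACETS = ["f1", "f2", "f3", "f4", "f5"]


def _model_from_paths(paths: dict, k: int = 3) -> CholeskyModel:
    x = np.zeros((k, k))
    z = np.zeros((k, k))
    for (prefix, m) in (("lA", x), ("lE", z)):
        for i in range(k):
            for j in range(i + 1):
                m[i, j] = paths.get(f"{prefix}_{i + 1}_{j + 1}", 0.0)
    return CholeskyModel(TRAITS3[:k], x, z)


@pytest.fixture(scope="module")
def tri_dataset():
    """Standardized trivariate cohort at reduced group sizes."""
    return simulate_twins(
        trivariate_study_config(61, pair_counts={"MZ": (500, 0), "DZ": (600, 0)})
    )


@pytest.fixture(scope="module")
def tri_fit(tri_dataset):
    return fit_cholesky(tri_dataset, TRAITS3, compute_se=True)


class TestCholeskyArithmetic:
    def test_adjusted_heritability_from_calibrated_paths(self):
        model = _model_from_paths(STUDY_CHOLESKY_PATHS)
        assert adjusted_heritability(model) == pytest.approx(0.378, abs=0.001)
        assert round(adjusted_heritability(model), 2) == 0.38

    def test_unique_fraction_from_calibrated_paths(self):
        model = _model_from_paths(STUDY_CHOLESKY_PATHS)
        assert unique_genetic_fraction(model) == pytest.approx(0.70, abs=0.005)

    def test_no_cross_paths_reduces_to_univariate_h2(self):
        paths = {"lA_1_1": 0.7, "lA_2_2": 0.6, "lA_3_3": np.sqrt(0.54),
                 "lE_1_1": 0.7, "lE_2_2": 0.8, "lE_3_3": np.sqrt(0.46)}
        model = _model_from_paths(paths)
        assert adjusted_heritability(model) == pytest.approx(0.54)
        assert unique_genetic_fraction(model) == pytest.approx(1.0)

    def test_zero_unique_genetic_path(self):
        paths = dict(STUDY_CHOLESKY_PATHS)
        paths["lA_3_3"] = 0.0
        model = _model_from_paths(paths)
        assert unique_genetic_fraction(model) == 0.0

    def test_adjusted_equals_total_times_unique_fraction(self, tri_fit):
        """On standardized fits the adjustment identity holds exactly:
        adj-h2 = h2_total * unique-fraction (both from the same paths)."""
        _, model = tri_fit
        k = 3
        a_tot = float((model.x[k - 1] ** 2).sum())
        e_tot = float((model.z[k - 1] ** 2).sum())
        h2_total = a_tot / (a_tot + e_tot)
        lhs = adjusted_heritability(model)
        rhs = h2_total * unique_genetic_fraction(model)
        assert lhs == pytest.approx(rhs, abs=1e-6)


class TestCholeskyFit:
    def test_path_recovery_within_wald_intervals(self, tri_fit):
        f, model = tri_fit
        assert f.converged
        checked = 0
        for name, true in STUDY_CHOLESKY_PATHS.items():
            se = f.se.get(name, float("nan"))
            if not np.isfinite(se) or se == 0:
                continue
            est = abs(f.params[name]) if name in ("lA_1_1",) else f.params[name]
            assert est == pytest.approx(true, abs=3 * se + 0.02), name
            checked += 1
        assert checked >= 10

    def test_univariate_degenerate_case_matches_ae_fit(self, tri_dataset):
        f1, model1 = fit_cholesky(tri_dataset, ["BMRQ"], compute_se=False)
        ds = tri_dataset.zscored(["BMRQ"])
        # same mean structure as the path model (age covariate included)
        ae = TwinModel(["BMRQ"], BiometricCov(1, ("A", "E")), MeanStructure("single", age=True))
        f2 = fit(ae, ds, compute_se=False)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-4)
        assert model1.x[0, 0] ** 2 == pytest.approx(f2.params["A_1_1"], abs=1e-3)

    def test_cross_path_test_has_one_df_and_detects_real_path(self, tri_dataset, tri_fit):
        f, _ = tri_fit
        comp = cross_path_lrt(tri_dataset, f, "lA_3_1")
        assert comp.ddf == 1
        assert comp.pvalue < 0.007  # generative lambda_A31 = 0.255 is large

    def test_null_cross_path_not_rejected(self, tri_dataset, tri_fit):
        """The generative environmental path from trait 1 to trait 3 is
        zero, so its removal should not significantly worsen the fit."""
        f, _ = tri_fit
        comp = cross_path_lrt(tri_dataset, f, "lE_3_1")
        assert comp.pvalue > 0.007

    def test_diagonal_path_refused(self, tri_dataset, tri_fit):
        f, _ = tri_fit
        with pytest.raises(ValueError, match="off-diagonal"):
            cross_path_lrt(tri_dataset, f, "lA_2_2")


class TestParametrisationEquivalence:
    def test_cholesky_and_direct_symmetric_reach_equal_likelihood(self, tri_dataset):
        """Both parametrisations saturate the AE structure, so their
        maximized likelihoods must agree."""
        ds = tri_dataset.zscored(TRAITS3)
        chol = TwinModel(TRAITS3, CholeskyCov(3), MeanStructure("single"))
        sym = TwinModel(TRAITS3, BiometricCov(3, ("A", "E")), MeanStructure("single"))
        f_chol = fit(chol, ds, compute_se=False)
        f_sym = fit(sym, ds, compute_se=False)
        assert f_chol.k == f_sym.k
        assert abs(f_chol.loglik - f_sym.loglik) < 1e-4


@pytest.fixture(scope="module")
def facet_dataset():
    # full pooled study size: the shared-factor and covariance-equality
    # tests are calibrated against the study's own power
    return simulate_twins(
        facet_study_config(62, pair_counts={"MZ": (1059, 0), "DZ": (1246, 0)})
    )


@pytest.fixture(scope="module")
def facet_distinct(facet_dataset):
    return fit_distinct_factors(facet_dataset, FACETS, compute_se=True)


class TestDistinctFactors:
    def test_facet_heritabilities_in_published_band(self, facet_distinct):
        _, model, _ = facet_distinct
        h2 = model.heritabilities()
        assert np.all(h2 > 0.3) and np.all(h2 < 0.65)

    def test_genetic_correlations_recovered(self, facet_dataset, facet_distinct):
        """R_A from the fit approximates the generative genetic correlations
        implied by the published twin-correlation structure."""
        from twinpaths.synthetic_data import published_facet_covariance

        pop = published_facet_covariance()
        k = 5
        cross_mz = pop["MZ"][:k, k:]
        cross_dz = pop["DZ"][:k, k:]
        a_true = 2.0 * (cross_mz - cross_dz)
        a_true = (a_true + a_true.T) / 2
        d = np.sqrt(np.diag(a_true))
        r_true = a_true / np.outer(d, d)
        _, _, corr = facet_distinct
        mask = ~np.eye(k, dtype=bool)
        assert np.max(np.abs(corr.r_a[mask] - r_true[mask])) < 0.2
        assert np.mean(np.abs(corr.r_a[mask] - r_true[mask])) < 0.1

    def test_zero_cross_covariance_gives_identity_ra(self):
        cfg = SimConfig(
            seed=63,
            traits=["u", "v"],
            group_pair_counts={"MZ": (2000, 0), "DZ": (2000, 0)},
            generative=(
                BiometricCov(2, ("A", "E")),
                {"A_1_1": 0.5, "A_2_1": 0.0, "A_2_2": 0.5,
                 "E_1_1": 0.5, "E_2_1": 0.0, "E_2_2": 0.5},
            ),
        )
        ds = simulate_twins(cfg)
        _, _, corr = fit_distinct_factors(ds, ["u", "v"], compute_se=False)
        assert abs(corr.r_a[0, 1]) < 0.12

    def test_duplicate_traits_give_unit_correlations(self):
        ds = simulate_twins(
            facet_study_config(64, pair_counts={"MZ": (400, 0), "DZ": (400, 0)})
        )
        df = ds.df.copy()
        rng = np.random.default_rng(1)
        for s in ("1", "2"):
            df[f"g1_{s}"] = df[f"f1_{s}"]
            df[f"g2_{s}"] = df[f"f1_{s}"] + rng.normal(scale=0.2, size=len(df))
        _, _, corr = fit_distinct_factors(TwinDataset(df), ["g1", "g2"], compute_se=False)
        assert corr.r_a[0, 1] > 0.95
        assert corr.r_e[0, 1] > 0.9


class TestSharedFactor:
    def test_nested_in_distinct_solution(self, facet_dataset, facet_distinct):
        f_dist, _, _ = facet_distinct
        for comp in ("A", "E"):
            f_shared, _ = fit_shared_factor(facet_dataset, FACETS, component=comp)
            assert f_shared.loglik <= f_dist.loglik + 1e-6
            comparison = lrt(f_dist, f_shared)
            assert comparison.ddf == 5  # k(k-1)/2 - k for k = 5

    def test_true_one_factor_structure_not_rejected(self):
        lam = np.full(5, 0.6)
        a = np.outer(lam, lam) + np.diag(np.full(5, 0.14))
        e = np.diag(np.full(5, 0.5)) + 0.1 - np.diag(np.full(5, 0.1))
        sigma = {
            "MZ": np.block([[a + e, a], [a, a + e]]),
            "DZ": np.block([[a + e, 0.5 * a], [0.5 * a, a + e]]),
        }
        cfg = SimConfig(
            seed=65,
            traits=FACETS,
            group_pair_counts={"MZ": (700, 0), "DZ": (800, 0)},
            generative=sigma,
        )
        ds = simulate_twins(cfg)
        f_dist, _, _ = fit_distinct_factors(ds, FACETS, compute_se=False)
        f_shared, model = fit_shared_factor(ds, FACETS, component="A")
        comp = lrt(f_dist, f_shared)
        assert comp.pvalue > 0.007
        assert model.loadings[0] >= 0  # reflection resolved

    def test_published_structure_rejects_single_genetic_factor(self, facet_dataset, facet_distinct):
        f_dist, _, _ = facet_distinct
        f_shared, _ = fit_shared_factor(facet_dataset, FACETS, component="A")
        assert lrt(f_dist, f_shared).pvalue < 0.007

    def test_too_few_traits_rejected(self, facet_dataset):
        with pytest.raises(ValueError, match="k >= 3"):
            fit_shared_factor(facet_dataset, ["f1", "f2"], component="A")


class TestCovarianceEquality:
    def test_equal_generative_covariances_not_rejected(self):
        a = np.array([[0.5, 0.2, 0.2], [0.2, 0.5, 0.1], [0.2, 0.1, 0.5]])
        e = np.diag([0.5, 0.5, 0.5])
        sigma = {
            "MZ": np.block([[a + e, a], [a, a + e]]),
            "DZ": np.block([[a + e, 0.5 * a], [0.5 * a, a + e]]),
        }
        cfg = SimConfig(
            seed=66,
            traits=["t1", "t2", "t3"],
            group_pair_counts={"MZ": (700, 0), "DZ": (800, 0)},
            generative=sigma,
        )
        ds = simulate_twins(cfg)
        f, _, _ = fit_distinct_factors(ds, ["t1", "t2", "t3"], compute_se=False)
        comp = covariance_equality_lrt(ds, f, [("t1", "t2"), ("t1", "t3")], "A")
        assert comp.ddf == 1
        assert comp.pvalue > 0.007

    def test_unequal_covariances_rejected(self):
        """A generative genetic-correlation contrast of 0.3 at study-scale
        sample size is rejected by the equality constraint."""
        a = np.array([[0.5, 0.05, 0.2], [0.05, 0.5, 0.1], [0.2, 0.1, 0.5]])
        e = np.diag([0.5, 0.5, 0.5])
        sigma = {
            "MZ": np.block([[a + e, a], [a, a + e]]),
            "DZ": np.block([[a + e, 0.5 * a], [0.5 * a, a + e]]),
        }
        cfg = SimConfig(
            seed=67,
            traits=["t1", "t2", "t3"],
            group_pair_counts={"MZ": (1059, 0), "DZ": (1246, 0)},
            generative=sigma,
        )
        ds = simulate_twins(cfg)
        f, _, _ = fit_distinct_factors(ds, ["t1", "t2", "t3"], compute_se=False)
        comp = covariance_equality_lrt(ds, f, [("t1", "t2"), ("t1", "t3")], "A")
        assert comp.pvalue < 0.007

    def test_single_pair_rejected(self, facet_dataset, facet_distinct):
        f, _, _ = facet_distinct
        with pytest.raises(ValueError):
            covariance_equality_lrt(facet_dataset, f, [("f1", "f2")], "A")

    def test_self_pair_rejected(self, facet_dataset, facet_distinct):
        f, _, _ = facet_distinct
        with pytest.raises(ValueError):
            covariance_equality_lrt(facet_dataset, f, [("f1", "f1"), ("f1", "f2")], "A")
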