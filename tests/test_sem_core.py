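"""Engine-level checks: FIML likelihood against a dense oracle, parameter
maps, implied moments, model comparison and fit indices."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from twinpaths.data import TwinDataset
from twinpaths.sem_core import (
    BiometricCov,
    CholeskyCov,
    FitResult,
    IndependenceCov,
    MeanStructure,
    ModelComparison,
    ParameterMap,
    SaturatedCov,
    TwinModel,
    build_cache,
    fiml_loglik,
    fit,
    fit_indices,
    information_criteria,
    lrt,
)
from twinpaths.synthetic_data import simulate_twins

from conftest import ae_config


# ----------------------------------------------------------------------
# parameter map
# ----------------------------------------------------------------------
class TestParameterMap:
    def test_fix_and_tie_reduce_free_count(self):
        pm = ParameterMap(["a", "b", "c", "d"], fix={"a": 1.0}, tie=[("b", "c")])
        assert pm.n_free == 2
        full = pm.expand(np.array([5.0, 7.0]))
        assert full == {"a": 1.0, "b": 5.0, "c": 5.0, "d": 7.0}

    def test_tie_with_fixed_member_fixes_group(self):
        pm = ParameterMap(["a", "b"], fix={"a": 2.0}, tie=[("a", "b")])
        assert pm.n_free == 0
        assert pm.expand(np.array([])) == {"a": 2.0, "b": 2.0}

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError):
            ParameterMap(["a"], fix={"zz": 0.0})

    def test_reduce_averages_tied_entries(self):
        pm = ParameterMap(["a", "b"], tie=[("a", "b")])
        x = pm.reduce({"a": 1.0, "b": 3.0})
        assert x.tolist() == [2.0]

    def test_overlapping_ties_merge(self):
        pm = ParameterMap(["a", "b", "c"], tie=[("a", "b"), ("b", "c")])
        assert pm.n_free == 1


# ----------------------------------------------------------------------
# implied moments
# ----------------------------------------------------------------------
class TestImpliedMoments:
    def test_univariate_ae_mz(self):
        cov = BiometricCov(1, ("A", "E"))
        sigma = cov.sigma({"A_1_1": 0.54, "E_1_1": 0.46}, "MZ")
        assert np.allclose(sigma, [[1.0, 0.54], [0.54, 1.0]])

    def test_univariate_ae_dz(self):
        cov = BiometricCov(1, ("A", "E"))
        sigma = cov.sigma({"A_1_1": 0.54, "E_1_1": 0.46}, "DZ")
        assert sigma[0, 1] == pytest.approx(0.27)

    def test_ade_dz_kinship_weighting(self):
        cov = BiometricCov(1, ("A", "D", "E"))
        sigma = cov.sigma({"A_1_1": 0.4, "D_1_1": 0.2, "E_1_1": 0.4}, "DZ")
        assert sigma[0, 1] == pytest.approx(0.5 * 0.4 + 0.25 * 0.2)

    def test_cholesky_equals_direct_symmetric_structure(self):
        k = 3
        rng = np.random.default_rng(0)
        x = np.tril(rng.normal(size=(k, k)))
        z = np.tril(rng.normal(size=(k, k)))
        params = {}
        for prefix, m in (("lA", x), ("lE", z)):
            for i in range(k):
                for j in range(i + 1):
                    params[f"{prefix}_{i + 1}_{j + 1}"] = m[i, j]
        chol = CholeskyCov(k).sigma(params, "DZ")
        a, e = x @ x.T, z @ z.T
        expected = np.block([[a + e, 0.5 * a], [0.5 * a, a + e]])
        assert np.allclose(chol, expected)

    def test_unknown_group_raises(self):
        with pytest.raises(KeyError):
            BiometricCov(1).sigma({"A_1_1": 1, "E_1_1": 1}, "XX")


# ----------------------------------------------------------------------
# FIML log-likelihood
# ----------------------------------------------------------------------
def _oracle_loglik(model, params, data):
    """Brute-force per-pair dense MVN log-density (complete and incomplete
    rows handled by explicit marginalization)."""
    caches, _, _ = build_cache(model, data)
    groups = list(caches)
    from twinpaths.sem_core import _mean_matrix

    total = 0.0
    for g, cache in caches.items():
        sigma = model.cov.sigma(params, g)
        means = _mean_matrix(model, params, groups, cache)
        for i in range(cache.n):
            obs = np.flatnonzero(~np.isnan(cache.y[i]))
            if obs.size == 0:
                continue
            total += sps.multivariate_normal.logpdf(
                cache.y[i, obs], mean=means[i, obs], cov=sigma[np.ix_(obs, obs)]
            )
    return total


@pytest.fixture(scope="module")
def tiny():
    return simulate_twins(ae_config(seed=9, n_mz=25, n_dz=25))


class TestFimlLoglik:
    def test_matches_dense_oracle_on_random_parameter_points(self, tiny):
        model = TwinModel(["y"], BiometricCov(1, ("A", "E")), MeanStructure("single"))
        rng = np.random.default_rng(7)
        for _ in range(100):
            params = {
                "A_1_1": rng.uniform(0.1, 1.0),
                "E_1_1": rng.uniform(0.2, 1.0),
                "mu[y]": rng.normal(scale=0.5),
            }
            ours = fiml_loglik(model, params, tiny)
            assert ours == pytest.approx(_oracle_loglik(model, params, tiny), abs=1e-8)

    def test_missing_twin_contributes_marginal_density(self):
        df = simulate_twins(ae_config(seed=3, n_mz=1, n_dz=0)).df
        df.loc[0, "y_2"] = np.nan
        ds = TwinDataset(df)
        model = TwinModel(["y"], BiometricCov(1, ("A", "E")), MeanStructure("single"))
        params = {"A_1_1": 0.5, "E_1_1": 0.5, "mu[y]": 0.1}
        expected = sps.norm.logpdf(df.loc[0, "y_1"], loc=0.1, scale=1.0)
        assert fiml_loglik(model, params, ds) == pytest.approx(expected, abs=1e-10)

    def test_duplicating_rows_doubles_loglik(self, tiny):
        import pandas as pd

        model = TwinModel(["y"], BiometricCov(1, ("A", "E")), MeanStructure("single"))
        params = {"A_1_1": 0.5, "E_1_1": 0.5, "mu[y]": 0.0}
        base = fiml_loglik(model, params, tiny)
        doubled = TwinDataset(
            pd.concat([tiny.df, tiny.df], ignore_index=True)
        )
        assert fiml_loglik(model, params, doubled) == pytest.approx(2 * base, rel=1e-12)

    def test_singular_covariance_penalized_not_crashed(self, tiny):
        model = TwinModel(["y"], BiometricCov(1, ("A", "E")), MeanStructure("single"))
        ll = fiml_loglik(model, {"A_1_1": 1.0, "E_1_1": -1.0, "mu[y]": 0.0}, tiny)
        assert np.isfinite(ll) and ll < -1e9


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------
class TestFit:
    def test_parameter_recovery_ae(self, ae_dataset):
        model = TwinModel(["y"], BiometricCov(1, ("A", "E")), MeanStructure("single"))
        f = fit(model, ae_dataset)
        assert f.converged
        assert f.params["A_1_1"] == pytest.approx(0.54, abs=2.5 * f.se["A_1_1"] + 1e-9)

    def test_multistart_agreement_from_true_values(self, ae_dataset):
        model = TwinModel(["y"], BiometricCov(1, ("A", "E")), MeanStructure("single"))
        f_default = fit(model, ae_dataset, compute_se=False)
        f_truth = fit(
            model,
            ae_dataset,
            start={"A_1_1": 0.54, "E_1_1": 0.46, "mu[y]": 0.0},
            compute_se=False,
        )
        assert abs(f_default.loglik - f_truth.loglik) < 1e-4

    def test_saturated_dominates_structured(self, small_ae_dataset):
        groups = small_ae_dataset.groups
        sat = TwinModel(
            ["y"], SaturatedCov(1, groups), MeanStructure("by_group")
        )
        struct = TwinModel(["y"], BiometricCov(1, ("A", "E")), MeanStructure("single"))
        f_sat = fit(sat, small_ae_dataset, compute_se=False)
        f_struct = fit(struct, small_ae_dataset, compute_se=False)
        assert f_sat.loglik >= f_struct.loglik - 1e-6

    def test_adding_free_parameter_never_decreases_loglik(self, small_ae_dataset):
        model = TwinModel(["y"], BiometricCov(1, ("A", "D", "E")), MeanStructure("single"))
        f_full = fit(model, small_ae_dataset, compute_se=False)
        f_nested = fit(model, small_ae_dataset, fix={"D_1_1": 0.0}, compute_se=False)
        assert f_full.loglik >= f_nested.loglik - 1e-6

    def test_twin_relabeling_invariance(self, small_ae_dataset):
        """Swapping twin 1 and twin 2 leaves the likelihood of an
        order-symmetric model unchanged."""
        model = TwinModel(["y"], BiometricCov(1, ("A", "E")), MeanStructure("single"))
        f = fit(model, small_ae_dataset, compute_se=False)
        df = small_ae_dataset.df.copy()
        df[["y_1", "y_2"]] = df[["y_2", "y_1"]].to_numpy()
        swapped = TwinDataset(df)
        assert fiml_loglik(model, f.params, swapped) == pytest.approx(f.loglik, abs=1e-8)

    def test_empty_dataset_raises(self):
        import pandas as pd

        df = pd.DataFrame(
            columns=["pair_id", "zygosity_group", "sex_1", "sex_2", "age_1", "age_2", "y_1", "y_2"]
        )
        model = TwinModel(["y"], BiometricCov(1, ("A", "E")), MeanStructure("single"))
        with pytest.raises(ValueError):
            fit(model, TwinDataset(df))


# ----------------------------------------------------------------------
# model comparison and information criteria
# ----------------------------------------------------------------------
def _dummy_fit(loglik, k, n=100):
    f = FitResult(
        model=None, params={}, loglik=loglik, k=k, n=n, aic=0, bic=0,
        converged=True, pmap=ParameterMap([]),
    )
    f.aic, f.bic = information_criteria(f)
    return f


class TestComparison:
    def test_identical_models_give_p_one(self):
        a = _dummy_fit(-100.0, 3)
        comp = lrt(a, a)
        assert comp.chisq == 0.0 and comp.pvalue == 1.0

    def test_reversed_nesting_raises(self):
        with pytest.raises(ValueError):
            lrt(_dummy_fit(-100.0, 2), _dummy_fit(-100.0, 5))

    def test_aic_formula(self):
        f = _dummy_fit(-100.0, 2)
        assert f.aic == pytest.approx(204.0)

    def test_bic_schwarz_and_printed_variants(self):
        f = _dummy_fit(-50.0, 3, n=100)
        aic, bic = information_criteria(f, bic_variant="schwarz")
        assert bic == pytest.approx(3 * math.log(100) + 100)
        _, bic_printed = information_criteria(f, bic_variant="printed")
        assert bic_printed == pytest.approx(3 * math.log(3) + 100)

    def test_nested_model_detected_as_worse_fit(self, small_ae_dataset):
        model = TwinModel(["y"], BiometricCov(1, ("A", "E")), MeanStructure("single"))
        f_full = fit(model, small_ae_dataset, compute_se=False)
        f_nested = fit(model, small_ae_dataset, fix={"A_1_1": 0.0}, compute_se=False)
        comp = lrt(f_full, f_nested)
        assert comp.ddf == 1 and comp.chisq >= 0


@pytest.fixture(scope="module")
def fits():
    ds = simulate_twins(ae_config(seed=77, n_mz=400, n_dz=400))
    groups = ds.groups
    sat = TwinModel(["y"], SaturatedCov(1, groups), MeanStructure("by_group"))
    base = TwinModel(["y"], IndependenceCov(1, groups), MeanStructure("by_group"))
    model = TwinModel(["y"], BiometricCov(1, ("A", "E")), MeanStructure("single"))
    return (
        fit(model, ds, compute_se=False),
        fit(sat, ds, compute_se=False),
        fit(base, ds, compute_se=False),
    )


class TestFitIndices:
    def test_saturated_as_model_gives_perfect_fit(self, fits):
        _, f_sat, f_base = fits
        cfi, srmr = fit_indices(f_sat, f_sat, f_base)
        assert cfi == pytest.approx(1.0)
        assert srmr == pytest.approx(0.0, abs=1e-10)

    def test_baseline_as_model_gives_cfi_zero(self, fits):
        _, f_sat, f_base = fits
        cfi, _ = fit_indices(f_base, f_sat, f_base)
        assert cfi == pytest.approx(0.0, abs=1e-9)

    def test_well_specified_model_fits_cleanly(self, fits):
        f_model, f_sat, f_base = fits
        cfi, srmr = fit_indices(f_model, f_sat, f_base)
        assert cfi > 0.98
        assert srmr < 0.05

    def test_non_nested_baseline_rejected(self, fits):
        f_model, f_sat, _ = fits
        with pytest.raises(ValueError):
            fit_indices(f_model, f_sat, f_sat)
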