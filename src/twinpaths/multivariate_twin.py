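"""Multivariate twin models.

Three AE solutions over k standardized traits:

* **Cholesky (path) model** — triangular loadings ordered so that the last
  trait's genetic and environmental variance is split into parts shared
  with the earlier traits and a unique residual.  Used to adjust the
  heritability of music reward sensitivity for music perceptual ability
  and general reward sensitivity.
* **Distinct factor solution** — direct symmetric estimation of all
  within- and cross-trait A and E (co)variances, from which genetic and
  environmental correlation matrices are extracted.
* **Shared factor solution** — a hybrid independent-pathway variant in
  which one component's cross-trait covariance collapses to a single
  common factor plus trait-specific variances; nested in the distinct
  solution (df difference k(k-1)/2 - k), so an LRT tests whether a single
  shared factor suffices.

The Cholesky and distinct-factor parametrisations both saturate the AE
covariance structure, so their maximized likelihoods coincide — a useful
internal cross-check.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .data import TwinDataset
from .sem_core import (
    BiometricCov,
    CholeskyCov,
    FitResult,
    MeanStructure,
    ModelComparison,
    SharedFactorCov,
    TwinModel,
    fit,
    lrt,
)

__all__ = [
    "CholeskyModel",
    "DirectSymmetricModel",
    "SharedFactorModel",
    "CorrelationStructure",
    "fit_cholesky",
    "adjusted_heritability",
    "unique_genetic_fraction",
    "test_cross_path",
    "fit_distinct_factors",
    "fit_shared_factor",
    "test_covariance_equality",
]


def _mean_structure(data: TwinDataset) -> MeanStructure:
    sexes = set(data.df["sex_1"].dropna()) | set(data.df["sex_2"].dropna())
    import pandas as pd

    ages = pd.concat([data.df["age_1"], data.df["age_2"]]).dropna()
    age = len(ages) > 1 and float(ages.std()) > 0
    return MeanStructure("by_sex" if len(sexes) > 1 else "single", age=age)


# ----------------------------------------------------------------------
# Cholesky decomposition
# ----------------------------------------------------------------------
@dataclass
class CholeskyModel:
    """Lower-triangular A and E path matrices for an ordered trait list."""

    traits: list[str]
    x: np.ndarray  # A paths
    z: np.ndarray  # E paths
    standardized: bool = True

    @property
    def a_within(self) -> np.ndarray:
        return self.x @ self.x.T

    @property
    def e_within(self) -> np.ndarray:
        return self.z @ self.z.T

    def path(self, component: str, i: int, j: int) -> float:
        m = self.x if component == "A" else self.z
        return float(m[i, j])


def _sign_fix_lower(m: np.ndarray) -> np.ndarray:
    """Resolve column reflection invariance: diagonal entries >= 0."""
    out = m.copy()
    for j in range(m.shape[1]):
        if out[j, j] < 0:
            out[:, j] = -out[:, j]
    return out


def fit_cholesky(
    data: TwinDataset,
    trait_order: list[str],
    standardize: bool = True,
    compute_se: bool = True,
) -> tuple[FitResult, CholeskyModel]:
    """ML fit of the k-variate AE Cholesky model on (by default z-scored)
    traits.  The trait order determines which shared components are
    regressed out of the final trait."""
    k = len(trait_order)
    if k < 1:
        raise ValueError("need at least one trait")
    ds = data.zscored(trait_order) if standardize else data
    model = TwinModel(list(trait_order), CholeskyCov(k), _mean_structure(ds), "cholesky")
    f = fit(model, ds, compute_se=compute_se)
    cov: CholeskyCov = model.cov
    x, z = cov.paths(f.params)
    x, z = _sign_fix_lower(x), _sign_fix_lower(z)
    for prefix, m in (("lA", x), ("lE", z)):
        for i in range(k):
            for j in range(i + 1):
                f.params[f"{prefix}_{i + 1}_{j + 1}"] = float(m[i, j])
    return f, CholeskyModel(list(trait_order), x, z, standardized=standardize)


def _last_trait_terms(model: CholeskyModel) -> tuple[float, float, float, float]:
    k = len(model.traits)
    a_unique = model.x[k - 1, k - 1] ** 2
    a_shared = float((model.x[k - 1, : k - 1] ** 2).sum())
    e_unique = model.z[k - 1, k - 1] ** 2
    e_shared = float((model.z[k - 1, : k - 1] ** 2).sum())
    return a_unique, a_shared, e_unique, e_shared


def adjusted_heritability(model: CholeskyModel) -> float:
    """Heritability of the last trait net of components shared with the
    earlier traits: unique A variance over the trait's total variance."""
    a_u, a_s, e_u, e_s = _last_trait_terms(model)
    denom = a_u + e_u + a_s + e_s
    if denom <= 0:
        raise ValueError("last trait has zero implied variance")
    return a_u / denom


def unique_genetic_fraction(model: CholeskyModel) -> float:
    """Share of the last trait's additive genetic variance unique to it."""
    a_u, a_s, _, _ = _last_trait_terms(model)
    if a_u + a_s <= 0:
        raise ValueError("last trait has zero genetic variance")
    return a_u / (a_u + a_s)


_PATH_RE = re.compile(r"^l([AE])_(\d+)_(\d+)$")


def test_cross_path(
    data: TwinDataset,
    full_fit: FitResult,
    path_id: str,
    standardize: bool = True,
) -> ModelComparison:
    """LRT of the full Cholesky model against one with the named cross-path
    (e.g. ``lA_3_1``) fixed to zero.  Diagonal paths are refused: zeroing
    them changes the model's rank, which is not a cross-trait test."""
    m = _PATH_RE.match(path_id)
    if not m:
        raise ValueError(f"unrecognized path id {path_id!r}")
    i, j = int(m.group(2)), int(m.group(3))
    if i == j:
        raise ValueError("only off-diagonal (cross) paths can be tested")
    model: TwinModel = full_fit.model
    ds = data.zscored(model.traits) if standardize else data
    nested = fit(model, ds, fix={path_id: 0.0}, start=full_fit.params, compute_se=False)
    return lrt(full_fit, nested)


# ----------------------------------------------------------------------
# distinct factor solution (direct symmetric)
# ----------------------------------------------------------------------
@dataclass
class DirectSymmetricModel:
    """Freely estimated A and E variances/covariances for k traits."""

    traits: list[str]
    a: np.ndarray
    e: np.ndarray
    out_of_bounds: bool = False  # negative variances or |r| > 1 occurred

    def heritabilities(self) -> np.ndarray:
        return np.diag(self.a) / (np.diag(self.a) + np.diag(self.e))


@dataclass
class CorrelationStructure:
    """Genetic and environmental correlation matrices with Wald CIs."""

    traits: list[str]
    r_a: np.ndarray
    r_e: np.ndarray
    ci_a: dict[tuple[int, int], tuple[float, float]] = field(default_factory=dict)
    ci_e: dict[tuple[int, int], tuple[float, float]] = field(default_factory=dict)
    flagged: bool = False


def _component_corr(m: np.ndarray) -> tuple[np.ndarray, bool]:
    d = np.diag(m).copy()
    bad = np.any(d <= 0)
    d = np.where(d <= 0, np.nan, d)
    r = m / np.sqrt(np.outer(d, d))
    np.fill_diagonal(r, 1.0)
    oob = bad or bool(np.nanmax(np.abs(r)) > 1 + 1e-9)
    return r, oob


def fit_distinct_factors(
    data: TwinDataset,
    traits: list[str],
    standardize: bool = False,
    compute_se: bool = True,
) -> tuple[FitResult, DirectSymmetricModel, CorrelationStructure]:
    """Direct-symmetric AE fit of all within- and cross-trait variances and
    covariances, with genetic/environmental correlations extracted as
    ``r = cov / sqrt(var_i * var_j)`` (delta-method CIs).  Out-of-bound
    estimates (negative variances, |r| > 1) are flagged, not truncated."""
    k = len(traits)
    if k < 2:
        raise ValueError("need at least two traits")
    ds = data.zscored(traits) if standardize else data
    model = TwinModel(list(traits), BiometricCov(k, ("A", "E")), _mean_structure(ds), "distinct")
    f = fit(model, ds, compute_se=compute_se)
    cov: BiometricCov = model.cov
    a = cov.component(f.params, "A")
    e = cov.component(f.params, "E")
    r_a, oob_a = _component_corr(a)
    r_e, oob_e = _component_corr(e)
    ds_model = DirectSymmetricModel(list(traits), a, e, out_of_bounds=oob_a or oob_e)
    corr = CorrelationStructure(list(traits), r_a, r_e, flagged=ds_model.out_of_bounds)
    if f.vcov is not None:
        zq = sps.norm.ppf(0.975)
        for comp, ci_store in (("A", corr.ci_a), ("E", corr.ci_e)):
            for i in range(k):
                for j in range(i):
                    def r_fun(p, c=comp, ii=i, jj=j):
                        den = p[f"{c}_{ii + 1}_{ii + 1}"] * p[f"{c}_{jj + 1}_{jj + 1}"]
                        if den <= 0:
                            return float("nan")
                        return p[f"{c}_{ii + 1}_{jj + 1}"] / math.sqrt(den)

                    val, se = f.derived(r_fun)
                    ci_store[(i, j)] = (val - zq * se, val + zq * se)
    return f, ds_model, corr


# ----------------------------------------------------------------------
# shared factor solutions
# ----------------------------------------------------------------------
@dataclass
class SharedFactorModel:
    """Rank-1-plus-diagonal structure on one component, free on the other."""

    traits: list[str]
    component: str  # which component carries the shared factor
    loadings: np.ndarray
    unique: np.ndarray
    other: np.ndarray  # free symmetric matrix of the other component

    @property
    def shared_total(self) -> np.ndarray:
        return np.outer(self.loadings, self.loadings) + np.diag(self.unique)


def fit_shared_factor(
    data: TwinDataset,
    traits: list[str],
    component: str = "A",
    standardize: bool = False,
    compute_se: bool = False,
) -> tuple[FitResult, SharedFactorModel]:
    """Fit the shared-factor (hybrid independent-pathway) AE solution with
    the common factor on ``component``; report loadings with the first
    loading >= 0 (the sign flip leaves the likelihood unchanged)."""
    k = len(traits)
    cov = SharedFactorCov(k, shared=component)  # raises for k < 3
    ds = data.zscored(traits) if standardize else data
    model = TwinModel(list(traits), cov, _mean_structure(ds), f"shared-{component}")
    f = fit(model, ds, compute_se=compute_se)
    lam = np.array([f.params[f"ls_{i + 1}"] for i in range(k)])
    if lam[0] < 0:
        lam = -lam
        for i in range(k):
            f.params[f"ls_{i + 1}"] = float(lam[i])
    uniq = np.array([f.params[f"u{component}_{i + 1}"] for i in range(k)])
    other = np.array(
        [
            [f.params[f"{cov.other}_{max(i, j) + 1}_{min(i, j) + 1}"] for j in range(k)]
            for i in range(k)
        ]
    )
    return f, SharedFactorModel(list(traits), component, lam, uniq, other)


# ----------------------------------------------------------------------
# covariance-equality tests (six-variate extension)
# ----------------------------------------------------------------------
def test_covariance_equality(
    data: TwinDataset,
    distinct_fit: FitResult,
    pairs: list[tuple[str, str]],
    component: str = "A",
) -> ModelComparison:
    """LRT of the distinct solution against a model in which the named
    trait-pair (co)variances of one component are constrained equal.

    Used in the six-variate extension to test whether, e.g., the genetic
    covariance between music perception and the social-reward facet
    exceeds its covariance with every other facet.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two trait pairs to constrain equal")
    model: TwinModel = distinct_fit.model
    traits = model.traits
    names = []
    for t1, t2 in pairs:
        i, j = traits.index(t1), traits.index(t2)
        if i == j:
            raise ValueError(f"pair ({t1}, {t2}) is not a cross-trait covariance")
        hi, lo = max(i, j), min(i, j)
        name = f"{component}_{hi + 1}_{lo + 1}"
        if name in names:
            raise ValueError(f"duplicate constraint on {name}")
        names.append(name)
    nested = fit(model, data, tie=[names], start=distinct_fit.params, compute_se=False)
    return lrt(distinct_fit, nested)
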