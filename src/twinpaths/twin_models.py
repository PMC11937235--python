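"""Univariate classical-twin-design analysis.

Stages, in study order: saturated multigroup model with sequential
equality constraints (twin order, zygosity, sex) as assumption tests; twin
correlations from the constrained saturated model; model-family selection
(ADE if r_MZ exceeds twice r_DZ, else ACE); the biometric fit with nested
reductions tested by likelihood ratio; and the closed-form descriptive
statistics (heritability, Cohen's d, covariate variance share, skewness).

The biometric model is fit by the direct symmetric approach — variance
components estimated freely, without positivity bounds — with sex-specific
means and an age covariate shared across the five groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import sem_core
from .data import GROUP_SEXES, KINSHIP, TwinDataset
from .sem_core import (
    BiometricCov,
    FitResult,
    MeanStructure,
    ModelComparison,
    SaturatedCov,
    TwinModel,
    fit,
    lrt,
)

__all__ = [
    "VarianceComponents",
    "TwinCorrelations",
    "SaturatedSequence",
    "BiometricResult",
    "fit_saturated",
    "twin_correlations",
    "select_family",
    "fit_biometric",
    "heritability",
    "cohens_d",
    "covariate_variance_share",
    "skewness",
]


def _cell_sex(group: str, slot: int) -> str:
    sexes = GROUP_SEXES.get(group)
    return sexes[slot] if sexes else "U"


def _is_mz(group: str) -> bool:
    return KINSHIP[group][0] == 1.0


# ----------------------------------------------------------------------
# saturated model and assumption tests
# ----------------------------------------------------------------------
@dataclass
class SaturatedSequence:
    """Fits of the saturated model under increasingly strict constraints."""

    trait: str
    fits: dict[str, FitResult]
    comparisons: dict[str, ModelComparison]

    def most_parsimonious(self, alpha: float = 0.007) -> str:
        """Last constraint level not rejected against its predecessor."""
        chosen = "free"
        for level, comp in self.comparisons.items():
            if comp.pvalue < alpha:
                break
            chosen = level
        return chosen


def _saturated_ties(trait: str, groups: list[str], level: str) -> list[list[str]]:
    ties: list[list[str]] = []
    if level == "free":
        return ties
    for g in groups:  # twin order: variances equal across slots; means too,
        # except in opposite-sex pairs where the slots differ by sex
        if _cell_sex(g, 0) == _cell_sex(g, 1):
            ties.append([f"mu[{g}:1:{trait}]", f"mu[{g}:2:{trait}]"])
        ties.append([f"S[{g}]_1_1", f"S[{g}]_2_2"])
    if level == "order":
        return ties
    # zygosity: one variance everywhere; means equal across groups within sex
    ties.append([f"S[{g}]_{d}_{d}" for g in groups for d in (1, 2)])
    cells: dict[str, list[str]] = {}
    for g in groups:
        for slot in (0, 1):
            cells.setdefault(_cell_sex(g, slot), []).append(f"mu[{g}:{slot + 1}:{trait}]")
    for names in cells.values():
        if len(names) > 1:
            ties.append(names)
    if level == "zygosity":
        return ties
    if level == "sex":  # all means equal
        ties.append([f"mu[{g}:{s}:{trait}]" for g in groups for s in (1, 2)])
        return ties
    raise ValueError(f"unknown constraint level {level!r}")


def fit_saturated(
    data: TwinDataset,
    trait: str,
    levels: tuple[str, ...] = ("free", "order", "zygosity", "sex"),
    age: bool = True,
    compute_se: bool = False,
) -> SaturatedSequence:
    """Fit the saturated five-group model under sequential equality
    constraints, comparing each level to its predecessor by LRT."""
    groups = [g for g in data.groups if data.n_pairs(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least two groups with data")
    model = TwinModel(
        [trait], SaturatedCov(1, groups), MeanStructure("by_group", age=age), "saturated"
    )
    fits: dict[str, FitResult] = {}
    comparisons: dict[str, ModelComparison] = {}
    prev = None
    for level in levels:
        ties = _saturated_ties(trait, groups, level)
        warm = fits[prev].params if prev is not None else None
        f = fit(model, data, tie=ties, start=warm, compute_se=compute_se)
        fits[level] = f
        if prev is not None:
            if f.loglik > fits[prev].loglik:
                # constrained fit found a better optimum: warm-restart the
                # fuller model so the nesting inequality holds
                fits[prev] = fit(
                    model,
                    data,
                    tie=_saturated_ties(trait, groups, prev),
                    start=f.params,
                    compute_se=compute_se,
                )
            comparisons[level] = lrt(fits[prev], f)
        prev = level
    return SaturatedSequence(trait, fits, comparisons)


# ----------------------------------------------------------------------
# twin correlations
# ----------------------------------------------------------------------
@dataclass
class TwinCorrelations:
    """Within-pair correlations per zygosity class with Fisher-z 95% CIs."""

    trait: str
    r: dict[str, float]
    ci: dict[str, tuple[float, float]]
    n_pairs: dict[str, int]
    fit: FitResult = field(repr=False, default=None)

    def __getitem__(self, key: str) -> float:
        return self.r[key]


def twin_correlations(
    data: TwinDataset,
    trait: str,
    by: str = "zygosity",
    age: bool = True,
    level: float = 0.95,
) -> TwinCorrelations:
    """Standardized within-pair covariance from the constrained saturated
    model (variances equal everywhere, means sex-specific, covariances
    pooled per zygosity class or free per group)."""
    groups = [g for g in data.groups if data.n_complete_pairs(trait, g) >= 2]
    if not groups:
        raise ValueError("no group with >= 2 complete pairs")
    vals = pd.concat([data.df[f"{trait}_1"], data.df[f"{trait}_2"]]).dropna()
    if vals.nunique() <= 1:
        raise ValueError(f"trait {trait} is degenerate (constant)")
    sub = TwinDataset(data.df[data.df["zygosity_group"].isin(groups)])
    model = TwinModel(
        [trait], SaturatedCov(1, groups), MeanStructure("by_group", age=age)
    )
    ties = _saturated_ties(trait, groups, "zygosity")
    classes: dict[str, list[str]]
    if by == "zygosity":
        classes = {}
        for g in groups:
            classes.setdefault("MZ" if _is_mz(g) else "DZ", []).append(g)
        for members in classes.values():
            if len(members) > 1:
                ties.append([f"S[{g}]_2_1" for g in members])
    elif by == "group":
        classes = {g: [g] for g in groups}
    else:
        raise ValueError("by must be 'zygosity' or 'group'")
    f = fit(model, sub, tie=ties, compute_se=False)
    var = f.params[f"S[{groups[0]}]_1_1"]
    zq = sps.norm.ppf(0.5 + level / 2.0)
    r, ci, n_pairs = {}, {}, {}
    for cls, members in sorted(classes.items()):
        cov = f.params[f"S[{members[0]}]_2_1"]
        r_c = float(np.clip(cov / var, -0.999999, 0.999999))
        n_c = sum(data.n_complete_pairs(trait, g) for g in members)
        if n_c > 3:
            z = math.atanh(r_c)
            half = zq / math.sqrt(n_c - 3)
            ci[cls] = (math.tanh(z - half), math.tanh(z + half))
        else:
            ci[cls] = (float("nan"), float("nan"))
        r[cls] = r_c
        n_pairs[cls] = n_c
    return TwinCorrelations(trait, r, ci, n_pairs, f)


def select_family(r_mz: float, r_dz: float) -> str:
    """ADE if the MZ correlation exceeds twice the DZ correlation, else ACE
    (ties resolve to ACE: C and D are both zero-identified at equality)."""
    if not (np.isfinite(r_mz) and np.isfinite(r_dz)):
        raise ValueError("correlations must be finite")
    return "ADE" if r_mz > 2.0 * r_dz else "ACE"


# ----------------------------------------------------------------------
# biometric model and reductions
# ----------------------------------------------------------------------
@dataclass
class VarianceComponents:
    """Raw and standardized variance components from the selected model."""

    family: str
    model_name: str  # e.g. "AE" after reduction
    raw: dict[str, float]
    se: dict[str, float]
    standardized: dict[str, tuple[float, float, float]]  # value, lo, hi
    h2: tuple[float, float, float] | None  # AE-standardized heritability


@dataclass
class BiometricResult:
    trait: str
    family: str
    fits: dict[str, FitResult]
    comparisons: dict[str, ModelComparison]
    best: str
    components: VarianceComponents

    @property
    def best_fit(self) -> FitResult:
        return self.fits[self.best]


def _mean_mode_for(data: TwinDataset) -> str:
    sexes = set(data.df["sex_1"].dropna()) | set(data.df["sex_2"].dropna())
    return "by_sex" if len(sexes) > 1 else "single"


def _age_varies(data: TwinDataset) -> bool:
    ages = pd.concat([data.df["age_1"], data.df["age_2"]]).dropna()
    return len(ages) > 1 and float(ages.std()) > 0

def fit_biometric(
    data: TwinDataset,
    trait: str,
    family: str | None = None,
    alpha: float = 0.007,
    mean_mode: str | None = None,
    age: bool | None = None,
    compute_se: bool = True,
) -> BiometricResult:
    """Fit the five-group biometric model and its nested reductions.

    The full ADE (or ACE) model is compared by LRT with the AE reduction
    (dropping D or C) and the E-only reduction; the most parsimonious model
    not significantly worse at ``alpha`` is selected.  Components are
    reported net of the age covariate.
    """
    if family is None:
        tc = twin_correlations(data, trait)
        family = select_family(tc.r.get("MZ", 0.0), tc.r.get("DZ", 0.0))
    if family not in ("ADE", "ACE"):
        raise ValueError("family must be 'ADE' or 'ACE'")
    extra = "D" if family == "ADE" else "C"
    mean_mode = mean_mode or _mean_mode_for(data)
    age = _age_varies(data) if age is None else age
    mean = MeanStructure(mean_mode, age=age)
    model = TwinModel([trait], BiometricCov(1, ("A", extra, "E")), mean, family)

    fits: dict[str, FitResult] = {}
    comparisons: dict[str, ModelComparison] = {}
    fits[family] = fit(model, data, compute_se=compute_se)
    fits["AE"] = fit(
        model, data, fix={f"{extra}_1_1": 0.0},
        start=fits[family].params, compute_se=compute_se,
    )
    if fits["AE"].loglik > fits[family].loglik:
        # the reduced model found a better optimum: warm-restart the full
        # model from it so the nesting inequality holds at convergence
        fits[family] = fit(
            model, data, start=fits["AE"].params, compute_se=compute_se
        )
    comparisons["AE"] = lrt(fits[family], fits["AE"])
    fits["E"] = fit(
        model, data, fix={f"{extra}_1_1": 0.0, "A_1_1": 0.0}, compute_se=compute_se
    )
    comparisons["E"] = lrt(fits["AE"], fits["E"])

    best = family
    if comparisons["AE"].pvalue >= alpha:
        best = "AE"
        if comparisons["E"].pvalue >= alpha:
            best = "E"
    bf = fits[best]

    raw = {c: bf.params[f"{c}_1_1"] for c in ("A", extra, "E")}
    se = {c: bf.se.get(f"{c}_1_1", float("nan")) for c in ("A", extra, "E")}
    zq = sps.norm.ppf(0.975)
    standardized = {}
    for c in ("A", extra, "E"):
        def share(p, comp=c):
            tot = p["A_1_1"] + p[f"{extra}_1_1"] + p["E_1_1"]
            return p[f"{comp}_1_1"] / tot

        val, s = bf.derived(share) if bf.vcov is not None else (share(bf.params), float("nan"))
        standardized[c] = (val, val - zq * s, val + zq * s)
    h2 = None
    if best in ("AE", family):
        def h2_fun(p):
            return p["A_1_1"] / (p["A_1_1"] + p["E_1_1"])

        val, s = bf.derived(h2_fun) if bf.vcov is not None else (h2_fun(bf.params), float("nan"))
        h2 = (val, val - zq * s, val + zq * s)
    components = VarianceComponents(family, best, raw, se, standardized, h2)
    return BiometricResult(trait, family, fits, comparisons, best, components)


# ----------------------------------------------------------------------
# closed-form derived statistics
# ----------------------------------------------------------------------
def heritability(sigma_a2: float, sigma_e2: float) -> float:
    """AE twin heritability: sigma_A^2 / (sigma_A^2 + sigma_E^2)."""
    tot = sigma_a2 + sigma_e2
    if tot <= 0:
        raise ValueError("sigma_A^2 + sigma_E^2 must be positive")
    return sigma_a2 / tot


def cohens_d(mean_1: float, mean_2: float, pooled_sd: float) -> float:
    """Standardized mean difference (mean_1 - mean_2) / pooled SD."""
    if pooled_sd <= 0:
        raise ValueError("pooled SD must be positive")
    return (mean_1 - mean_2) / pooled_sd


def covariate_variance_share(
    slope: float, covariate_variance: float, phenotype_variance: float
) -> float:
    """Fraction of phenotypic variance carried by a mean-structure
    covariate: slope^2 * var(covariate) / var(phenotype)."""
    if covariate_variance <= 0 or phenotype_variance <= 0:
        raise ValueError("variances must be positive")
    return slope**2 * covariate_variance / phenotype_variance


def skewness(values) -> tuple[float, bool]:
    """Adjusted Fisher-Pearson standardized third moment, plus the
    normal-theory ML gate (|skew| < 2 permits the ML estimator)."""
    vals = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(vals) < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.ptp(vals) == 0:
        raise ValueError("skewness undefined for constant input")
    g = float(sps.skew(vals, bias=False))
    return g, abs(g) < 2.0
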