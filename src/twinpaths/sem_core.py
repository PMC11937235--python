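"""Multigroup mean-and-covariance structure engine with FIML.

Every biometric model in this package is expressed as a pair of maps from a
named parameter vector to, per zygosity group, a mean structure (sex-specific
intercepts plus an optional age slope) and an implied covariance matrix for
the stacked twin observation vector ``(trait_1..k of twin 1, trait_1..k of
twin 2)``.  Estimation is full-information maximum likelihood (FIML): each
pair contributes the multivariate-normal log-density of its *observed*
sub-vector, so incomplete pairs are retained.  Rows are grouped by
missing-data pattern so each pattern's covariance sub-block is factorized
once.

Equality constraints and fixed parameters are handled by
:class:`ParameterMap`, which is how nested models (dropped variance
components, zeroed cross-paths, tied covariances) are built for
likelihood-ratio testing.

Numerical conventions
---------------------
* Optimizer: L-BFGS-B on the unconstrained parameter space with 2-point
  numerical gradients; no boundary constraints on variances (the direct
  symmetric parametrisation is deliberately unbounded).
* Convergence: optimizer success plus a polish restart; failures are
  flagged on the result, never silently accepted.
* Standard errors: inverse observed information, with the Hessian computed
  by central finite differences; derived quantities use the delta method.
* Non-positive-definite implied covariances during the search are mapped to
  a large finite penalty (graded by the most negative eigenvalue) so the
  optimizer can recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .data import KINSHIP, GROUP_SEXES, TwinDataset

LOG_2PI = math.log(2.0 * math.pi)
_PENALTY = -1e10

__all__ = [
    "ParameterMap",
    "MeanStructure",
    "SaturatedCov",
    "IndependenceCov",
    "BiometricCov",
    "CholeskyCov",
    "SharedFactorCov",
    "FactorCov",
    "TwinModel",
    "FitResult",
    "ModelComparison",
    "fit",
    "fiml_loglik",
    "lrt",
    "information_criteria",
    "fit_indices",
]


# ----------------------------------------------------------------------
# parameter bookkeeping
# ----------------------------------------------------------------------
class ParameterMap:
    """Maps a free parameter vector onto the model's full named vector.

    ``fix`` pins named parameters to constants; ``tie`` is an iterable of
    name tuples constrained equal (sharing one free slot).  Tying a group
    that contains a fixed member fixes the whole group.
    """

    def __init__(
        self,
        names: Sequence[str],
        fix: Mapping[str, float] | None = None,
        tie: Iterable[Sequence[str]] | None = None,
    ) -> None:
        self.names = list(names)
        name_set = set(self.names)
        fix = dict(fix or {})
        ties = [tuple(t) for t in (tie or [])]
        for n in list(fix) + [n for t in ties for n in t]:
            if n not in name_set:
                raise KeyError(f"unknown parameter {n!r}")

        parent = {n: n for n in self.names}

        def find(n):
            while parent[n] != n:
                parent[n] = parent[parent[n]]
                n = parent[n]
            return n

        for group in ties:
            for other in group[1:]:
                ra, rb = find(group[0]), find(other)
                if ra != rb:
                    parent[rb] = ra

        self.fixed: dict[str, float] = {}
        for n, v in fix.items():
            root = find(n)
            if root in self.fixed and self.fixed[root] != v:
                raise ValueError(f"contradictory fixes for tied parameter {n}")
            self.fixed[root] = float(v)

        self.free_names: list[str] = []
        slot: dict[str, int] = {}
        for n in self.names:
            root = find(n)
            if root in self.fixed:
                continue
            if root not in slot:
                slot[root] = len(self.free_names)
                self.free_names.append(root)
        self._root = {n: find(n) for n in self.names}
        self._slot = slot

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def expand(self, free: np.ndarray) -> dict[str, float]:
        out = {}
        for n in self.names:
            root = self._root[n]
            out[n] = self.fixed.get(root, None)
            if out[n] is None:
                out[n] = float(free[self._slot[root]])
        return out

    def reduce(self, full: Mapping[str, float]) -> np.ndarray:
        """Free-vector start values: mean of each tied group's entries."""
        acc = np.zeros(self.n_free)
        cnt = np.zeros(self.n_free)
        for n in self.names:
            root = self._root[n]
            if root in self.fixed:
                continue
            i = self._slot[root]
            acc[i] += full[n]
            cnt[i] += 1
        return acc / np.maximum(cnt, 1)

    def is_free(self, name: str) -> bool:
        return self._root[name] not in self.fixed

    def slot_of(self, name: str) -> int | None:
        root = self._root[name]
        return None if root in self.fixed else self._slot[root]


# ----------------------------------------------------------------------
# symmetric-matrix parameter helpers
# ----------------------------------------------------------------------
def _sym_names(prefix: str, k: int) -> list[str]:
    return [f"{prefix}_{i + 1}_{j + 1}" for i in range(k) for j in range(i + 1)]


def _sym_build(params: Mapping[str, float], prefix: str, k: int) -> np.ndarray:
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1):
            v = params[f"{prefix}_{i + 1}_{j + 1}"]
            m[i, j] = m[j, i] = v
    return m


def _sym_values(mat: np.ndarray, prefix: str) -> dict[str, float]:
    k = mat.shape[0]
    return {
        f"{prefix}_{i + 1}_{j + 1}": float(mat[i, j])
        for i in range(k)
        for j in range(i + 1)
    }


def _lower_names(prefix: str, k: int) -> list[str]:
    return _sym_names(prefix, k)


def _lower_build(params: Mapping[str, float], prefix: str, k: int) -> np.ndarray:
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1):
            m[i, j] = params[f"{prefix}_{i + 1}_{j + 1}"]
    return m


def nearest_psd(mat: np.ndarray, eps: float = 0.0) -> tuple[np.ndarray, float]:
    """Eigenvalue-clipped projection onto the PSD cone; returns distance."""
    sym = (mat + mat.T) / 2.0
    w, v = np.linalg.eigh(sym)
    w_clip = np.clip(w, eps, None)
    proj = v @ np.diag(w_clip) @ v.T
    return (proj + proj.T) / 2.0, float(np.linalg.norm(proj - sym))


# ----------------------------------------------------------------------
# covariance structures
# ----------------------------------------------------------------------
class CovStructure:
    """Implied-covariance parametrisation. ``pair`` marks twin-pair models."""

    k: int
    pair: bool = True

    @property
    def names(self) -> list[str]:  # pragma: no cover - abstract
        raise NotImplementedError

    def sigma(self, params: Mapping[str, float], group: str) -> np.ndarray:
        raise NotImplementedError

    def start(self, stats: dict) -> dict[str, float]:
        raise NotImplementedError

    @property
    def dim(self) -> int:
        return 2 * self.k if self.pair else self.k


class SaturatedCov(CovStructure):
    """Free symmetric covariance per group (the saturated twin model)."""

    def __init__(self, k: int, groups: Sequence[str], pair: bool = True):
        self.k = k
        self.pair = pair
        self.groups = list(groups)

    @property
    def names(self) -> list[str]:
        return [n for g in self.groups for n in _sym_names(f"S[{g}]", self.dim)]

    def sigma(self, params, group):
        return _sym_build(params, f"S[{group}]", self.dim)

    def start(self, stats):
        out = {}
        for g in self.groups:
            out.update(_sym_values(stats[g]["cov"], f"S[{g}]"))
        return out


class IndependenceCov(CovStructure):
    """Diagonal covariance per group: the null baseline for CFI."""

    def __init__(self, k: int, groups: Sequence[str], pair: bool = True):
        self.k = k
        self.pair = pair
        self.groups = list(groups)

    @property
    def names(self) -> list[str]:
        return [f"V[{g}]_{i + 1}" for g in self.groups for i in range(self.dim)]

    def sigma(self, params, group):
        return np.diag([params[f"V[{group}]_{i + 1}"] for i in range(self.dim)])

    def start(self, stats):
        out = {}
        for g in self.groups:
            d = np.diag(stats[g]["cov"])
            out.update({f"V[{g}]_{i + 1}": float(d[i]) for i in range(self.dim)})
        return out


class BiometricCov(CovStructure):
    """Direct-symmetric variance-component model.

    Each component in ``components`` (subset of A, D, C, E; E mandatory)
    contributes a free symmetric k x k (co)variance matrix, estimated
    without positivity bounds.  Within-twin block: sum of all components.
    Cross-twin block: ``r_alpha * A + r_delta * D + C``, with the kinship
    coefficients keyed to the zygosity group.
    """

    def __init__(self, k: int, components: Sequence[str] = ("A", "E")):
        if "E" not in components:
            raise ValueError("E component is mandatory")
        if "C" in components and "D" in components:
            raise ValueError("C and D are jointly unidentified in the twin design")
        self.k = k
        self.components = tuple(components)

    @property
    def names(self) -> list[str]:
        return [n for c in self.components for n in _sym_names(c, self.k)]

    def component(self, params, comp) -> np.ndarray:
        return _sym_build(params, comp, self.k)

    def sigma(self, params, group):
        r_a, r_d = KINSHIP[group]
        k = self.k
        within = np.zeros((k, k))
        cross = np.zeros((k, k))
        for c in self.components:
            m = self.component(params, c)
            within += m
            if c == "A":
                cross += r_a * m
            elif c == "D":
                cross += r_d * m
            elif c == "C":
                cross += m
        return np.block([[within, cross], [cross.T, within]])

    def start(self, stats):
        w, c_mz, c_dz = _pooled_blocks(stats, self.k)
        if "D" in self.components:
            a0 = 4 * c_dz - c_mz
            d0 = 2 * c_mz - 4 * c_dz
        elif "C" in self.components:
            a0 = 2 * (c_mz - c_dz)
            d0 = 2 * c_dz - c_mz  # reused as C start
        else:
            a0 = c_mz if np.any(c_mz) else 2 * c_dz
            d0 = None
        a0 = _shrink_cross(a0)
        out = _sym_values(_floor_diag(a0, w, 0.1), "A")
        if d0 is not None:
            comp = "D" if "D" in self.components else "C"
            out.update(_sym_values(_floor_diag(_shrink_cross(d0), w, 0.05), comp))
        total_other = sum(
            _sym_build(out, c, self.k) for c in self.components if c != "E"
        )
        e0 = _floor_diag(w - total_other, w, 0.2)
        out.update(_sym_values(e0, "E"))
        return out


class CholeskyCov(CovStructure):
    """Triangular path (Cholesky) AE twin model.

    ``A = X X^T`` and ``E = Z Z^T`` with X, Z lower triangular; the
    cross-twin block is ``r_alpha * A``.  PSD by construction; reflection
    invariance is resolved by reporting diagonal paths >= 0.
    """

    def __init__(self, k: int):
        self.k = k

    @property
    def names(self) -> list[str]:
        return _lower_names("lA", self.k) + _lower_names("lE", self.k)

    def paths(self, params) -> tuple[np.ndarray, np.ndarray]:
        return _lower_build(params, "lA", self.k), _lower_build(params, "lE", self.k)

    def sigma(self, params, group):
        r_a, _ = KINSHIP[group]
        x, z = self.paths(params)
        a = x @ x.T
        e = z @ z.T
        return np.block([[a + e, r_a * a], [r_a * a, a + e]])

    def start(self, stats):
        w, c_mz, c_dz = _pooled_blocks(stats, self.k)
        a0 = _floor_diag(_shrink_cross(c_mz if np.any(c_mz) else 2 * c_dz), w, 0.1)
        e0 = _floor_diag(w - a0, w, 0.2)
        x = np.linalg.cholesky(nearest_psd(a0, 1e-4)[0] + 1e-6 * np.eye(self.k))
        z = np.linalg.cholesky(nearest_psd(e0, 1e-4)[0] + 1e-6 * np.eye(self.k))
        out = {}
        for prefix, m in (("lA", x), ("lE", z)):
            for i in range(self.k):
                for j in range(i + 1):
                    out[f"{prefix}_{i + 1}_{j + 1}"] = float(m[i, j])
        return out


class SharedFactorCov(CovStructure):
    """Hybrid independent-pathway model on one component.

    The ``shared`` component ('A' or 'E') is a rank-1 common factor plus a
    trait-specific diagonal: ``X_s X_s^T + diag(u)``.  The other component
    keeps a free symmetric matrix, so the model is nested in the
    direct-symmetric (distinct factor) solution with df difference
    k(k-1)/2 - k.
    """

    def __init__(self, k: int, shared: str = "A"):
        if shared not in ("A", "E"):
            raise ValueError("shared component must be 'A' or 'E'")
        if k < 3:
            raise ValueError("rank-1 + diagonal structure needs k >= 3 traits")
        self.k = k
        self.shared = shared
        self.other = "E" if shared == "A" else "A"

    @property
    def names(self) -> list[str]:
        return (
            [f"ls_{i + 1}" for i in range(self.k)]
            + [f"u{self.shared}_{i + 1}" for i in range(self.k)]
            + _sym_names(self.other, self.k)
        )

    def shared_total(self, params) -> np.ndarray:
        lam = np.array([params[f"ls_{i + 1}"] for i in range(self.k)])
        uniq = np.array([params[f"u{self.shared}_{i + 1}"] for i in range(self.k)])
        return np.outer(lam, lam) + np.diag(uniq)

    def sigma(self, params, group):
        r_a, _ = KINSHIP[group]
        tot = self.shared_total(params)
        other = _sym_build(params, self.other, self.k)
        a = tot if self.shared == "A" else other
        e = other if self.shared == "A" else tot
        return np.block([[a + e, r_a * a], [r_a * a, a + e]])

    def start(self, stats):
        w, c_mz, c_dz = _pooled_blocks(stats, self.k)
        a0 = _floor_diag(_shrink_cross(c_mz if np.any(c_mz) else 2 * c_dz), w, 0.1)
        e0 = _floor_diag(w - a0, w, 0.2)
        tgt = a0 if self.shared == "A" else e0
        other0 = e0 if self.shared == "A" else a0
        vals, vecs = np.linalg.eigh(tgt)
        lam = vecs[:, -1] * math.sqrt(max(vals[-1], 1e-3))
        if lam[0] < 0:
            lam = -lam
        uniq = np.maximum(np.diag(tgt) - lam**2, 0.05 * np.diag(w))
        out = {f"ls_{i + 1}": float(lam[i]) for i in range(self.k)}
        out.update({f"u{self.shared}_{i + 1}": float(uniq[i]) for i in range(self.k)})
        out.update(_sym_values(other0, self.other))
        return out


class FactorCov(CovStructure):
    """Single-group one-factor model for individual-level indicators."""

    pair = False

    def __init__(self, k: int):
        if k < 4:
            raise ValueError("a one-factor model needs >= 4 indicators")
        self.k = k

    @property
    def names(self) -> list[str]:
        return (
            [f"load_{i + 1}" for i in range(self.k)]
            + ["fvar"]
            + [f"uvar_{i + 1}" for i in range(self.k)]
        )

    def sigma(self, params, group):
        lam = np.array([params[f"load_{i + 1}"] for i in range(self.k)])
        theta = np.array([params[f"uvar_{i + 1}"] for i in range(self.k)])
        return params["fvar"] * np.outer(lam, lam) + np.diag(theta)

    def start(self, stats):
        cov = next(iter(stats.values()))["cov"]
        sd = np.sqrt(np.clip(np.diag(cov), 1e-8, None))
        out = {f"load_{i + 1}": float(sd[i] / sd[0]) for i in range(self.k)}
        out["fvar"] = float(0.5 * cov[0, 0])
        for i in range(self.k):
            out[f"uvar_{i + 1}"] = float(0.5 * cov[i, i])
        return out


def _pooled_blocks(stats: dict, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pair-count-weighted within-twin and MZ/DZ cross-twin sample blocks."""
    w_acc = np.zeros((k, k))
    w_n = 0.0
    cross = {True: np.zeros((k, k)), False: np.zeros((k, k))}
    cross_n = {True: 0.0, False: 0.0}
    for g, st in stats.items():
        cov = np.nan_to_num(st["cov"])
        n = st["n"]
        if cov.shape[0] == k:  # individual-level data
            w_acc += n * cov
            w_n += n
            continue
        w_acc += n * (cov[:k, :k] + cov[k:, k:]) / 2.0
        w_n += n
        is_mz = KINSHIP[g][0] == 1.0
        b = (cov[:k, k:] + cov[k:, :k].T) / 2.0
        cross[is_mz] += n * (b + b.T) / 2.0
        cross_n[is_mz] += n
    w = w_acc / max(w_n, 1)
    c_mz = cross[True] / max(cross_n[True], 1)
    c_dz = cross[False] / max(cross_n[False], 1)
    return w, c_mz, c_dz


def _shrink_cross(m: np.ndarray, factor: float = 0.9) -> np.ndarray:
    out = m * factor
    np.fill_diagonal(out, np.diag(m))
    return out


def _floor_diag(m: np.ndarray, w: np.ndarray, frac: float) -> np.ndarray:
    out = (m + m.T) / 2.0
    floor = frac * np.clip(np.diag(w), 1e-8, None)
    d = np.maximum(np.diag(out), floor)
    np.fill_diagonal(out, d)
    return out


# ----------------------------------------------------------------------
# mean structure
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class MeanStructure:
    """Mean model for the stacked observation vector.

    mode
        ``single``: one intercept per trait, shared across groups/sexes;
        ``by_sex``: free per-sex intercepts per trait, shared across
        zygosity groups and twin order;
        ``by_group``: free per group x twin-slot x trait (saturated means).
    age
        Include a per-trait age slope (age centered at the sample mean).
    """

    mode: str = "single"
    age: bool = False

    def names(self, traits: Sequence[str], groups: Sequence[str], slots: int) -> list[str]:
        if self.mode == "single":
            out = [f"mu[{t}]" for t in traits]
        elif self.mode == "by_sex":
            out = [f"mu[{t}:{s}]" for t in traits for s in ("F", "M")]
        elif self.mode == "by_group":
            out = [
                f"mu[{g}:{sl + 1}:{t}]"
                for g in groups
                for sl in range(slots)
                for t in traits
            ]
        else:
            raise ValueError(f"unknown mean mode {self.mode!r}")
        if self.age:
            out += [f"bage[{t}]" for t in traits]
        return out


# ----------------------------------------------------------------------
# model container and data cache
# ----------------------------------------------------------------------
@dataclass
class TwinModel:
    """A biometric model: traits + covariance structure + mean structure."""

    traits: list[str]
    cov: CovStructure
    mean: MeanStructure = field(default_factory=MeanStructure)
    name: str = ""

    def __post_init__(self):
        if self.cov.k != len(self.traits):
            raise ValueError("covariance structure dimension != number of traits")

    @property
    def slots(self) -> int:
        return 2 if self.cov.pair else 1

    def param_names(self, groups: Sequence[str]) -> list[str]:
        return list(self.cov.names) + self.mean.names(self.traits, groups, self.slots)


class _GroupCache:
    """Per-group observation matrix, missingness patterns and mean indices."""

    def __init__(self, group, y, mean_idx, age_cells, trait_cells):
        self.group = group
        self.y = y
        self.mean_idx = mean_idx
        self.age_cells = age_cells
        self.trait_cells = trait_cells
        self.n = y.shape[0]
        mask = ~np.isnan(y)
        self.patterns = []
        if y.shape[0]:
            uniq, inv = np.unique(mask, axis=0, return_inverse=True)
            for i, pat in enumerate(uniq):
                obs = np.flatnonzero(pat)
                if obs.size == 0:
                    continue
                rows = np.flatnonzero(inv == i)
                self.patterns.append((obs, rows))
        self.complete = all(len(obs) == y.shape[1] for obs, _ in self.patterns)

    def sample_stats(self) -> dict:
        df = pd.DataFrame(self.y)
        cov = df.cov(min_periods=2).to_numpy()
        var = np.nanvar(self.y, axis=0, ddof=1) if self.n > 1 else np.ones(self.y.shape[1])
        d = np.diag(cov).copy()
        bad = ~np.isfinite(d)
        d[bad] = np.where(np.isfinite(var[bad]), var[bad], 1.0)
        cov[np.arange(len(d)), np.arange(len(d))] = np.where(np.isfinite(d), d, 1.0)
        cov = np.nan_to_num(cov)
        mean = np.nan_to_num(np.nanmean(self.y, axis=0)) if self.n else np.zeros(self.y.shape[1])
        return {"cov": cov, "mean": mean, "n": max(self.n, 1)}


def _sex_code(val) -> int:
    return 1 if str(val).upper().startswith("M") else 0


def build_cache(
    model: TwinModel, data, age_center: float | None = None
) -> tuple[dict[str, _GroupCache], float, int]:
    """Build per-group caches from a TwinDataset (pair models) or a plain
    individual-level DataFrame (``cov.pair`` False).  Returns the caches,
    the age-centering constant and the number of observed individuals."""
    traits = model.traits
    k = len(traits)
    if model.cov.pair:
        if not isinstance(data, TwinDataset):
            data = TwinDataset(data)
        groups = data.groups
        if age_center is None:
            ages = pd.concat([data.df["age_1"], data.df["age_2"]])
            age_center = float(ages.mean()) if ages.notna().any() else 0.0
        caches = {}
        n_ind = 0
        for g in groups:
            gdf = data.group_frame(g)
            cols = [f"{t}_1" for t in traits] + [f"{t}_2" for t in traits]
            y = gdf[cols].to_numpy(dtype=float)
            n, p = y.shape
            trait_cells = np.tile(np.arange(k), 2)
            slot_cells = np.repeat([0, 1], k)
            ages = gdf[["age_1", "age_2"]].to_numpy(dtype=float)
            age_cells = np.nan_to_num(ages[:, slot_cells] - age_center)
            mean_idx = _mean_index(model.mean, g, gdf, traits, trait_cells, slot_cells, groups)
            caches[g] = _GroupCache(g, y, mean_idx, age_cells, trait_cells)
            for slot in range(2):
                n_ind += int(np.any(~np.isnan(y[:, slot * k : (slot + 1) * k]), axis=1).sum())
        return caches, age_center, n_ind
    # individual-level data
    df = data.df if isinstance(data, TwinDataset) else data
    y = df[list(traits)].to_numpy(dtype=float)
    n, p = y.shape
    trait_cells = np.arange(k)
    if age_center is None:
        age_center = float(df["age"].mean()) if "age" in df else 0.0
    age_cells = (
        np.nan_to_num(df[["age"]].to_numpy(dtype=float) - age_center)[:, np.zeros(k, int)]
        if "age" in df
        else np.zeros((n, k))
    )
    mean_idx = _mean_index(model.mean, "all", df, traits, trait_cells, np.zeros(k, int), ["all"])
    cache = _GroupCache("all", y, mean_idx, age_cells, trait_cells)
    n_ind = int(np.any(~np.isnan(y), axis=1).sum())
    return {"all": cache}, age_center, n_ind


def _mean_index(mean, group, gdf, traits, trait_cells, slot_cells, groups):
    """(n, p) integer index into the mean-parameter vector."""
    k = len(traits)
    n = len(gdf)
    p = len(trait_cells)
    if mean.mode == "single":
        return np.broadcast_to(trait_cells, (n, p)).copy()
    if mean.mode == "by_sex":
        # layout: trait-major, F then M
        if f"sex_1" in gdf.columns:
            sex = np.column_stack(
                [gdf[f"sex_{sl + 1}"].map(_sex_code).to_numpy() for sl in (0, 1)]
            )
            sex_cells = sex[:, slot_cells]
        elif "sex" in gdf.columns:
            sex_cells = gdf["sex"].map(_sex_code).to_numpy()[:, None] * np.ones((1, p), int)
        else:
            sex_cells = np.zeros((n, p), int)
        return 2 * np.broadcast_to(trait_cells, (n, p)) + sex_cells.astype(int)
    if mean.mode == "by_group":
        gi = groups.index(group)
        slots = int(slot_cells.max()) + 1
        base = gi * slots * k + slot_cells * k + trait_cells
        return np.broadcast_to(base, (n, p)).copy()
    raise ValueError(mean.mode)


def _mean_matrix(model, params, groups, cache: _GroupCache) -> np.ndarray:
    mean_names = model.mean.names(model.traits, groups, model.slots)
    n_age = len(model.traits) if model.mean.age else 0
    vec = np.array([params[n] for n in mean_names])
    core = vec[: len(vec) - n_age]
    m = core[cache.mean_idx].astype(float)
    if model.mean.age:
        bage = vec[len(vec) - n_age :]
        m = m + bage[cache.trait_cells] * cache.age_cells
    return m


# ----------------------------------------------------------------------
# FIML log-likelihood
# ----------------------------------------------------------------------
def _group_loglik(sigma: np.ndarray, y: np.ndarray, m: np.ndarray, patterns) -> float:
    ll = 0.0
    for obs, rows in patterns:
        s = sigma[np.ix_(obs, obs)]
        try:
            chol = np.linalg.cholesky(s)
        except np.linalg.LinAlgError:
            w = np.linalg.eigvalsh((s + s.T) / 2.0)
            return _PENALTY * (1.0 + max(0.0, -float(w.min())))
        resid = y[np.ix_(rows, obs)] - m[np.ix_(rows, obs)]
        z = linalg.solve_triangular(chol, resid.T, lower=True)
        logdet = 2.0 * float(np.log(np.diag(chol)).sum())
        ll += -0.5 * (len(rows) * (len(obs) * LOG_2PI + logdet) + float((z**2).sum()))
    return ll


def fiml_loglik(
    model: TwinModel,
    params: Mapping[str, float],
    data,
    age_center: float | None = None,
    _caches=None,
) -> float:
    """Full-information ML log-likelihood of ``data`` under ``params``.

    Complete rows reproduce the dense multivariate-normal log-density;
    incomplete rows contribute the density of the observed sub-vector.
    Singular implied covariances yield a large finite penalty (flagged by
    its magnitude) rather than an exception.
    """
    if _caches is None:
        _caches, age_center, _ = build_cache(model, data, age_center)
    groups = list(_caches)
    ll = 0.0
    for g, cache in _caches.items():
        if cache.n == 0:
            continue
        sigma = model.cov.sigma(params, g)
        if not np.all(np.isfinite(sigma)):
            return _PENALTY * 2
        m = _mean_matrix(model, params, groups, cache)
        ll += _group_loglik(sigma, cache.y, m, cache.patterns)
        if ll <= _PENALTY:
            return ll
    return ll


# ----------------------------------------------------------------------
# fit results
# ----------------------------------------------------------------------
@dataclass
class FitResult:
    """Converged (or honestly flagged) estimates for one model on one dataset."""

    model: TwinModel
    params: dict[str, float]
    loglik: float
    k: int
    n: int
    aic: float
    bic: float
    converged: bool
    pmap: ParameterMap
    vcov: np.ndarray | None = None
    se: dict[str, float] = field(default_factory=dict)
    groups: list[str] = field(default_factory=list)
    group_n: dict[str, int] = field(default_factory=dict)
    age_center: float = 0.0
    message: str = ""

    def implied_covariance(self, group: str) -> np.ndarray:
        return self.model.cov.sigma(self.params, group)

    def derived(self, fun: Callable[[Mapping[str, float]], float]) -> tuple[float, float]:
        """Value and delta-method SE of a scalar function of the parameters."""
        value = float(fun(self.params))
        if self.vcov is None:
            return value, float("nan")
        x0 = self.pmap.reduce(self.params)
        grad = np.zeros_like(x0)
        h = 1e-5 * (1.0 + np.abs(x0))
        for i in range(len(x0)):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += h[i]
            xm[i] -= h[i]
            grad[i] = (fun(self.pmap.expand(xp)) - fun(self.pmap.expand(xm))) / (2 * h[i])
        var = float(grad @ self.vcov @ grad)
        return value, math.sqrt(max(var, 0.0))

    def derived_ci(self, fun, level: float = 0.95) -> tuple[float, float, float]:
        value, se = self.derived(fun)
        zq = stats.norm.ppf(0.5 + level / 2.0)
        return value, value - zq * se, value + zq * se


@dataclass
class ModelComparison:
    """Likelihood-ratio comparison of a nested model against its parent."""

    chisq: float
    ddf: int
    pvalue: float
    full_loglik: float
    nested_loglik: float


def lrt(full: FitResult, nested: FitResult, tol: float = 1e-6) -> ModelComparison:
    """LRT: chi-square = 2(lnL_full - lnL_nested) on df = k_full - k_nested."""
    ddf = full.k - nested.k
    if ddf < 0:
        raise ValueError("nested model must not have more free parameters than full")
    chisq = 2.0 * (full.loglik - nested.loglik)
    if chisq < -tol:
        raise ValueError(
            f"nested model fits better than full (delta chisq = {chisq:.4g}); "
            "check convergence"
        )
    chisq = max(chisq, 0.0)
    if ddf == 0:  # degenerate comparison of a model with itself
        p = 1.0 if chisq <= tol else 0.0
    else:
        p = float(stats.chi2.sf(chisq, ddf))
    return ModelComparison(chisq, ddf, p, full.loglik, nested.loglik)


def information_criteria(
    fit_result: FitResult, bic_variant: str = "schwarz"
) -> tuple[float, float]:
    """AIC = 2k - 2 lnL; BIC = k ln(N) (Schwarz) or the ``printed`` k ln(k)."""
    k, ll = fit_result.k, fit_result.loglik
    aic = 2.0 * k - 2.0 * ll
    if bic_variant == "schwarz":
        bic = k * math.log(max(fit_result.n, 1)) - 2.0 * ll
    elif bic_variant == "printed":
        bic = k * math.log(max(k, 1)) - 2.0 * ll
    else:
        raise ValueError("bic_variant must be 'schwarz' or 'printed'")
    return aic, bic


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------
def _closed_form_saturated(model, caches, groups, n_ind, pmap, age_center):
    """Exact ML for the saturated model with per-group free means and no
    covariate, when every row is complete: sample means and ML covariances."""
    params = {}
    ll = 0.0
    for gi, (g, cache) in enumerate(caches.items()):
        y = cache.y
        n, p = y.shape
        mean = y.mean(axis=0)
        cov = np.cov(y, rowvar=False, ddof=0) if n > 1 else np.eye(p)
        cov = np.atleast_2d(cov)
        params.update(_sym_values(cov, f"S[{g}]"))
        k = len(model.traits)
        for sl in range(model.slots):
            for ti, t in enumerate(model.traits):
                params[f"mu[{g}:{sl + 1}:{t}]"] = float(mean[sl * k + ti])
        m = np.broadcast_to(mean, (n, p))
        ll += _group_loglik(cov, y, m, cache.patterns)
    result = FitResult(
        model=model,
        params=params,
        loglik=ll,
        k=pmap.n_free,
        n=n_ind,
        aic=0.0,
        bic=0.0,
        converged=True,
        pmap=pmap,
        groups=groups,
        group_n={g: c.n for g, c in caches.items()},
        age_center=age_center,
        message="closed form",
    )
    result.aic, result.bic = information_criteria(result)
    return result


def _hessian(f: Callable[[np.ndarray], float], x: np.ndarray, rel_step: float = 1e-4):
    m = len(x)
    h = rel_step * (1.0 + np.abs(x))
    hess = np.zeros((m, m))
    f0 = f(x)
    fp = np.zeros(m)
    fm = np.zeros(m)
    for i in range(m):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        fp[i], fm[i] = f(xp), f(xm)
        hess[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(m):
        for j in range(i):
            xpp = x.copy()
            xpp[[i, j]] += [h[i], h[j]]
            xmm = x.copy()
            xmm[[i, j]] -= [h[i], h[j]]
            hess[i, j] = hess[j, i] = (
                f(xpp) - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + f(xmm)
            ) / (2 * h[i] * h[j])
    return hess


def fit(
    model: TwinModel,
    data,
    *,
    fix: Mapping[str, float] | None = None,
    tie: Iterable[Sequence[str]] | None = None,
    start: Mapping[str, float] | None = None,
    compute_se: bool = True,
    age_center: float | None = None,
    maxiter: int = 3000,
) -> FitResult:
    """Maximize the FIML log-likelihood of ``model`` on ``data``.

    ``fix`` and ``tie`` build constrained (nested) variants; ``start``
    overrides the method-of-moments start values.  Non-convergence is
    reported on the result, with estimates still returned.
    """
    caches, age_center, n_ind = build_cache(model, data, age_center)
    groups = list(caches)
    if n_ind == 0:
        raise ValueError("dataset contains no observed phenotypes")
    names = model.param_names(groups)
    pmap = ParameterMap(names, fix=fix, tie=tie)

    if (
        isinstance(model.cov, SaturatedCov)
        and model.mean.mode == "by_group"
        and not model.mean.age
        and not fix
        and not tie
        and start is None
        and all(c.complete and c.n > c.y.shape[1] for c in caches.values())
    ):
        return _closed_form_saturated(model, caches, groups, n_ind, pmap, age_center)

    stats_by_group = {g: c.sample_stats() for g, c in caches.items()}
    full_start = model.cov.start(stats_by_group)
    full_start.update(_mean_start(model, groups, stats_by_group))
    if start:
        full_start.update(start)
    x0 = pmap.reduce(full_start)

    def objective(x):
        return -fiml_loglik(model, pmap.expand(x), None, _caches=caches)

    res = optimize.minimize(
        objective, x0, method="L-BFGS-B", options={"maxiter": maxiter, "maxfun": 10 * maxiter}
    )
    # polish: restart once from the solution (cheap, helps flat regions)
    res2 = optimize.minimize(
        objective, res.x, method="L-BFGS-B", options={"maxiter": maxiter}
    )
    if res2.fun <= res.fun:
        res = res2
    if not res.success and pmap.n_free <= 20:
        # gradient-free fallback for cliff-adjacent (near-singular) optima
        res3 = optimize.minimize(
            objective, res.x, method="Nelder-Mead",
            options={"maxiter": 400 * pmap.n_free, "fatol": 1e-9, "xatol": 1e-9},
        )
        if res3.fun <= res.fun:
            res = res3
    params = pmap.expand(res.x)
    ll = -float(res.fun)
    converged = bool(res.success) and ll > _PENALTY / 2
    result = FitResult(
        model=model,
        params=params,
        loglik=ll,
        k=pmap.n_free,
        n=n_ind,
        aic=0.0,
        bic=0.0,
        converged=converged,
        pmap=pmap,
        groups=groups,
        group_n={g: c.n for g, c in caches.items()},
        age_center=age_center,
        message=str(res.message),
    )
    result.aic, result.bic = information_criteria(result)
    if compute_se and pmap.n_free and converged:
        hess = _hessian(objective, res.x)
        try:
            vcov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(hess)
        d = np.diag(vcov).copy()
        if np.any(d < 0):
            d = np.where(d < 0, np.nan, d)
        result.vcov = vcov
        se_free = np.sqrt(d)
        for n in names:
            slot = pmap.slot_of(n)
            result.se[n] = float(se_free[slot]) if slot is not None else 0.0
    return result


def _mean_start(model, groups, stats_by_group) -> dict[str, float]:
    names = model.mean.names(model.traits, groups, model.slots)
    k = len(model.traits)
    pooled = np.zeros(model.cov.dim)
    n_tot = 0
    for st in stats_by_group.values():
        pooled += st["n"] * st["mean"]
        n_tot += st["n"]
    pooled /= max(n_tot, 1)
    by_trait = (
        (pooled[:k] + pooled[k:]) / 2.0 if model.cov.pair else pooled
    )
    out = {}
    for n in names:
        if n.startswith("bage"):
            out[n] = 0.0
        elif model.mean.mode == "by_group":
            g, sl, t = n[3:-1].split(":", 2)
            sl = int(sl) - 1
            ti = model.traits.index(t)
            out[n] = float(stats_by_group[g]["mean"][sl * k + ti])
        else:
            t = n[3:-1].split(":", 1)[0]
            out[n] = float(by_trait[model.traits.index(t)])
    return out


# ----------------------------------------------------------------------
# fit indices
# ----------------------------------------------------------------------
def fit_indices(
    model_fit: FitResult, saturated_fit: FitResult, baseline_fit: FitResult
) -> tuple[float, float]:
    """CFI and SRMR of a structured model against saturated and baseline fits.

    CFI uses the likelihood-ratio chi-squares against the saturated model.
    SRMR is computed per group on residuals standardized by the saturated
    (observed) variances — including diagonal terms — and combined across
    groups by a pair-count-weighted root mean square.
    """
    if model_fit.k > saturated_fit.k:
        raise ValueError("model has more free parameters than the saturated model")
    if baseline_fit.loglik > model_fit.loglik + 1e-6:
        raise ValueError(
            "baseline fits better than the model; it is not an admissible "
            "null baseline for CFI"
        )
    chi_m = max(2.0 * (saturated_fit.loglik - model_fit.loglik), 0.0)
    df_m = saturated_fit.k - model_fit.k
    chi_b = max(2.0 * (saturated_fit.loglik - baseline_fit.loglik), 0.0)
    df_b = saturated_fit.k - baseline_fit.k
    num = max(chi_m - df_m, 0.0)
    den = max(chi_b - df_b, num)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    ss_acc = 0.0
    w_acc = 0.0
    for g in model_fit.groups:
        s_obs = saturated_fit.implied_covariance(g)
        s_mod = model_fit.implied_covariance(g)
        sd = np.sqrt(np.clip(np.diag(s_obs), 1e-12, None))
        resid = (s_obs - s_mod) / np.outer(sd, sd)
        iu = np.triu_indices_from(resid)
        n_g = model_fit.group_n.get(g, 1)
        ss_acc += n_g * float((resid[iu] ** 2).mean())
        w_acc += n_g
    srmr = math.sqrt(ss_acc / max(w_acc, 1))
    return cfi, srmr
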