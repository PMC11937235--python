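"""Questionnaire scoring, one-factor CFA, and the effective-number-of-tests
multiplicity correction.

The two instruments handled here are the 20-item Barcelona Music Reward
Questionnaire (BMRQ; five response options recoded 1-5, two reverse-coded
items, total score 20-100 with five 4-item facet sums) and the 5-item
Behavioral Approach System Reward Responsiveness scale (BAS-RR; responses
1-4, sum score 5-20).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sem_core
from .sem_core import FactorCov, MeanStructure, SaturatedCov, IndependenceCov, TwinModel

__all__ = [
    "InstrumentSpec",
    "BMRQ",
    "BASRR",
    "MultiplicityResult",
    "score_instrument",
    "fit_one_factor_cfa",
    "effective_tests",
]

BMRQ_FACETS = ("f1", "f2", "f3", "f4", "f5")
FACET_LABELS = {
    "f1": "emotion evocation",
    "f2": "mood regulation",
    "f3": "music seeking",
    "f4": "sensory motor",
    "f5": "social reward",
}


@dataclass(frozen=True)
class InstrumentSpec:
    """Scoring rule for a sum-score questionnaire."""

    name: str
    n_items: int
    response_min: int
    response_max: int
    reverse_items: tuple[int, ...] = ()  # 0-based indices, stored raw
    facets: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if any(i < 0 or i >= self.n_items for i in self.reverse_items):
            raise ValueError("reverse item index out of range")
        if self.facets:
            covered = sorted(i for idx in self.facets.values() for i in idx)
            if covered != list(range(self.n_items)):
                raise ValueError("facet map must partition the items")

    @property
    def score_min(self) -> int:
        return self.n_items * self.response_min

    @property
    def score_max(self) -> int:
        return self.n_items * self.response_max

    def recode(self, raw: np.ndarray) -> np.ndarray:
        """Apply reverse-coding: r -> min + max - r on the reverse items."""
        out = np.array(raw, dtype=float)
        for i in self.reverse_items:
            out[..., i] = self.response_min + self.response_max - out[..., i]
        return out


#: which two BMRQ items are reverse-coded is a configuration choice; every
#: statistic in this package depends only on the count (two).
BMRQ = InstrumentSpec(
    name="BMRQ",
    n_items=20,
    response_min=1,
    response_max=5,
    reverse_items=(1, 10),
    facets={f: tuple(range(4 * i, 4 * i + 4)) for i, f in enumerate(BMRQ_FACETS)},
)

BASRR = InstrumentSpec(name="BASRR", n_items=5, response_min=1, response_max=4)


def score_instrument(items: pd.DataFrame, spec: InstrumentSpec) -> pd.DataFrame:
    """Sum-score a wide item table (columns ``item_1`` .. ``item_n``).

    Reverse-coded items are recoded as ``min + max - raw`` before summing.
    Any missing item leaves the affected score(s) missing — no proration.
    Out-of-range responses raise, naming the offending rows.
    """
    cols = [f"item_{i + 1}" for i in range(spec.n_items)]
    missing_cols = [c for c in cols if c not in items.columns]
    if missing_cols:
        raise ValueError(f"item table lacks columns {missing_cols}")
    raw = items[cols].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (raw < spec.response_min) | (raw > spec.response_max)
    if np.any(bad):
        rows = np.flatnonzero(bad.any(axis=1))[:10].tolist()
        raise ValueError(f"{spec.name}: out-of-range responses in rows {rows}")
    recoded = spec.recode(raw)
    out = pd.DataFrame(index=items.index)
    out["total"] = recoded.sum(axis=1)
    out.loc[np.isnan(recoded).any(axis=1), "total"] = np.nan
    for facet, idx in spec.facets.items():
        sub = recoded[:, list(idx)]
        out[facet] = sub.sum(axis=1)
        out.loc[np.isnan(sub).any(axis=1), facet] = np.nan
    return out


def fit_one_factor_cfa(
    facet_scores: pd.DataFrame, indicators: list[str] | None = None
) -> dict:
    """Single-group one-factor CFA (first loading fixed to 1) on individual
    rows, e.g. one twin per pair to avoid within-pair dependence.

    Returns the model fit together with CFI and SRMR computed against the
    saturated and independence (free means/variances) models.
    """
    indicators = indicators or [c for c in BMRQ_FACETS if c in facet_scores.columns]
    if len(indicators) < 4:
        raise ValueError("one-factor CFA needs at least 4 indicators")
    df = facet_scores[indicators].dropna().reset_index(drop=True)
    k = len(indicators)
    mean = MeanStructure(mode="by_group")
    model = TwinModel(indicators, FactorCov(k), mean, name="one-factor CFA")
    model_fit = sem_core.fit(model, df, fix={"load_1": 1.0}, compute_se=False)
    sat = TwinModel(indicators, SaturatedCov(k, ["all"], pair=False), mean)
    base = TwinModel(indicators, IndependenceCov(k, ["all"], pair=False), mean)
    sat_fit = sem_core.fit(sat, df, compute_se=False)
    base_fit = sem_core.fit(base, df, compute_se=False)
    cfi, srmr = sem_core.fit_indices(model_fit, sat_fit, base_fit)
    return {"fit": model_fit, "cfi": cfi, "srmr": srmr,
            "saturated": sat_fit, "baseline": base_fit}


@dataclass
class MultiplicityResult:
    """Effective number of tests and the Bonferroni-adjusted alpha."""

    meff: int
    alpha: float
    base_alpha: float
    threshold: float
    explained: np.ndarray  # cumulative eigenvalue fractions


def effective_tests(
    correlation_matrix: np.ndarray,
    variance_threshold: float = 0.995,
    base_alpha: float = 0.05,
    clip_negative: bool = True,
) -> MultiplicityResult:
    """Effective number of independent tests (Gao's eigenvalue method).

    ``Meff`` is the smallest number of leading eigenvalues of the variable
    correlation matrix whose sum explains ``variance_threshold`` of the
    total variance; the adjusted threshold is ``base_alpha / Meff``.

    Near-zero negative eigenvalues (a by-product of pairwise-complete
    correlation estimation) are clipped at zero; a genuinely indefinite
    matrix raises.
    """
    r = np.asarray(correlation_matrix, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(r, r.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(r), 1.0, atol=1e-6):
        raise ValueError("correlation matrix must have unit diagonal")
    w = np.linalg.eigvalsh(r)[::-1]
    if w.min() < -1e-6:
        if not clip_negative:
            raise ValueError("correlation matrix is not positive semi-definite")
        if w.min() < -0.05:
            raise ValueError(
                f"correlation matrix is indefinite (min eigenvalue {w.min():.3g})"
            )
    w = np.clip(w, 0.0, None)
    frac = np.cumsum(w) / w.sum()
    meff = int(np.searchsorted(frac, variance_threshold - 1e-12) + 1)
    return MultiplicityResult(
        meff=meff,
        alpha=base_alpha / meff,
        base_alpha=base_alpha,
        threshold=variance_threshold,
        explained=frac,
    )
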