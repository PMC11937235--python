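"""End-to-end study pipeline.

Runs the analysis stages in the order of the study design — descriptives
and multiplicity threshold, univariate variance decomposition, trivariate
Cholesky adjustment, facet-level factor solutions, six-variate extension —
on either a simulated cohort or a user-supplied wide CSV, writing one JSON
report (full precision) and one markdown summary (2-decimal display) per
stage plus a manifest.  Deterministic for a fixed seed; a failed stage is
recorded in the manifest and later independent stages still run.
"""

from __future__ import annotations

import json
import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import TwinDataset, read_twin_csv
from .psychometrics import BMRQ, BMRQ_FACETS, effective_tests, fit_one_factor_cfa
from .synthetic_data import (
    SimConfig,
    facet_study_config,
    simulate_twins,
    trivariate_study_config,
)
from .twin_models import fit_biometric, select_family, skewness, twin_correlations
from .multivariate_twin import (
    adjusted_heritability,
    fit_cholesky,
    fit_distinct_factors,
    fit_shared_factor,
    test_cross_path,
    unique_genetic_fraction,
)
from .sem_core import lrt

log = logging.getLogger("twinpaths")

ALL_STAGES = ("descriptives", "multiplicity", "univariate", "cholesky", "facets", "sixvariate")


@dataclass
class PipelineConfig:
    """Pipeline inputs, stage toggles and output location."""

    seed: int = 17
    source: str | SimConfig | None = None  # CSV path, SimConfig, or None (demo)
    out_dir: str = "twinpaths_out"
    alpha: float = 0.007
    stages: tuple[str, ...] = ALL_STAGES
    univariate_trait: str = "BMRQ"
    cholesky_traits: tuple[str, ...] = ("SMDT", "BASRR", "BMRQ")
    facet_traits: tuple[str, ...] = BMRQ_FACETS
    demo_pairs: tuple[int, int] = (350, 400)  # MZ, DZ pairs for the demo cohort

    def validate(self) -> "PipelineConfig":
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        return self


def demo_dataset(seed: int, n_mz: int = 350, n_dz: int = 400) -> TwinDataset:
    """Bundled demo cohort: a standardized trivariate block (perception,
    general reward, music reward) under the calibrated Cholesky paths and
    an independent five-facet block from the published facet correlation/SD structure,
    simulated on pooled MZ/DZ groups."""
    counts = {"MZ": (n_mz, 0), "DZ": (n_dz, 0)}
    tri = simulate_twins(trivariate_study_config(seed, pair_counts=counts))
    fac = simulate_twins(facet_study_config(seed + 1, pair_counts=counts))
    df = tri.df.copy()
    for t in fac.traits:
        for s in ("1", "2"):
            df[f"{t}_{s}"] = fac.df[f"{t}_{s}"].to_numpy()
    return TwinDataset(df)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(results: dict, path) -> list[Path]:
    """Write ``<path>.json`` (full precision) and ``<path>.md`` (2-decimal
    display tables)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    json_path = path.with_suffix(".json")
    json_path.write_text(json.dumps(_jsonable(results), indent=2, sort_keys=True))
    lines = [f"# {path.stem}", ""]
    for key, val in results.items():
        lines.append(f"- **{key}**: {_fmt(val)}")
    md_path = path.with_suffix(".md")
    md_path.write_text("\n".join(lines) + "\n")
    return [json_path, md_path]


def _fmt(val) -> str:
    if isinstance(val, float):
        return f"{val:.2f}"
    if isinstance(val, dict):
        return "{" + ", ".join(f"{k}: {_fmt(v)}" for k, v in val.items()) + "}"
    if isinstance(val, (list, tuple)):
        if len(val) == 2 and all(isinstance(v, (int, float)) for v in val):
            return f"[{val[0]:.2f}, {val[1]:.2f}]"
        return "[" + ", ".join(_fmt(v) for v in val) + "]"
    if isinstance(val, np.ndarray):
        return _fmt(val.tolist())
    return str(val)


def _comparison_row(comp) -> dict:
    return {"chisq": comp.chisq, "ddf": comp.ddf, "p": comp.pvalue}


# ----------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------
def _stage_descriptives(ds: TwinDataset, cfg: PipelineConfig) -> dict:
    out: dict = {"n_pairs": {g: ds.n_pairs(g) for g in ds.groups}}
    trait = cfg.univariate_trait
    ind = ds.individual_frame()
    if trait in ind:
        vals = ind[trait].dropna()
        skew, ml_ok = skewness(vals)
        out[trait] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std()),
            "skew": skew,
            "ml_permissible": bool(ml_ok),
        }
    facets = [t for t in cfg.facet_traits if t in ind]
    if len(facets) >= 4:
        one_twin = ind[ind["twin"] == 1]
        cfa = fit_one_factor_cfa(one_twin, facets)
        out["one_factor_cfa"] = {"cfi": cfa["cfi"], "srmr": cfa["srmr"]}
    return out


def _stage_multiplicity(ds: TwinDataset, cfg: PipelineConfig) -> dict:
    ind = ds.individual_frame()
    one_twin = ind[ind["twin"] == 1]
    variables = [
        t
        for t in (*cfg.cholesky_traits[:-1], *cfg.facet_traits)
        if t in one_twin.columns
    ]
    r = one_twin[variables].corr().to_numpy()
    res = effective_tests(r, base_alpha=0.05)
    return {
        "variables": variables,
        "meff": res.meff,
        "alpha": res.alpha,
        "alpha_rounded": round(res.alpha, 3),
    }


def _stage_univariate(ds: TwinDataset, cfg: PipelineConfig) -> dict:
    trait = cfg.univariate_trait
    tc = twin_correlations(ds, trait)
    family = select_family(tc.r.get("MZ", 0.0), tc.r.get("DZ", 0.0))
    res = fit_biometric(ds, trait, family=family, alpha=cfg.alpha)
    return {
        "trait": trait,
        "twin_correlations": {k: {"r": tc.r[k], "ci": tc.ci[k], "n_pairs": tc.n_pairs[k]} for k in tc.r},
        "family": family,
        "reduction": {k: _comparison_row(v) for k, v in res.comparisons.items()},
        "best_model": res.best,
        "standardized": res.components.standardized,
        "h2": res.components.h2,
    }


def _stage_cholesky(ds: TwinDataset, cfg: PipelineConfig) -> dict:
    traits = list(cfg.cholesky_traits)
    f, model = fit_cholesky(ds, traits, compute_se=False)
    k = len(traits)
    tests = {}
    for comp in ("A", "E"):
        for j in range(1, k):
            pid = f"l{comp}_{k}_{j}"
            tests[pid] = _comparison_row(test_cross_path(ds, f, pid))
    return {
        "traits": traits,
        "adjusted_h2": adjusted_heritability(model),
        "unique_genetic_fraction": unique_genetic_fraction(model),
        "a_paths": model.x,
        "e_paths": model.z,
        "cross_path_tests": tests,
        "loglik": f.loglik,
        "converged": f.converged,
    }


def _stage_facets(ds: TwinDataset, cfg: PipelineConfig) -> dict:
    traits = list(cfg.facet_traits)
    f_dist, ds_model, corr = fit_distinct_factors(ds, traits, compute_se=False)
    f_sa, _ = fit_shared_factor(ds, traits, component="A")
    f_se, _ = fit_shared_factor(ds, traits, component="E")
    h2 = ds_model.heritabilities()
    return {
        "traits": traits,
        "heritabilities": {t: float(h) for t, h in zip(traits, h2)},
        "h2_min": float(np.min(h2)),
        "h2_max": float(np.max(h2)),
        "r_a": corr.r_a,
        "r_e": corr.r_e,
        "shared_genetic_lrt": _comparison_row(lrt(f_dist, f_sa)),
        "shared_environmental_lrt": _comparison_row(lrt(f_dist, f_se)),
        "out_of_bounds": ds_model.out_of_bounds,
    }


def _stage_sixvariate(ds: TwinDataset, cfg: PipelineConfig) -> dict:
    anchor = cfg.cholesky_traits[0]  # music perceptual ability
    traits = [anchor, *cfg.facet_traits]
    f, ds_model, corr = fit_distinct_factors(ds, traits, compute_se=False)
    from .multivariate_twin import test_covariance_equality

    pairs = [(anchor, t) for t in cfg.facet_traits]
    eq = test_covariance_equality(ds, f, pairs, component="A")
    return {
        "traits": traits,
        "r_a_with_anchor": {t: float(corr.r_a[0, i + 1]) for i, t in enumerate(cfg.facet_traits)},
        "r_e_with_anchor": {t: float(corr.r_e[0, i + 1]) for i, t in enumerate(cfg.facet_traits)},
        "equality_test": _comparison_row(eq),
    }


_STAGE_FUNCS = {
    "descriptives": _stage_descriptives,
    "multiplicity": _stage_multiplicity,
    "univariate": _stage_univariate,
    "cholesky": _stage_cholesky,
    "facets": _stage_facets,
    "sixvariate": _stage_sixvariate,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in study order and write reports.

    Returns the manifest (also written to ``manifest.json``).  Stage
    failures are caught, logged and recorded; later stages still run.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    if config.source is None:
        ds = demo_dataset(config.seed, *config.demo_pairs)
    elif isinstance(config.source, SimConfig):
        ds = simulate_twins(config.source)
    else:
        ds = read_twin_csv(config.source)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "n_pairs": {g: ds.n_pairs(g) for g in ds.groups},
        "stages": {},
    }
    for stage in config.stages:
        start = time.time()
        try:
            result = _STAGE_FUNCS[stage](ds, config)
            files = write_report(result, out_dir / stage)
            manifest["stages"][stage] = {
                "status": "ok",
                "files": [str(f) for f in files],
                "seconds": round(time.time() - start, 2),
            }
            log.info("stage %s completed in %.1fs", stage, time.time() - start)
        except Exception as exc:  # stage isolation is deliberate
            log.error("stage %s failed: %s", stage, exc)
            manifest["stages"][stage] = {
                "status": "error",
                "error": f"{type(exc).__name__}: {exc}",
                "traceback": traceback.format_exc(limit=5),
            }
    manifest["wallclock_seconds"] = round(time.time() - t0, 2)
    (out_dir / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
    return manifest
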