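"""Wide-format twin-pair tables.

A cohort is stored one row per twin pair with per-twin slots (``_1`` /
``_2`` column suffixes).  The five analysis strata follow the usual
sex-by-zygosity split of population twin registries: monozygotic women
(``MZw``), monozygotic men (``MZm``), dizygotic women (``DZw``), dizygotic
men (``DZm``) and opposite-sex dizygotic pairs (``DZos``).  Generic ``MZ``
and ``DZ`` labels are also accepted for simulations that do not stratify
by sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: expected additive (r_alpha) and dominance (r_delta) genetic relatedness
KINSHIP: dict[str, tuple[float, float]] = {
    "MZw": (1.0, 1.0),
    "MZm": (1.0, 1.0),
    "MZ": (1.0, 1.0),
    "DZw": (0.5, 0.25),
    "DZm": (0.5, 0.25),
    "DZos": (0.5, 0.25),
    "DZ": (0.5, 0.25),
}

ZYGOSITY_GROUPS = ("MZw", "MZm", "DZw", "DZm", "DZos")

#: fixed per-group twin sexes; None means unconstrained
GROUP_SEXES: dict[str, tuple[str, str] | None] = {
    "MZw": ("F", "F"),
    "MZm": ("M", "M"),
    "DZw": ("F", "F"),
    "DZm": ("M", "M"),
    "DZos": ("F", "M"),
    "MZ": None,
    "DZ": None,
}

_META_COLS = ("pair_id", "zygosity_group", "sex_1", "sex_2", "age_1", "age_2")


class TwinDataError(ValueError):
    """Raised when a twin table violates a structural invariant."""


@dataclass
class TwinDataset:
    """A cohort of twin pairs with (possibly missing) phenotype scores.

    Parameters
    ----------
    df
        Wide table with columns ``pair_id``, ``zygosity_group``,
        ``sex_1``, ``sex_2``, ``age_1``, ``age_2`` and one
        ``<trait>_1`` / ``<trait>_2`` pair of columns per phenotype.
        Missing scores are NaN.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _META_COLS if c not in self.df.columns]
        if missing:
            raise TwinDataError(f"missing required columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    # ------------------------------------------------------------------
    @property
    def traits(self) -> list[str]:
        out = []
        for c in self.df.columns:
            if c.endswith("_1") and c not in _META_COLS:
                t = c[:-2]
                if f"{t}_2" in self.df.columns:
                    out.append(t)
        return out

    @property
    def groups(self) -> list[str]:
        return sorted(self.df["zygosity_group"].unique())

    def n_pairs(self, group: str | None = None) -> int:
        if group is None:
            return len(self.df)
        return int((self.df["zygosity_group"] == group).sum())

    def n_complete_pairs(self, trait: str, group: str | None = None) -> int:
        df = self.df if group is None else self.df[self.df["zygosity_group"] == group]
        return int((df[f"{trait}_1"].notna() & df[f"{trait}_2"].notna()).sum())

    def n_individuals(self, traits: list[str] | None = None) -> int:
        """Twins with at least one observed phenotype among ``traits``."""
        traits = traits or self.traits
        n = 0
        for slot in ("1", "2"):
            cols = [f"{t}_{slot}" for t in traits]
            n += int(self.df[cols].notna().any(axis=1).sum())
        return n

    def group_frame(self, group: str) -> pd.DataFrame:
        return self.df[self.df["zygosity_group"] == group]

    def individual_frame(self, traits: list[str] | None = None) -> pd.DataFrame:
        """Long view: one row per twin (columns trait, sex, age, pair_id, twin)."""
        traits = traits or self.traits
        parts = []
        for slot in ("1", "2"):
            cols = {f"{t}_{slot}": t for t in traits}
            part = self.df[["pair_id", "zygosity_group", f"sex_{slot}", f"age_{slot}", *cols]].rename(
                columns={f"sex_{slot}": "sex", f"age_{slot}": "age", **cols}
            )
            part["twin"] = int(slot)
            parts.append(part)
        return pd.concat(parts, ignore_index=True)

    # ------------------------------------------------------------------
    def validate(self) -> "TwinDataset":
        """Check structural invariants, raising with offending pair ids."""
        df = self.df
        unknown = set(df["zygosity_group"]) - set(KINSHIP)
        if unknown:
            raise TwinDataError(f"unknown zygosity groups: {sorted(unknown)}")
        for g, sexes in GROUP_SEXES.items():
            if sexes is None:
                continue
            sub = df[df["zygosity_group"] == g]
            complete_sex = sub["sex_1"].notna() & sub["sex_2"].notna()
            if g.startswith("MZ") or g in ("DZw", "DZm"):
                bad = sub[complete_sex & (sub["sex_1"] != sub["sex_2"])]
                if len(bad):
                    raise TwinDataError(
                        f"same-sex group {g} has discordant-sex pairs: "
                        f"{bad['pair_id'].tolist()[:10]}"
                    )
            if g == "DZos":
                bad = sub[complete_sex & (sub["sex_1"] == sub["sex_2"])]
                if len(bad):
                    raise TwinDataError(
                        f"opposite-sex group has same-sex pairs: {bad['pair_id'].tolist()[:10]}"
                    )
        ages = pd.concat([df["age_1"], df["age_2"]])
        if (ages.dropna() < 0).any():
            raise TwinDataError("negative ages present")
        return self

    def drop_empty_pairs(self) -> tuple["TwinDataset", int]:
        """Drop pairs in which both twins miss every phenotype."""
        cols = [f"{t}_{s}" for t in self.traits for s in ("1", "2")]
        if not cols:
            return self, 0
        keep = self.df[cols].notna().any(axis=1)
        dropped = int((~keep).sum())
        return TwinDataset(self.df[keep]), dropped

    def zscored(self, traits: list[str] | None = None) -> "TwinDataset":
        """Standardize each trait using pooled individual-level moments."""
        traits = traits or self.traits
        df = self.df.copy()
        for t in traits:
            vals = pd.concat([df[f"{t}_1"], df[f"{t}_2"]])
            mu, sd = vals.mean(), vals.std(ddof=1)
            if not np.isfinite(sd) or sd <= 0:
                raise TwinDataError(f"trait {t} has zero or undefined variance")
            for s in ("1", "2"):
                df[f"{t}_{s}"] = (df[f"{t}_{s}"] - mu) / sd
        return TwinDataset(df)

    # ------------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TwinDataset":
        df = pd.read_csv(path)
        ds = cls(df)
        ds.validate()
        return ds


def read_twin_csv(path, validate: bool = True) -> TwinDataset:
    """Read a wide twin CSV, validate invariants, drop fully-empty pairs."""
    ds = TwinDataset(pd.read_csv(path))
    if validate:
        ds.validate()
    ds, _ = ds.drop_empty_pairs()
    return ds
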