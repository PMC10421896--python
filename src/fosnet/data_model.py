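"""Region atlas and expression-matrix containers.

The analysis operates on a table of immediate-early-gene (c-Fos) positive
cell counts: one row per animal, one column per brain region, plus a
behavioural-condition label per animal.  Regions belong to anatomical
groups (prefrontal cortex, amygdala, hippocampal subfields, ...) which
define the blocks used by the connectivity summaries.

Values may be on the raw count scale or expressed as percent of the
baseline (homecage) group's per-region mean; Pearson correlations are
invariant under that linear rescaling, so downstream network results do
not depend on which scale is used.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GROUP_LABELS",
    "RegionAtlas",
    "ExpressionMatrix",
    "ConditionDesign",
    "load_atlas",
    "default_atlas",
    "load_expression",
    "normalize_to_baseline",
    "AtlasError",
    "ExpressionError",
]

#: The nine anatomical group labels of the default 49-region atlas.
GROUP_LABELS = ("PFC", "mPFC", "RSC", "TAL", "AMY", "DH", "VH", "SUB", "PHC")

RAW = "raw"
PERCENT_OF_BASELINE = "percent_of_baseline"


class AtlasError(ValueError):
    """Raised for malformed or inconsistent region atlases."""


class ExpressionError(ValueError):
    """Raised for malformed expression tables."""


@dataclass(frozen=True)
class RegionAtlas:
    """Mapping from region codes to full names and anatomical groups.

    Parameters
    ----------
    table
        DataFrame with columns ``code``, ``name``, ``group``.  Codes must
        be unique and non-empty; groups must come from a fixed label set
        (by default the nine anatomical groups).
    """

    table: pd.DataFrame
    allowed_groups: tuple[str, ...] = GROUP_LABELS

    def __post_init__(self) -> None:
        required = {"code", "name", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise AtlasError(f"atlas table missing columns: {sorted(missing)}")
        codes = self.table["code"].astype(str)
        if (codes.str.len() == 0).any():
            raise AtlasError("atlas contains empty region codes")
        dup = codes[codes.duplicated()].tolist()
        if dup:
            raise AtlasError(f"duplicate region codes in atlas: {sorted(set(dup))}")
        bad = sorted(set(self.table["group"]) - set(self.allowed_groups))
        if bad:
            raise AtlasError(f"unknown anatomical group labels: {bad}")
        object.__setattr__(self, "table", self.table.reset_index(drop=True))

    # -- accessors ---------------------------------------------------------
    @property
    def codes(self) -> list[str]:
        return self.table["code"].tolist()

    @property
    def groups(self) -> list[str]:
        """Distinct group labels, in first-appearance order."""
        return list(dict.fromkeys(self.table["group"]))

    def group_of(self, code: str) -> str:
        row = self.table.loc[self.table["code"] == code]
        if row.empty:
            raise KeyError(code)
        return row["group"].iloc[0]

    def group_map(self) -> dict[str, str]:
        return dict(zip(self.table["code"], self.table["group"]))

    def regions_in(self, group: str) -> list[str]:
        return self.table.loc[self.table["group"] == group, "code"].tolist()

    def subset(self, codes: Iterable[str] | None = None, groups: Iterable[str] | None = None) -> "RegionAtlas":
        tab = self.table
        if codes is not None:
            codes = list(codes)
            tab = tab[tab["code"].isin(codes)]
        if groups is not None:
            tab = tab[tab["group"].isin(list(groups))]
        return RegionAtlas(tab.reset_index(drop=True), self.allowed_groups)

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def load_atlas(path: str | Path, allowed_groups: tuple[str, ...] = GROUP_LABELS) -> RegionAtlas:
    """Read a region atlas from a delimited-text file (columns code,name,group)."""
    try:
        table = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise AtlasError(f"could not parse atlas file {path}: {exc}") from exc
    if table.empty:
        raise AtlasError(f"atlas file {path} is empty")
    return RegionAtlas(table, allowed_groups)


def default_atlas() -> RegionAtlas:
    """The packaged 49-region / 9-group atlas."""
    ref = importlib.resources.files("fosnet.data") / "default_atlas.csv"
    with importlib.resources.as_file(ref) as path:
        return load_atlas(path)


@dataclass
class ConditionDesign:
    """Condition names, per-condition sample sizes and the baseline label.

    The default mirrors a six-condition fear-conditioning cohort: homecage
    baseline (HC), contextual fear conditioning with the context and shock
    overlapped (CFC) or separated by five seconds (CFC-5s), context-only
    controls (CT, CT-5s) and an immediate-shock control (US).
    """

    sizes: dict[str, int]
    baseline: str = "HC"

    def __post_init__(self) -> None:
        if self.baseline not in self.sizes:
            raise ValueError(f"baseline condition {self.baseline!r} not among conditions {sorted(self.sizes)}")
        small = {c: n for c, n in self.sizes.items() if n < 4}
        if small:
            # correlation p-values need df = n - 2 >= 2
            raise ValueError(f"sample sizes below the minimum of 4: {small}")

    @property
    def conditions(self) -> list[str]:
        return list(self.sizes)

    @property
    def n_animals(self) -> int:
        return int(sum(self.sizes.values()))

    @classmethod
    def from_expression(cls, expr: "ExpressionMatrix", baseline: str = "HC") -> "ConditionDesign":
        counts = expr.conditions.value_counts()
        order = list(dict.fromkeys(expr.conditions))
        return cls({c: int(counts[c]) for c in order}, baseline=baseline)


def study_design() -> ConditionDesign:
    """The six-group cohort layout (69 animals after tissue loss)."""
    return ConditionDesign(
        {"HC": 12, "CFC": 11, "CFC-5s": 11, "CT": 11, "CT-5s": 12, "US": 12},
        baseline="HC",
    )


@dataclass
class ExpressionMatrix:
    """Animals-by-regions expression values with condition labels.

    ``values`` is indexed by animal id with one column per region code in
    atlas order.  Missing measurements are explicit ``NaN`` (some animals
    lose posterior tissue during sectioning); they propagate into
    pairwise-complete correlations downstream.
    """

    values: pd.DataFrame
    conditions: pd.Series
    atlas: RegionAtlas
    scale: str = RAW

    def __post_init__(self) -> None:
        if self.scale not in (RAW, PERCENT_OF_BASELINE):
            raise ExpressionError(f"unknown scale tag {self.scale!r}")
        unknown = [c for c in self.values.columns if c not in set(self.atlas.codes)]
        if unknown:
            raise ExpressionError(f"region columns absent from atlas: {unknown}")
        # normalize column order to atlas order
        ordered = [c for c in self.atlas.codes if c in self.values.columns]
        self.values = self.values[ordered]
        if not self.values.index.equals(self.conditions.index):
            raise ExpressionError("values and condition labels index different animals")
        arr = self.values.to_numpy(dtype=float)
        finite = np.isfinite(arr) | np.isnan(arr)
        if not finite.all():
            raise ExpressionError("expression values must be finite or NaN")
        if arr.size and not np.isnan(arr).all() and np.nanmin(arr) < 0:
            raise ExpressionError("negative expression values are not allowed")

    # -- accessors ---------------------------------------------------------
    @property
    def regions(self) -> list[str]:
        return list(self.values.columns)

    @property
    def animals(self) -> list[str]:
        return list(self.values.index)

    def condition_set(self) -> list[str]:
        return list(dict.fromkeys(self.conditions))

    def subset(self, condition: str | Iterable[str]) -> "ExpressionMatrix":
        wanted = {condition} if isinstance(condition, str) else set(condition)
        missing = wanted - set(self.conditions)
        if missing:
            raise KeyError(f"conditions not present: {sorted(missing)}")
        mask = self.conditions.isin(wanted)
        return ExpressionMatrix(
            self.values.loc[mask].copy(), self.conditions.loc[mask].copy(), self.atlas, self.scale
        )

    def group_values(self, design: ConditionDesign | None = None) -> dict[str, pd.DataFrame]:
        conds = design.conditions if design is not None else self.condition_set()
        return {c: self.values.loc[self.conditions == c] for c in conds}

    # -- i/o ---------------------------------------------------------------
    def to_csv(self, path: str | Path, float_format: str = "%.10g") -> None:
        out = self.values.copy()
        out.insert(0, "condition", self.conditions)
        out.insert(0, "animal_id", out.index)
        out.to_csv(path, index=False, float_format=float_format)

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out.insert(0, "condition", self.conditions)
        return out


def load_expression(path: str | Path, atlas: RegionAtlas) -> ExpressionMatrix:
    """Read a wide expression table (animal_id, condition, one column per region)."""
    table = pd.read_csv(path)
    if table.empty:
        raise ExpressionError(f"expression file {path} is empty")
    for col in ("animal_id", "condition"):
        if col not in table.columns:
            raise ExpressionError(f"expression file missing required column {col!r}")
    region_cols = [c for c in table.columns if c not in ("animal_id", "condition")]
    unknown = [c for c in region_cols if c not in set(atlas.codes)]
    if unknown:
        raise ExpressionError(f"region columns absent from atlas: {unknown}")
    values = table[region_cols].astype(float)
    if (values.to_numpy() < 0).any():
        raise ExpressionError("negative expression values in file")
    values.index = table["animal_id"].astype(str)
    conditions = pd.Series(table["condition"].astype(str).to_numpy(), index=values.index, name="condition")
    return ExpressionMatrix(values, conditions, atlas, scale=RAW)


def normalize_to_baseline(expr: ExpressionMatrix, design: ConditionDesign) -> ExpressionMatrix:
    """Express every value as percent of the baseline group's per-region mean.

    A value equal to the baseline mean maps to 100.  The baseline group's
    own per-region means are exactly 100 afterwards.  Raises if any region
    has a zero (or undefined) baseline mean.
    """
    if expr.scale != RAW:
        raise ExpressionError("expression is already normalized")
    base = expr.values.loc[expr.conditions == design.baseline]
    if base.empty:
        raise ExpressionError(f"no animals in baseline condition {design.baseline!r}")
    means = base.mean(axis=0, skipna=True)
    bad = means.index[(means == 0) | means.isna()].tolist()
    if bad:
        raise ExpressionError(f"zero or undefined baseline mean in regions: {bad}")
    values = expr.values / means * 100.0
    return ExpressionMatrix(values, expr.conditions.copy(), expr.atlas, scale=PERCENT_OF_BASELINE)
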