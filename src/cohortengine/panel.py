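"""Core data containers and readers/writers for population panels.

The canonical in-memory container is :class:`PopulationPanel`, a validated
long-format table of population counts keyed by (area, race, sex, age, year).
Age groups use the 18-code ladder common to US bridged-race population files:
code ``a`` covers ages ``[5(a-1), 5a)`` for ``a < 18`` and code 18 is the
open-ended interval 85+.  Sex codes are 1 (Male) and 2 (Female).  Race codes
are small positive integers interpreted through a registry (default four
groups: 1 = White NH, 2 = Black NH, 3 = Hispanic, 4 = Other NH; a three-group
registry is used for validation-style layouts).

Area codes are opaque strings except that their first two characters are the
state code, which is needed to pool child-woman ratios at the state level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AGE_CODES",
    "SEX_CODES",
    "RACE_REGISTRY_FOUR",
    "RACE_REGISTRY_THREE",
    "PanelSchemaError",
    "PanelValidationError",
    "PopulationPanel",
    "GroupQuartersTable",
    "ControlTable",
    "DensePanel",
    "read_panel",
    "read_control",
    "write_projection",
    "write_panel",
]

AGE_CODES: tuple[int, ...] = tuple(range(1, 19))
OPEN_AGE_CODE = 18
SEX_CODES: tuple[int, ...] = (1, 2)
MALE, FEMALE = 1, 2

RACE_REGISTRY_FOUR: Mapping[int, str] = {
    1: "White NH",
    2: "Black NH",
    3: "Hispanic",
    4: "Other NH",
}
RACE_REGISTRY_THREE: Mapping[int, str] = {1: "White", 2: "Black", 3: "Other"}

#: childbearing female age codes, ages [15, 50)
CHILDBEARING_AGE_CODES: tuple[int, ...] = tuple(range(4, 11))

KEY_COLUMNS = ["area", "race", "sex", "age", "year"]
PANEL_COLUMNS = KEY_COLUMNS + ["value"]

DEFAULT_SCHEMA = {
    "area": ("area", "county", "fips", "geoid"),
    "race": ("race",),
    "sex": ("sex",),
    "age": ("age", "agegrp", "age_group"),
    "year": ("year", "time"),
    "value": ("value", "population", "pop", "count"),
}


class PanelSchemaError(ValueError):
    """A required column is missing or cannot be mapped."""


class PanelValidationError(ValueError):
    """Panel rows violate a structural invariant."""


def _resolve_columns(df: pd.DataFrame, schema: Mapping[str, str] | None) -> dict[str, str]:
    lower = {c.lower(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for canon, aliases in DEFAULT_SCHEMA.items():
        if schema and canon in schema:
            if schema[canon] not in df.columns:
                raise PanelSchemaError(
                    f"column {schema[canon]!r} (mapped to {canon!r}) not in file"
                )
            resolved[canon] = schema[canon]
            continue
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
        else:
            raise PanelSchemaError(f"no column found for {canon!r} (aliases: {aliases})")
    return resolved


def _validate_frame(df: pd.DataFrame, ages: Sequence[int] = AGE_CODES) -> pd.DataFrame:
    neg = df.index[df["value"] < 0]
    if len(neg):
        raise PanelValidationError(f"negative population values at rows {list(neg[:10])}")
    bad_age = sorted(set(df["age"]) - set(ages))
    if bad_age:
        raise PanelValidationError(
            f"age codes {bad_age} outside the supported ladder {ages[0]}..{ages[-1]}"
        )
    bad_sex = sorted(set(df["sex"]) - set(SEX_CODES))
    if bad_sex:
        raise PanelValidationError(f"sex codes must be 1 (Male) or 2 (Female); got {bad_sex}")
    if (df["race"] < 1).any():
        raise PanelValidationError("race codes must be positive integers")
    dup = df.duplicated(subset=KEY_COLUMNS, keep=False)
    if dup.any():
        keys = df.loc[dup, KEY_COLUMNS].drop_duplicates().head(10)
        raise PanelValidationError(
            "duplicate (area, race, sex, age, year) keys: "
            + "; ".join(str(tuple(r)) for r in keys.itertuples(index=False))
        )
    return df


@dataclass
class DensePanel:
    """Dense array view of a panel: ``values[area, race, sex, age, time]``.

    Cells absent from the source table are zero-filled.  Coordinate order is
    sorted and stable, so two panels with the same keys align elementwise.
    """

    values: np.ndarray
    areas: list[str]
    races: list[int]
    years: list[int]
    ages: list[int] = field(default_factory=lambda: list(AGE_CODES))
    sexes: list[int] = field(default_factory=lambda: list(SEX_CODES))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def state_of_area(self) -> np.ndarray:
        """Index of each area's state (first two characters of the code)."""
        states = sorted({a[:2] for a in self.areas})
        lookup = {s: i for i, s in enumerate(states)}
        return np.array([lookup[a[:2]] for a in self.areas]), states

    def to_panel(self) -> "PopulationPanel":
        idx = pd.MultiIndex.from_product(
            [self.areas, self.races, self.sexes, self.ages, self.years],
            names=KEY_COLUMNS,
        )
        df = pd.DataFrame({"value": self.values.ravel()}, index=idx).reset_index()
        return PopulationPanel(df, validate=False)


class PopulationPanel:
    """Validated long-format population counts.

    Parameters
    ----------
    df : DataFrame with columns area, race, sex, age, year, value.
    validate : run invariant checks (non-negativity, code ladder, key
        uniqueness).  Skipped for frames produced internally.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.loc[:, PANEL_COLUMNS].copy()
        df["area"] = df["area"].astype(str)
        for col in ("race", "sex", "age", "year"):
            df[col] = df[col].astype(int)
        df["value"] = df["value"].astype(float)
        if validate:
            _validate_frame(df)
        self.df = df.sort_values(KEY_COLUMNS, ignore_index=True)

    # -- basic introspection -------------------------------------------------
    @property
    def areas(self) -> list[str]:
        return sorted(self.df["area"].unique())

    @property
    def races(self) -> list[int]:
        return sorted(int(v) for v in self.df["race"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(int(v) for v in self.df["year"].unique())

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PopulationPanel):
            return NotImplemented
        return self.df.equals(other.df)

    def slice_year(self, year: int) -> pd.DataFrame:
        out = self.df[self.df["year"] == year]
        if out.empty:
            raise KeyError(f"panel has no rows for year {year}")
        return out

    def total(self, year: int | None = None) -> float:
        df = self.df if year is None else self.slice_year(year)
        return float(df["value"].sum())

    # -- dense conversion ----------------------------------------------------
    def to_dense(self, years: Iterable[int] | None = None) -> DensePanel:
        years = list(years) if years is not None else self.years
        areas, races = self.areas, self.races
        shape = (len(areas), len(races), len(SEX_CODES), len(AGE_CODES), len(years))
        vals = np.zeros(shape)
        df = self.df[self.df["year"].isin(years)]
        ai = pd.Categorical(df["area"], categories=areas).codes
        ri = pd.Categorical(df["race"], categories=races).codes
        si = df["sex"].to_numpy() - 1
        gi = df["age"].to_numpy() - 1
        ti = pd.Categorical(df["year"], categories=years).codes
        vals[ai, ri, si, gi, ti] = df["value"].to_numpy()
        return DensePanel(vals, areas, races, years)

    def check_complete(self) -> None:
        """Raise if any (area, race, sex, age, year) combination is absent."""
        expected = (
            len(self.areas) * len(self.races) * len(SEX_CODES) * len(AGE_CODES) * len(self.years)
        )
        if len(self.df) == expected:
            return
        idx = pd.MultiIndex.from_product(
            [self.areas, self.races, list(SEX_CODES), list(AGE_CODES), self.years],
            names=KEY_COLUMNS,
        )
        have = pd.MultiIndex.from_frame(self.df[KEY_COLUMNS])
        missing = idx.difference(have)
        raise PanelValidationError(
            f"panel is missing {len(missing)} cells, e.g. {list(missing[:5])}"
        )


class GroupQuartersTable(PopulationPanel):
    """Group-quarters (institutional/non-household) counts, same keys as a panel."""


class ControlTable:
    """Scenario control totals by (sex, age, year)."""

    COLUMNS = ["sex", "age", "year", "value"]

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.loc[:, self.COLUMNS].copy()
        for col in ("sex", "age", "year"):
            df[col] = df[col].astype(int)
        df["value"] = df["value"].astype(float)
        if validate:
            if (df["value"] < 0).any():
                raise PanelValidationError("control totals must be non-negative")
            if df.duplicated(subset=["sex", "age", "year"]).any():
                raise PanelValidationError("duplicate (sex, age, year) control keys")
        self.df = df.sort_values(["year", "sex", "age"], ignore_index=True)

    @property
    def years(self) -> list[int]:
        return sorted(int(v) for v in self.df["year"].unique())

    @property
    def ages(self) -> list[int]:
        return sorted(int(v) for v in self.df["age"].unique())

    def __eq__(self, other) -> bool:
        if not isinstance(other, ControlTable):
            return NotImplemented
        return self.df.equals(other.df)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_panel(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    cls: type[PopulationPanel] = PopulationPanel,
) -> PopulationPanel:
    """Read a delimited population table into a validated panel.

    ``schema`` maps canonical names (area/race/sex/age/year/value) to the
    file's column names; common aliases (county, population, time, ...) are
    recognised automatically.  Rows with identical keys are rejected.
    """
    path = Path(path)
    sep = _sep_for(path)
    header = pd.read_csv(path, sep=sep, nrows=0)
    cols = _resolve_columns(header, schema)
    raw = pd.read_csv(path, sep=sep, dtype={cols["area"]: str})
    df = raw.rename(columns={v: k for k, v in cols.items()})
    df["area"] = df["area"].astype(str)
    return cls(df[PANEL_COLUMNS])


def read_control(path: str | Path) -> ControlTable:
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path))
    raw.columns = [c.lower() for c in raw.columns]
    rename = {"time": "year", "population": "value", "pop": "value", "total": "value"}
    raw = raw.rename(columns=rename)
    missing = [c for c in ControlTable.COLUMNS if c not in raw.columns]
    if missing:
        raise PanelSchemaError(f"control file missing columns {missing}")
    return ControlTable(raw[ControlTable.COLUMNS])


def write_panel(panel: PopulationPanel, path: str | Path) -> None:
    """Write a panel in the canonical input layout (no completeness demands)."""
    path = Path(path)
    panel.df.to_csv(path, sep=_sep_for(path), index=False)


def write_projection(
    panel: PopulationPanel,
    scenario: str,
    path: str | Path,
    rounding: str = "none",
) -> None:
    """Write a projected panel in the deposited-output coding.

    Columns are area, year, scenario, age (1-18), sex (1 Male / 2 Female),
    race, population.  The panel must be complete over its declared area,
    race, sex, age and year codes.  ``rounding`` is ``"none"`` (write real
    values) or ``"nearest"`` (round half-to-even to whole persons).
    """
    if rounding not in {"none", "nearest"}:
        raise ValueError(f"rounding must be 'none' or 'nearest', got {rounding!r}")
    panel.check_complete()
    out = panel.df.rename(columns={"value": "population"}).copy()
    if rounding == "nearest":
        out["population"] = np.rint(out["population"]).astype(int)
    elif (out["population"] == np.rint(out["population"])).all():
        out["population"] = out["population"].astype(int)
    out["scenario"] = scenario
    out = out[["area", "year", "scenario", "age", "sex", "race", "population"]]
    path = Path(path)
    out.to_csv(path, sep=_sep_for(path), index=False)
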