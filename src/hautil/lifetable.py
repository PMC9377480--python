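"""Period life-table lookup used to set time trade-off horizons.

The TTO poses "X years in the assessed state versus fewer years Well"; the
full horizon X is the respondent's remaining life expectancy taken from a
period life table (column ``ex``, by single year of age and sex). A small
synthetic table covering ages 21-80 is bundled for tests and demos; any CSV
with the same columns (for example a national period life table restricted
to those ages) can be substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Union

import pandas as pd

from .errors import DomainError, FormatError

SEXES = ("female", "male")

REQUIRED_COLUMNS = ("age", "sex", "ex")


@dataclass(frozen=True)
class LifeTable:
    """Validated remaining-life-expectancy table, one row per (age, sex)."""

    data: pd.DataFrame  # columns: age (int), sex (str), ex (float)

    def age_range(self, sex: str) -> tuple[int, int]:
        sub = self.data[self.data["sex"] == sex]
        return int(sub["age"].min()), int(sub["age"].max())

    def remaining_years(self, age: int, sex: str) -> float:
        if sex not in SEXES:
            raise DomainError(f"unknown sex {sex!r}; expected one of {SEXES}")
        sub = self.data[(self.data["sex"] == sex) & (self.data["age"] == int(age))]
        if sub.empty:
            lo, hi = self.age_range(sex)
            raise DomainError(f"age {age} outside life-table range [{lo}, {hi}] for {sex}")
        return float(sub["ex"].iloc[0])


def read_life_table(path: Union[str, Path]) -> LifeTable:
    """Read and validate a life-table CSV with header ``age,sex,ex``.

    Rejects missing columns, non-numeric cells, unknown sex labels,
    non-contiguous ages, and any ``ex`` not strictly decreasing in age
    within a sex, naming the offending row.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty life-table file: {path}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"life table missing column(s): {', '.join(missing)}")
    if df.empty:
        raise FormatError("life table has no rows")

    for col in ("age", "ex"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0])
            raise FormatError(f"non-numeric {col!r} at row {row}")
        df[col] = coerced
    if not (df["age"] == df["age"].astype(int)).all():
        raise FormatError("ages must be integers")
    df["age"] = df["age"].astype(int)

    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        row = int(df.index[bad_sex][0])
        raise FormatError(f"unknown sex {df['sex'].iloc[row]!r} at row {row}")
    if (df["ex"] <= 0).any():
        row = int(df.index[df["ex"] <= 0][0])
        raise FormatError(f"non-positive ex at row {row}")
    if df.duplicated(subset=["age", "sex"]).any():
        row = int(df.index[df.duplicated(subset=["age", "sex"])][0])
        raise FormatError(f"duplicate (age, sex) at row {row}")

    for sex in df["sex"].unique():
        sub = df[df["sex"] == sex].sort_values("age")
        ages = sub["age"].to_numpy()
        if len(ages) > 1 and (ages[1:] - ages[:-1] != 1).any():
            raise FormatError(f"ages not contiguous for sex {sex!r}")
        ex = sub["ex"].to_numpy()
        increases = ex[1:] >= ex[:-1]
        if increases.any():
            age_bad = int(ages[1:][increases][0])
            raise FormatError(
                f"remaining life expectancy not strictly decreasing at age {age_bad} ({sex})"
            )

    return LifeTable(df.sort_values(["sex", "age"]).reset_index(drop=True))


def bundled_life_table_path() -> Path:
    """Path of the bundled synthetic life-table fixture (ages 21-80)."""
    return Path(resources.files("hautil").joinpath("data/life_table_synthetic.csv"))


def load_bundled_life_table() -> LifeTable:
    return read_life_table(bundled_life_table_path())


def tto_horizon(age: int, sex: str, table: LifeTable) -> int:
    """TTO horizon in whole years: remaining life expectancy at (age, sex),
    rounded to the nearest year (half rounds up), with a floor of 1 year."""
    ex = table.remaining_years(age, sex)
    return max(1, int(math.floor(ex + 0.5)))
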