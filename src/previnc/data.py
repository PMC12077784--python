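"""Containers and I/O for aggregated current-status data and life tables.

Aggregated current-status data record, per 5-year age group, how many people
were observed and how many had the condition at the inspection time.  Age
groups are encoded by closed integer bounds (a "20 to 24" group has
``age_start=20, age_end=24``); the representative age of such a group is its
midpoint ``(age_start + age_end + 1) / 2 = 22.5``.

Two worked example data sets ship with the package:

* breathlessness in British coal miners (a classic textbook table), with the
  matching paired life tables for England and Wales;
* ascertained type-2 diabetes in German women, 2009 and 2010, from statutory
  health insurance data (noise-protected and downsampled by its publisher).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "AggregatedPrevalenceTable",
    "SurvivorTable",
    "read_prevalence_csv",
    "read_lifetable_csv",
    "load_coalminers_prevalence",
    "load_coalminers_lifetable",
    "load_diabetes_prevalence",
]


@dataclass(frozen=True)
class AggregatedPrevalenceTable:
    """Per-age-group counts of observed persons and persons with the condition.

    Parameters
    ----------
    age_start, age_end : array of int
        Closed group bounds in years ("20 to 24" -> 20, 24).
    n : array of int
        Persons observed per group.
    c : array of int
        Persons with the condition per group, ``0 <= c <= n``.
    year : array of int, optional
        Calendar year per stratum, for data observed in several years.
    """

    age_start: np.ndarray
    age_end: np.ndarray
    n: np.ndarray
    c: np.ndarray
    year: np.ndarray | None = None

    def __post_init__(self):
        for name in ("age_start", "age_end", "n", "c"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if self.year is not None:
            object.__setattr__(self, "year", np.asarray(self.year))
        k = len(self.age_start)
        if not (len(self.age_end) == len(self.n) == len(self.c) == k):
            raise ValueError("all columns must have equal length")
        if self.year is not None and len(self.year) != k:
            raise ValueError("year column length mismatch")
        if np.any(self.c < 0) or np.any(self.c > self.n):
            bad = np.nonzero((self.c < 0) | (self.c > self.n))[0]
            raise ValueError(f"c must satisfy 0 <= c <= n; violated in rows {bad.tolist()}")
        if np.any(self.age_end < self.age_start):
            raise ValueError("age_end must be >= age_start in every group")
        self._check_overlap()

    def _check_overlap(self):
        # groups must be non-overlapping and ascending within each year stratum
        years = [None] if self.year is None else np.unique(self.year)
        for y in years:
            sel = slice(None) if y is None else self.year == y
            lo, hi = self.age_start[sel], self.age_end[sel]
            order = np.argsort(lo)
            lo, hi = lo[order], hi[order]
            if np.any(lo[1:] <= hi[:-1]):
                raise ValueError(f"overlapping age groups (year={y})")

    @property
    def midpoints(self) -> np.ndarray:
        """Representative age per group: ``(age_start + age_end + 1) / 2``."""
        return (self.age_start + self.age_end + 1) / 2.0

    @property
    def proportions(self) -> np.ndarray:
        """Observed prevalence ``c / n`` per group, as proportions."""
        return self.c / self.n

    @property
    def n_groups(self) -> int:
        return len(self.n)

    @property
    def years(self) -> np.ndarray | None:
        return None if self.year is None else np.unique(self.year)

    def select_year(self, y) -> "AggregatedPrevalenceTable":
        if self.year is None:
            raise ValueError("table has no year column")
        sel = self.year == y
        return AggregatedPrevalenceTable(
            self.age_start[sel], self.age_end[sel], self.n[sel], self.c[sel]
        )

    def to_frame(self) -> pd.DataFrame:
        d = {
            "age_start": self.age_start,
            "age_end": self.age_end,
            "n": self.n,
            "c": self.c,
        }
        if self.year is not None:
            d["year"] = self.year
        df = pd.DataFrame(d)
        df["prevalence_pct"] = 100.0 * self.c / self.n
        return df


@dataclass(frozen=True)
class SurvivorTable:
    """Life-table survivor columns on 5-year age groups.

    ``survivors[pop]`` is the number of a synthetic cohort still alive at the
    start of each age group; columns must be positive and non-increasing.
    """

    age_start: np.ndarray
    survivors: dict[str, np.ndarray] = field(default_factory=dict)
    group_width: int = 5

    def __post_init__(self):
        object.__setattr__(self, "age_start", np.asarray(self.age_start))
        object.__setattr__(
            self,
            "survivors",
            {k: np.asarray(v, dtype=float) for k, v in self.survivors.items()},
        )
        for name, col in self.survivors.items():
            if len(col) != len(self.age_start):
                raise ValueError(f"column {name!r} length mismatch")
            if np.any(col <= 0):
                raise ValueError(f"column {name!r} has non-positive survivor counts")
            bad = np.nonzero(np.diff(col) > 0)[0]
            if bad.size:
                raise ValueError(
                    f"survivor column {name!r} increases at rows {bad.tolist()}; "
                    "not a valid life table"
                )

    @property
    def populations(self) -> list[str]:
        return list(self.survivors)

    @property
    def n_groups(self) -> int:
        return len(self.age_start)


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def read_prevalence_csv(path) -> AggregatedPrevalenceTable:
    """Read an aggregated prevalence table.

    Expects columns ``age_start, age_end, n, c`` and optionally ``year``.  A
    ``prevalence`` or ``prevalence_pct`` column, if present, is cross-checked
    against ``100·c/n`` (warning above 0.01 percentage points) but never used
    as the data.
    """
    df = _read_csv(path)
    required = {"age_start", "age_end", "n", "c"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    for colname in sorted(required | ({"year"} & set(df.columns))):
        col = pd.to_numeric(df[colname], errors="coerce")
        if col.isna().any():
            rows = (np.nonzero(col.isna().to_numpy())[0] + 2).tolist()  # 1-based + header
            raise ValueError(f"{path}: non-numeric values in column {colname!r}, file rows {rows}")
        df[colname] = col
    table = AggregatedPrevalenceTable(
        df["age_start"].to_numpy(int),
        df["age_end"].to_numpy(int),
        df["n"].to_numpy(int),
        df["c"].to_numpy(int),
        df["year"].to_numpy(int) if "year" in df.columns else None,
    )
    for name in ("prevalence", "prevalence_pct"):
        if name in df.columns:
            stated = pd.to_numeric(df[name], errors="coerce").to_numpy()
            recomputed = 100.0 * table.c / table.n
            if np.nanmax(np.abs(stated - recomputed)) > 0.01:
                warnings.warn(
                    f"{path}: stated prevalence column deviates from 100*c/n by "
                    "more than 0.01 percentage points; using the recomputed values",
                    stacklevel=2,
                )
    return table


def read_lifetable_csv(path) -> SurvivorTable:
    """Read a survivor ("life") table: ``age_start`` plus one column per population.

    Rows are sorted by age if needed (with a warning); an increasing survivor
    sequence is a validation error naming the offending rows.
    """
    df = _read_csv(path)
    if "age_start" not in df.columns:
        raise ValueError(f"{path}: missing required column 'age_start'")
    pops = [col for col in df.columns if col != "age_start"]
    if not pops:
        raise ValueError(f"{path}: need at least one survivor column besides age_start")
    if not df["age_start"].is_monotonic_increasing:
        warnings.warn(f"{path}: rows not sorted by age_start; sorting", stacklevel=2)
        df = df.sort_values("age_start", ignore_index=True)
    return SurvivorTable(
        df["age_start"].to_numpy(int),
        {pop: df[pop].to_numpy(float) for pop in pops},
    )


def _dataset_path(name: str):
    return resources.files("previnc.datasets") / name


def load_coalminers_prevalence() -> AggregatedPrevalenceTable:
    """Breathlessness in British coal miners: 9 groups, ages 20-64."""
    return read_prevalence_csv(_dataset_path("coalminers_prevalence.csv"))


def load_coalminers_lifetable() -> SurvivorTable:
    """England & Wales life tables, general and breathlessness populations."""
    return read_lifetable_csv(_dataset_path("coalminers_lifetable.csv"))


def load_diabetes_prevalence() -> AggregatedPrevalenceTable:
    """Type-2 diabetes in German women, 2009-2010: 16 groups x 2 years."""
    return read_prevalence_csv(_dataset_path("diabetes_prevalence.csv"))
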