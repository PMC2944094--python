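"""Stratified health and population tables.

Event counts and person-years are held as pandas DataFrames keyed by the
stratum columns ``area_id, sex, age_band, year`` and, optionally,
``quintile`` (an area-level covariate quintile such as a deprivation
score).  Age bands are user-declared at load time: routine registries band
populations differently, so no band structure is hard-coded.  The default
band list used throughout the test fixtures is eighteen 5-year bands
0-4 ... 85+.

The module also expands ICD code filters ("icd10:C82-C85"), interpolates
populations between census years, and assigns covariate quintiles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_AGE_BANDS",
    "SEXES",
    "CountTable",
    "PopulationTable",
    "CodeFilter",
    "read_counts",
    "read_population",
    "write_counts",
    "write_population",
    "expand_code_filter",
    "interpolate_population",
    "assign_quintiles",
    "TableValidationError",
]

#: Conventional 5-year bands, 0-4 through 85+.
DEFAULT_AGE_BANDS: tuple[str, ...] = tuple(
    f"{lo}-{lo + 4}" for lo in range(0, 85, 5)
) + ("85+",)

SEXES = ("male", "female")

KEY_COLUMNS = ["area_id", "sex", "age_band", "year"]


class TableValidationError(ValueError):
    """Raised when a counts/population file violates the table contract.

    Carries a list of human-readable problems, each naming the offending
    line number(s) of the source file where applicable.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


def _key_columns(df: pd.DataFrame) -> list[str]:
    cols = list(KEY_COLUMNS)
    if "quintile" in df.columns:
        cols.append("quintile")
    return cols


def _validate_strata(df: pd.DataFrame, band_list, problems: list[str]) -> None:
    bands = set(band_list)
    bad = df.loc[~df["age_band"].isin(bands)]
    for idx, band in bad["age_band"].items():
        problems.append(f"line {idx + 2}: unknown age band {band!r}")
    bad_sex = df.loc[~df["sex"].isin(SEXES)]
    for idx, sex in bad_sex["sex"].items():
        problems.append(f"line {idx + 2}: unknown sex {sex!r}")
    if "quintile" in df.columns:
        q = pd.to_numeric(df["quintile"], errors="coerce")
        bad_q = df.loc[~q.isin([1, 2, 3, 4, 5])]
        for idx in bad_q.index:
            problems.append(
                f"line {idx + 2}: quintile {df.loc[idx, 'quintile']!r} not in 1..5"
            )
    keys = _key_columns(df)
    dup = df.duplicated(subset=keys, keep=False)
    if dup.any():
        for _, group in df.loc[dup].groupby(keys, observed=True):
            lines = ", ".join(str(i + 2) for i in group.index)
            problems.append(f"duplicate stratum key on lines {lines}")


@dataclass
class CountTable:
    """Event counts per (area, sex, age band, year[, quintile]) stratum."""

    data: pd.DataFrame
    band_list: tuple[str, ...] = DEFAULT_AGE_BANDS
    outcome: str = ""
    code_system: str = ""
    code_list: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        self.band_list = tuple(self.band_list)
        self.data = _normalise(self.data, "events", self.band_list, integer=True)

    @property
    def total(self) -> int:
        return int(self.data["events"].sum())

    def key_columns(self) -> list[str]:
        return _key_columns(self.data)


@dataclass
class PopulationTable:
    """Person-years at risk per stratum, same key structure as counts."""

    data: pd.DataFrame
    band_list: tuple[str, ...] = DEFAULT_AGE_BANDS

    def __post_init__(self):
        self.band_list = tuple(self.band_list)
        self.data = _normalise(self.data, "person_years", self.band_list)

    @property
    def total(self) -> float:
        return float(self.data["person_years"].sum())

    def key_columns(self) -> list[str]:
        return _key_columns(self.data)


def _normalise(df: pd.DataFrame, value_col: str, band_list, integer=False) -> pd.DataFrame:
    problems: list[str] = []
    df = df.reset_index(drop=True).copy()
    missing = [c for c in KEY_COLUMNS + [value_col] if c not in df.columns]
    if missing:
        raise TableValidationError([f"missing columns: {missing}"])
    df["year"] = df["year"].astype(int)
    values = pd.to_numeric(df[value_col], errors="coerce")
    for idx in df.index[values.isna()]:
        problems.append(f"line {idx + 2}: non-numeric {value_col}")
    neg = values < 0
    for idx in df.index[neg.fillna(False)]:
        problems.append(f"line {idx + 2}: negative {value_col} ({values[idx]})")
    if integer and not problems:
        frac = values % 1 != 0
        for idx in df.index[frac]:
            problems.append(f"line {idx + 2}: non-integer event count ({values[idx]})")
    _validate_strata(df, band_list, problems)
    if problems:
        raise TableValidationError(problems)
    df[value_col] = values.astype(int if integer else float)
    if "quintile" in df.columns:
        df["quintile"] = df["quintile"].astype(int)
    return df


def read_counts(path, band_list=DEFAULT_AGE_BANDS, schema: dict | None = None,
                outcome: str = "", **meta) -> CountTable:
    """Read a counts CSV into a validated :class:`CountTable`.

    Parameters
    ----------
    path
        CSV with header row and columns ``area_id, sex, age_band, year,
        [quintile], events`` (or any names remapped through *schema*).
    band_list
        Closed list of admissible age bands.
    schema
        Optional mapping from file column names to canonical names.

    Raises
    ------
    TableValidationError
        Naming each offending line for duplicate keys, unknown bands or
        sexes, and negative or non-integer counts.
    """
    df = pd.read_csv(path, dtype={"area_id": str})
    if schema:
        df = df.rename(columns=schema)
    return CountTable(df, band_list=band_list, outcome=outcome, **meta)


def read_population(path, band_list=DEFAULT_AGE_BANDS,
                    schema: dict | None = None) -> PopulationTable:
    """Read a person-years CSV into a validated :class:`PopulationTable`."""
    df = pd.read_csv(path, dtype={"area_id": str})
    if schema:
        df = df.rename(columns=schema)
    return PopulationTable(df, band_list=band_list)


def write_counts(table: CountTable, path) -> None:
    table.data.to_csv(path, index=False)


def write_population(table: PopulationTable, path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ICD code filters
# ---------------------------------------------------------------------------

_ICD10_RE = re.compile(r"^([A-Z])(\d{2})(?:\.(\w+))?$")


@dataclass(frozen=True)
class CodeFilter:
    """A set of diagnostic codes and closed code ranges in one system.

    ``include`` items are either single codes ("203", "C90", "C85.1") or
    inclusive ranges written with a dash or en-dash ("200-202", "C82-C85").
    Ranges expand at the 3-character category level within one system (and,
    for ICD-10, within one letter chapter).
    """

    code_system: str  # "icd9" | "icd10" | "user"
    include: tuple[str, ...]

    @classmethod
    def parse(cls, text: str) -> "CodeFilter":
        """Parse a config string like ``"icd10:C82-C85"`` or ``"icd9:200,202"``."""
        system, _, rest = text.partition(":")
        if not rest:
            raise ValueError(f"code filter {text!r} lacks 'system:codes'")
        items = tuple(s.strip() for s in rest.split(",") if s.strip())
        return cls(code_system=system.strip().lower(), include=items)


def _expand_range(system: str, start: str, end: str) -> list[str]:
    if system == "icd10":
        ms, me = _ICD10_RE.match(start), _ICD10_RE.match(end)
        if not ms or not me:
            raise ValueError(f"malformed ICD-10 range {start}-{end}")
        if ms.group(1) != me.group(1):
            raise ValueError(f"ICD-10 range {start}-{end} crosses letter chapters")
        lo, hi = int(ms.group(2)), int(me.group(2))
        if hi < lo:
            raise ValueError(f"range end before start: {start}-{end}")
        return [f"{ms.group(1)}{i:02d}" for i in range(lo, hi + 1)]
    if system == "icd9":
        if not (start.isdigit() and end.isdigit()):
            raise ValueError(f"malformed ICD-9 range {start}-{end}")
        lo, hi = int(start), int(end)
        if hi < lo:
            raise ValueError(f"range end before start: {start}-{end}")
        width = len(start)
        return [str(i).zfill(width) for i in range(lo, hi + 1)]
    raise ValueError(f"ranges are not defined for code system {system!r}")


def expand_code_filter(filt: CodeFilter) -> list[str]:
    """Expand ranges to a sorted, deduplicated list of concrete codes.

    Expansion is deterministic and order-independent; ranges are inclusive
    at both ends.  A reversed range ("C85-C82") is an error.
    """
    out: set[str] = set()
    for item in filt.include:
        item = item.replace("–", "-")  # en-dash tolerated
        if "-" in item:
            start, _, end = item.partition("-")
            out.update(_expand_range(filt.code_system, start.strip(), end.strip()))
        else:
            out.add(item)
    return sorted(out)


# ---------------------------------------------------------------------------
# Intercensal population interpolation
# ---------------------------------------------------------------------------

def interpolate_population(censuses: dict[int, PopulationTable], target_year: int,
                           method: str = "linear",
                           allow_extrapolation: bool = False) -> PopulationTable:
    """Cellwise linear interpolation of person-years between census years.

    At a census year the census table is returned exactly.  Outside the
    census hull the call is refused unless ``allow_extrapolation`` is set,
    in which case the nearest census segment is extended linearly.
    All censuses must share an identical stratum structure.
    """
    if method != "linear":
        raise ValueError(f"unknown interpolation method {method!r}")
    if not censuses:
        raise ValueError("no census tables supplied")
    years = sorted(censuses)
    if target_year in censuses:
        out = censuses[target_year]
        result = out.data.copy()
        result["year"] = target_year
        return PopulationTable(result, band_list=out.band_list)
    if not allow_extrapolation and not (years[0] <= target_year <= years[-1]):
        raise ValueError(
            f"target year {target_year} outside census hull "
            f"[{years[0]}, {years[-1]}]; pass allow_extrapolation=True to extend"
        )

    ref = censuses[years[0]]
    keys = [c for c in ref.key_columns() if c != "year"]
    frames = []
    for y in years:
        t = censuses[y]
        if tuple(t.band_list) != tuple(ref.band_list):
            raise ValueError("census tables declare different age-band lists")
        f = t.data.set_index(keys)["person_years"].sort_index()
        frames.append(f)
    base_index = frames[0].index
    for y, f in zip(years, frames):
        if not f.index.equals(base_index):
            raise ValueError(f"census {y} stratum structure differs from census {years[0]}")

    values = np.column_stack([f.to_numpy() for f in frames])
    if len(years) == 1:
        interp = values[:, 0]
    else:
        yrs = np.asarray(years, dtype=float)
        # np.interp clamps at the hull; build explicit segment extension for
        # extrapolation so the linear trend of the nearest segment continues.
        if target_year < yrs[0]:
            slope = (values[:, 1] - values[:, 0]) / (yrs[1] - yrs[0])
            interp = values[:, 0] + slope * (target_year - yrs[0])
        elif target_year > yrs[-1]:
            slope = (values[:, -1] - values[:, -2]) / (yrs[-1] - yrs[-2])
            interp = values[:, -1] + slope * (target_year - yrs[-1])
        else:
            interp = np.array([np.interp(target_year, yrs, row) for row in values])
    interp = np.clip(interp, 0.0, None)

    out = base_index.to_frame(index=False)
    out["year"] = int(target_year)
    out["person_years"] = interp
    return PopulationTable(out, band_list=ref.band_list)


# ---------------------------------------------------------------------------
# Covariate quintiles
# ---------------------------------------------------------------------------

def assign_quintiles(area_values: dict[str, float]) -> dict[str, int]:
    """Assign each area a quintile 1-5 of the area-value distribution.

    Boundaries sit at the 20/40/60/80th percentiles; a value exactly on a
    boundary goes to the *lower* quintile.  Requires at least 5 areas with
    finite values.
    """
    areas = list(area_values)
    vals = np.asarray([area_values[a] for a in areas], dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = [a for a, v in zip(areas, vals) if not np.isfinite(v)]
        raise ValueError(f"non-finite covariate values for areas {bad}")
    if len(areas) < 5:
        raise ValueError(f"need at least 5 areas to form quintiles, got {len(areas)}")
    breaks = np.percentile(vals, [20, 40, 60, 80])
    # side='left' counts only breaks strictly below the value: ties go low.
    quintiles = 1 + np.searchsorted(breaks, vals, side="left")
    return {a: int(q) for a, q in zip(areas, quintiles)}
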