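"""Readers and writers for the census-like input files and the population file.

All inputs are plain comma-separated text mirroring the public release
structures: an individual microdata sample, a hierarchical (household)
microdata sample, per-area aggregate profiles, a geographic hierarchy and a
projection table.  Readers are pure — the same file always yields the same
records.  Aggregate counts parse with or without thousands separators.

Small areas below the confidentiality threshold are absent from profiles;
:func:`read_profile` signals this with :data:`SUPPRESSED` rather than an
exception so pipelines can skip-and-log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .census_model import (
    CATEGORY_SIZES,
    OUTPUT_COLUMNS,
    CategoryMap,
    GeoHierarchy,
    validate_population_frame,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SCENARIOS",
    "SUPPRESSED",
    "SchemaError",
    "AreaProfile",
    "ProfileReader",
    "read_individual_microdata",
    "read_hierarchical_microdata",
    "read_profile",
    "read_geography",
    "read_projections",
    "write_population",
    "read_population",
    "population_path",
]

#: the nine projection growth scenarios
SCENARIOS: tuple[str, ...] = ("LG", "HG", "M1", "M2", "M3", "M4", "M5", "FA", "SA")

#: labels used for 5-year bands in the projection file; bands at 85+ collapse
#: into unified age group 17
PROJECTION_AGE_LABELS: dict[str, int] = {
    **{f"{5 * g} to {5 * g + 4} years": g for g in range(17)},
    "85 to 89 years": 17,
    "90 to 94 years": 17,
    "95 to 99 years": 17,
    "100 years and over": 17,
}
PROJECTION_SEX_LABELS = {"Females": 0, "Males": 1}

POPULATION_LABEL = "Population, 2016"
DWELLINGS_LABEL = "Private dwellings occupied by usual residents"


class SchemaError(ValueError):
    """An input file is missing a required column."""


class _Suppressed:
    """Marker for a small area absent from the profile (population < 40)."""

    def __repr__(self) -> str:  # pragma: no cover
        return "SUPPRESSED"

    def __bool__(self) -> bool:
        return False


SUPPRESSED = _Suppressed()


def _require(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file missing columns {missing}")


def _parse_count(x) -> float:
    if pd.isna(x) or x == "":
        return np.nan
    return float(str(x).replace(",", ""))


def read_individual_microdata(
    path: str | Path,
    province: str,
    cmap: CategoryMap | None = None,
) -> pd.DataFrame:
    """Read the weighted individual microdata sample for one province.

    Source categories are unified via *cmap*; records whose age code is the
    "not available" sentinel are dropped (their number is logged).  Returns a
    frame with the seven unified attribute columns plus ``weight``.
    """
    cmap = cmap or CategoryMap()
    df = pd.read_csv(path, dtype={"province": str})
    cols = ("id", "weight", "agegrp", "hdgree", "hhsize", "lfact",
            "province", "prihm", "sex", "totinc")
    _require(df, cols, "individual microdata")
    df = df[df["province"] == str(province)]
    if df.empty:
        return pd.DataFrame(
            columns=["agegrp", "sex", "hdgree", "lfact", "hhsize",
                     "totinc", "prihm", "weight"]
        )
    dropped = df["agegrp"].map(lambda c: cmap.is_ignored("agegrp", c))
    if dropped.any():
        logger.info("dropping %d records with unavailable age", int(dropped.sum()))
        df = df[~dropped]
    out = pd.DataFrame(index=df.index)
    for var in ("agegrp", "sex", "hdgree", "lfact", "hhsize", "prihm"):
        out[var] = df[var].map(lambda c, v=var: cmap.unify_code(v, c))
    out["totinc"] = df["totinc"].map(cmap.band_income)
    out["weight"] = df["weight"].astype(float)
    if (out["weight"] <= 0).any():
        raise ValueError("non-positive weights in individual microdata")
    return out.reset_index(drop=True)


def read_hierarchical_microdata(
    path: str | Path,
    province: str | None = None,
    cmap: CategoryMap | None = None,
) -> pd.DataFrame:
    """Read the household-grouped microdata sample.

    Returns a frame with ``hh_id, person_id, weight, agegrp, sex, prihm``
    (unified codes), optionally filtered to one province.  Households whose
    maintainer count is not exactly one are logged and dropped.
    """
    cmap = cmap or CategoryMap()
    df = pd.read_csv(path, dtype={"province": str})
    _require(df, ("hh_id", "person_id", "weight", "agegrp", "province",
                  "prihm", "sex"), "hierarchical microdata")
    if province is not None:
        df = df[df["province"] == str(province)]
    dropped = df["agegrp"].map(lambda c: cmap.is_ignored("agegrp", c))
    df = df[~dropped]
    out = pd.DataFrame(
        {
            "hh_id": df["hh_id"].to_numpy(),
            "person_id": df["person_id"].to_numpy(),
            "weight": df["weight"].astype(float).to_numpy(),
            "agegrp": df["agegrp"].map(lambda c: cmap.unify_code("agegrp", c)).to_numpy(),
            "sex": df["sex"].map(lambda c: cmap.unify_code("sex", c)).to_numpy(),
            "prihm": df["prihm"].map(lambda c: cmap.unify_code("prihm", c)).to_numpy(),
        }
    )
    n_maint = out.groupby("hh_id")["prihm"].sum()
    bad = n_maint[n_maint != 1].index
    if len(bad):
        logger.warning(
            "dropping %d households without exactly one maintainer", len(bad)
        )
        out = out[~out["hh_id"].isin(bad)]
    return out.reset_index(drop=True)


@dataclass
class AreaProfile:
    """Aggregate characteristic counts for one small area, keyed by label."""

    area: str
    rows: pd.DataFrame  # index: characteristic label; columns total, male, female

    def count(self, label: str) -> int:
        if label not in self.rows.index:
            raise KeyError(f"profile of area {self.area} has no row {label!r}")
        v = self.rows.loc[label, "total"]
        if pd.isna(v):
            raise KeyError(f"profile row {label!r} has no total for area {self.area}")
        return int(v)

    def sex_counts(self, label: str) -> tuple[int, int]:
        """(female, male) counts for a row; NaN becomes 0."""
        r = self.rows.loc[label]
        f = 0 if pd.isna(r["female"]) else int(r["female"])
        m = 0 if pd.isna(r["male"]) else int(r["male"])
        return f, m

    def has(self, label: str) -> bool:
        return label in self.rows.index and not pd.isna(self.rows.loc[label, "total"])


class ProfileReader:
    """Loads a region profile file once and serves per-area slices."""

    def __init__(self, path: str | Path):
        df = pd.read_csv(path, dtype={"area": str})
        _require(df, ("area", "characteristic", "total", "male", "female"),
                 "profile")
        for c in ("total", "male", "female"):
            df[c] = df[c].map(_parse_count)
        self._df = df
        self._by_area = {a: g for a, g in df.groupby("area")}

    @property
    def areas(self) -> list[str]:
        return sorted(self._by_area)

    def area(self, area_id: str):
        g = self._by_area.get(str(area_id))
        if g is None:
            return SUPPRESSED
        rows = g.set_index("characteristic")[["total", "male", "female"]]
        return AreaProfile(str(area_id), rows)


def read_profile(path: str | Path, area_id: str):
    """All profile rows for one area, or :data:`SUPPRESSED` if absent."""
    return ProfileReader(path).area(area_id)


def read_geography(path: str | Path) -> GeoHierarchy:
    df = pd.read_csv(path, dtype=str)
    return GeoHierarchy(df)


def read_projections(
    path: str | Path,
    scenario: str,
    year: int,
    province: str,
    scale: float = 1.0,
) -> np.ndarray:
    """Projected person counts by (sex, unified age group) for one slice.

    The file's 5-year bands above 85 are aggregated into unified age group
    17.  *scale* multiplies file values (for sources published in units of
    1 000 persons); the default treats values as persons as printed.
    Raises ``KeyError`` for a missing (scenario, year, province) slice.
    """
    df = pd.read_csv(path, dtype={"province": str})
    _require(df, ("year", "province", "scenario", "sex", "age_group", "value"),
             "projections")
    if scenario not in SCENARIOS:
        raise KeyError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    sel = df[
        (df["scenario"] == scenario)
        & (df["year"].astype(int) == int(year))
        & (df["province"] == str(province))
    ]
    if sel.empty:
        raise KeyError(
            f"projection slice ({scenario}, {year}, {province}) absent from {path}"
        )
    out = np.zeros((2, CATEGORY_SIZES["agegrp"]), dtype=float)
    for _, row in sel.iterrows():
        try:
            s = PROJECTION_SEX_LABELS[row["sex"]]
            g = PROJECTION_AGE_LABELS[row["age_group"]]
        except KeyError:
            raise SchemaError(
                f"unknown projection label {row['sex']!r}/{row['age_group']!r}"
            ) from None
        out[s, g] += _parse_count(row["value"]) * scale
    if (out < 0).any():
        raise ValueError("negative projection counts")
    return out


def write_population(individuals: pd.DataFrame, path: str | Path) -> None:
    """Write the population file (12 fixed columns, comma-separated).

    Refuses to write a frame that violates the individual invariants.
    """
    validate_population_frame(individuals)
    out = individuals[list(OUTPUT_COLUMNS)]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def read_population(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"area": str})
    _require(df, OUTPUT_COLUMNS, "population")
    for c in OUTPUT_COLUMNS:
        if c != "area":
            df[c] = df[c].astype(np.int64)
    return df[list(OUTPUT_COLUMNS)]


def population_path(
    root: str | Path,
    province_name: str,
    year: int,
    scenario: str | None = None,
    households: bool = False,
) -> Path:
    """Output naming convention: ``{province}/syn_pop[/{scenario}]/synthetic_pop_{year}[_hh]_.csv``.

    The base (2016) population has no scenario directory.
    """
    suffix = "_hh_" if households else "_"
    parts = [str(root), province_name.lower().replace(" ", "_"), "syn_pop"]
    if scenario is not None:
        parts.append(scenario)
    return Path(*parts) / f"synthetic_pop_{year}{suffix}.csv"
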