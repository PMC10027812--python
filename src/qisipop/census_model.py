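"""Domain types, category unification and the geographic hierarchy.

The synthetic population describes individuals by seven census attributes
(age group, sex, highest degree, labour force status, household size,
total income band, primary-maintainer flag) plus identifiers, an exact age,
a small-area code and a household type.  Microdata releases and aggregate
profiles use different category systems; :class:`CategoryMap` holds the
correspondence and is loaded from a versioned YAML configuration so a new
census vintage can be swapped in without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SYNTHESIS_VARIABLES",
    "CATEGORY_SIZES",
    "SEED_AXES",
    "OUTPUT_COLUMNS",
    "AGE_BANDS",
    "HHTYPE_UNSET",
    "UnifiedIndividual",
    "CategoryMap",
    "GeoHierarchy",
    "CategoryMappingError",
    "AreaFormatError",
    "parse_area_code",
    "format_area_code",
    "age_band",
    "validate_population_frame",
]

#: the seven attributes the synthesizer controls, in seed-axis order
SEED_AXES: tuple[str, ...] = (
    "agegrp", "sex", "hdgree", "lfact", "hhsize", "totinc", "prihm",
)
SYNTHESIS_VARIABLES = SEED_AXES

#: number of unified categories per attribute
CATEGORY_SIZES: dict[str, int] = {
    "agegrp": 18,
    "sex": 2,
    "hdgree": 3,
    "lfact": 3,
    "hhsize": 5,
    "totinc": 4,
    "prihm": 2,
}

#: column order of the population file
OUTPUT_COLUMNS: tuple[str, ...] = (
    "index", "HID", "sex", "prihm", "agegrp", "age", "area",
    "hdgree", "lfact", "hhsize", "totinc", "hhtype",
)

#: unified age group -> inclusive integer age range
AGE_BANDS: dict[int, tuple[int, int]] = {
    g: (5 * g, 5 * g + 4) for g in range(17)
}
AGE_BANDS[17] = (85, 120)

HHTYPE_UNSET = -1
AGE_UNSET = -1
HID_UNSET = -1


class CategoryMappingError(ValueError):
    """A microdata code has no unified category."""


class AreaFormatError(ValueError):
    """A small-area code is not an 8-digit string."""


def parse_area_code(code: str | int) -> tuple[str, str, str]:
    """Split an 8-digit area code into (province, division, area) parts.

    The code concatenates a 2-digit province, a 2-digit census division and
    a 4-digit area identifier; the concatenation of the returned parts
    reproduces the input.
    """
    s = str(code)
    if len(s) != 8 or not s.isdigit():
        raise AreaFormatError(f"area code must be exactly 8 digits, got {s!r}")
    return s[:2], s[2:4], s[4:]


def format_area_code(province: str, division: str, area: str) -> str:
    """Inverse of :func:`parse_area_code`."""
    code = f"{province}{division}{area}"
    if len(code) != 8 or not code.isdigit():
        raise AreaFormatError(f"parts do not form an 8-digit code: {code!r}")
    return code


def age_band(agegrp: int) -> tuple[int, int]:
    """Inclusive age range implied by a unified age group code."""
    try:
        return AGE_BANDS[int(agegrp)]
    except KeyError:
        raise ValueError(f"unknown age group code {agegrp}") from None


@dataclass
class UnifiedIndividual:
    """One synthetic person with the twelve output attributes.

    ``HID``, ``age`` and ``hhtype`` start at their unset sentinels (−1) and
    are filled by the household-assignment steps.
    """

    index: int
    sex: int
    prihm: int
    agegrp: int
    area: str
    hdgree: int
    lfact: int
    hhsize: int
    totinc: int
    HID: int = HID_UNSET
    age: int = AGE_UNSET
    hhtype: int = HHTYPE_UNSET

    def validate(self) -> None:
        for var in SEED_AXES:
            v = getattr(self, var)
            if not 0 <= v < CATEGORY_SIZES[var]:
                raise ValueError(f"{var}={v} outside unified range")
        parse_area_code(self.area)
        if self.age != AGE_UNSET:
            lo, hi = age_band(self.agegrp)
            if not lo <= self.age <= hi:
                raise ValueError(
                    f"age {self.age} outside band [{lo},{hi}] of agegrp {self.agegrp}"
                )
        if self.hhtype != HHTYPE_UNSET and not 0 <= self.hhtype <= 4:
            raise ValueError(f"hhtype={self.hhtype} outside 0..4")

    def as_row(self) -> tuple:
        return tuple(getattr(self, c) for c in OUTPUT_COLUMNS)


def validate_population_frame(df: pd.DataFrame) -> None:
    """Vectorised invariant check for a population table.

    Raises ``ValueError`` naming the first violated invariant.  ``age``/
    ``HID``/``hhtype`` equal to −1 are treated as unset and pass.
    """
    missing = [c for c in OUTPUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"population table missing columns {missing}")
    for var in SEED_AXES:
        v = df[var].to_numpy()
        if ((v < 0) | (v >= CATEGORY_SIZES[var])).any():
            raise ValueError(f"column {var} has codes outside unified range")
    areas = df["area"].astype(str)
    if not areas.str.fullmatch(r"\d{8}").all():
        raise ValueError("column area has non 8-digit codes")
    age = df["age"].to_numpy()
    set_age = age != AGE_UNSET
    if set_age.any():
        g = df["agegrp"].to_numpy()[set_age]
        a = age[set_age]
        lo = np.where(g < 17, 5 * g, 85)
        hi = np.where(g < 17, 5 * g + 4, 120)
        if ((a < lo) | (a > hi)).any():
            raise ValueError("age outside the band implied by agegrp")
    ht = df["hhtype"].to_numpy()
    if ((ht != HHTYPE_UNSET) & ((ht < 0) | (ht > 4))).any():
        raise ValueError("hhtype outside 0..4")
    if df["index"].duplicated().any():
        raise ValueError("index values are not unique")


class CategoryMap:
    """Correspondence between microdata codes, unified codes and profile labels.

    Parameters
    ----------
    config:
        Parsed YAML mapping (see ``data/categories_2016.yaml``).  When
        omitted the packaged 2016 configuration is used.
    """

    def __init__(self, config: Mapping | None = None):
        if config is None:
            text = (
                resources.files("qisipop.data")
                .joinpath("categories_2016.yaml")
                .read_text()
            )
            config = yaml.safe_load(text)
        self.version: str = str(config.get("version", "unversioned"))
        self._vars: dict[str, dict] = {
            k: dict(v) for k, v in config["variables"].items()
        }
        self._check_config()

    def _check_config(self) -> None:
        for var, spec in self._vars.items():
            labels = spec.get("profile_labels") or {}
            seen: set[str] = set()
            for lab_list in labels.values():
                for lab in lab_list:
                    if lab in seen:
                        raise ValueError(
                            f"profile label {lab!r} repeated within {var}"
                        )
                    seen.add(lab)
            if var == "totinc":
                continue
            n = CATEGORY_SIZES[var]
            bad = {
                c: u for c, u in spec["source_to_unified"].items()
                if not 0 <= u < n
            }
            if bad:
                raise ValueError(f"{var}: unified codes out of range: {bad}")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self._vars)

    def unify_code(self, variable: str, source_code: int) -> int:
        """Map one microdata source code to its unified category code.

        Raises :class:`CategoryMappingError` for an unknown code — unknown
        codes are never silently dropped.
        """
        if variable not in self._vars:
            raise CategoryMappingError(f"unknown variable {variable!r}")
        spec = self._vars[variable]
        code = int(source_code)
        if code in spec.get("ignored_source_codes", ()):
            raise CategoryMappingError(
                f"{variable} source code {code} is marked ignored; "
                "drop the record explicitly"
            )
        table = spec.get("source_to_unified")
        if table is None:
            raise CategoryMappingError(
                f"{variable} is value-banded, use band_income"
            )
        try:
            return table[code]
        except KeyError:
            raise CategoryMappingError(
                f"no unified category for {variable} source code {code}"
            ) from None

    def is_ignored(self, variable: str, source_code: int) -> bool:
        spec = self._vars.get(variable, {})
        return int(source_code) in spec.get("ignored_source_codes", ())

    def band_income(self, amount: float | int) -> int:
        """Band a dollar income amount into the unified income categories.

        Sentinel codes (not available / not applicable, i.e. under-15s) map
        to band 0, as do negative amounts (income "including loss").  Bands
        are left-closed: [20 000, 60 000) is band 1, etc.
        """
        spec = self._vars["totinc"]
        a = float(amount)
        if int(a) in spec.get("sentinel_codes", ()):
            return 0
        edges = spec["band_edges"]
        return int(np.searchsorted(np.asarray(edges, dtype=float), a, side="right"))

    def profile_labels(self, variable: str) -> dict[int, list[str]]:
        """Unified category -> list of profile characteristic labels summed into it."""
        return {
            int(k): list(v)
            for k, v in (self._vars[variable].get("profile_labels") or {}).items()
        }

    def under15_category(self, variable: str) -> int | None:
        """Category receiving the 0–14 population for 15+-only profile variables."""
        v = self._vars[variable].get("under15_to")
        return None if v is None else int(v)

    def source_codes(self, variable: str) -> list[int]:
        return sorted(self._vars[variable].get("source_to_unified", {}))


@dataclass
class GeoHierarchy:
    """Block → (area, subdivision, province) lookup table.

    Area codes are 8-digit strings whose first two digits equal the
    province code.
    """

    table: pd.DataFrame  # columns DBuid, DAuid, PRuid, PRename, CSDuid, CSDname

    REQUIRED = ("DBuid", "DAuid", "PRuid", "PRename", "CSDuid", "CSDname")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"geography table missing columns {missing}")
        t = self.table.copy()
        for col in ("DBuid", "DAuid", "PRuid", "CSDuid"):
            t[col] = t[col].astype(str)
        self.table = t
        per_area = t.drop_duplicates("DBuid").groupby("DAuid")[["CSDuid", "PRuid"]].nunique()
        multi = per_area[(per_area > 1).any(axis=1)]
        if len(multi):
            raise ValueError(
                f"areas mapped to multiple subdivisions/provinces: {list(multi.index)}"
            )
        bad_prefix = t[t["DAuid"].str[:2] != t["PRuid"].str[:2]]
        if len(bad_prefix):
            raise ValueError("area codes whose prefix is not the province code")

    @property
    def areas(self) -> pd.DataFrame:
        """One row per area with its subdivision and province codes."""
        return (
            self.table.drop_duplicates("DAuid")[
                ["DAuid", "CSDuid", "PRuid", "PRename", "CSDname"]
            ].reset_index(drop=True)
        )

    def areas_of_province(self, province: str) -> list[str]:
        a = self.areas
        return sorted(a.loc[a["PRuid"] == str(province), "DAuid"])

    def province_of_area(self, area: str) -> str:
        return parse_area_code(area)[0]

    def subdivision_of_area(self, area: str) -> str:
        a = self.areas
        hit = a.loc[a["DAuid"] == str(area), "CSDuid"]
        if hit.empty:
            raise KeyError(f"unknown area {area}")
        return hit.iloc[0]

    def provinces(self) -> list[str]:
        return sorted(self.table["PRuid"].unique())
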