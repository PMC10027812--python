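"""Generated census-like test world: ground truth plus the five input files.

:func:`gen_world` builds a complete fictitious population — households with
exactly one maintainer each, grouped into small areas of roughly 400–700
persons, with income, education and labour status depending on age — and
:func:`emit_inputs` degrades it exactly the way a confidentiality-protected
census release would:

* a ~2.7 % simple random sample of individuals (weights = 1/fraction),
* a ~1 % sample of whole households,
* per-area aggregate counts randomly rounded to multiples of 5, with areas
  under 40 persons suppressed entirely,
* the geographic hierarchy, and
* projected counts per scenario/year derived from stated per-cell annual
  growth multipliers.

Because the ground truth is retained, every pipeline stage can be checked
against the exact joint distribution it is trying to recover.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .census_io import SCENARIOS
from .census_model import CATEGORY_SIZES, CategoryMap, GeoHierarchy

__all__ = ["WorldConfig", "TrueWorld", "gen_world", "emit_inputs"]


def _default_scenario_rates() -> dict[str, tuple[float, float]]:
    """Per-scenario (annual growth rate, aging tilt).

    The tilt shifts growth towards older (positive) or younger (negative)
    age groups so fast-/slow-aging scenario shapes can be emulated.
    """
    return {
        "LG": (0.004, 0.0),
        "HG": (0.018, 0.0),
        "M1": (0.010, 0.0),
        "M2": (0.011, 0.0),
        "M3": (0.012, 0.0),
        "M4": (0.013, 0.0),
        "M5": (0.014, 0.0),
        "FA": (0.010, 0.008),
        "SA": (0.010, -0.008),
    }


@dataclass
class WorldConfig:
    """Study conditions for the generated world."""

    seed: int = 0
    n_provinces: int = 1
    n_subdivisions: int = 2          # per province
    n_areas: int = 10                # per province
    mean_area_population: int = 500  # small areas average 400-700 persons
    individual_fraction: float = 0.027
    household_fraction: float = 0.01
    rounding_base: int = 5
    suppression_threshold: int = 40
    projection_years: tuple[int, ...] = (2021, 2023, 2030)
    scenario_rates: dict = field(default_factory=_default_scenario_rates)
    # household size category probabilities (1,2,3,4,5+ persons)
    hhsize_dist: tuple[float, ...] = (0.28, 0.34, 0.15, 0.14, 0.09)
    # actual person counts within the 5+ category
    big_sizes: tuple[int, ...] = (5, 6, 7)
    big_size_dist: tuple[float, ...] = (0.7, 0.2, 0.1)
    couple_prob: float = 0.8         # 2nd member is a same-age partner
    child_prob: float = 0.85         # members 3+ are children vs other adults

    def __post_init__(self) -> None:
        if self.n_areas <= 0 or self.n_provinces <= 0 or self.n_subdivisions <= 0:
            raise ValueError("counts of provinces/subdivisions/areas must be positive")
        if not 0 < self.individual_fraction <= 1:
            raise ValueError("individual_fraction must be in (0, 1]")
        if not 0 < self.household_fraction <= 1:
            raise ValueError("household_fraction must be in (0, 1]")
        if abs(sum(self.hhsize_dist) - 1) > 1e-9:
            raise ValueError("hhsize_dist must normalise")
        for rates in self.scenario_rates.values():
            if 1 + rates[0] + abs(rates[1]) <= 0:
                raise ValueError("growth multipliers must stay positive")


# age-dependent attribute laws (unified categories); rows index coarse age
# classes: 0-14, 15-19, 20-24, 25-64, 65+
_HDGREE_BY_AGE = np.array([
    [1.00, 0.00, 0.00],
    [0.70, 0.28, 0.02],
    [0.20, 0.40, 0.40],
    [0.15, 0.30, 0.55],
    [0.25, 0.35, 0.40],
])
_LFACT_BY_AGE = np.array([
    [0.00, 0.00, 1.00],
    [0.30, 0.10, 0.60],
    [0.65, 0.10, 0.25],
    [0.72, 0.06, 0.22],
    [0.10, 0.01, 0.89],
])
_TOTINC_BY_AGE = np.array([
    [1.00, 0.00, 0.00, 0.00],
    [0.90, 0.09, 0.008, 0.002],
    [0.65, 0.30, 0.04, 0.01],
    [0.25, 0.40, 0.22, 0.13],
    [0.35, 0.45, 0.15, 0.05],
])
# maintainer age-group distribution (adults only)
_MAINTAINER_AGE = np.zeros(18)
_MAINTAINER_AGE[4:18] = [0.04, 0.08, 0.10, 0.10, 0.10, 0.10, 0.10, 0.09,
                         0.08, 0.07, 0.05, 0.04, 0.03, 0.02]
_CHILD_AGE = np.array([0.28, 0.28, 0.28, 0.16])     # age groups 0-3
_OTHER_ADULT_AGE = np.zeros(18)
_OTHER_ADULT_AGE[4:] = [0.18, 0.12, 0.09, 0.08, 0.08, 0.08, 0.08, 0.07,
                        0.06, 0.05, 0.04, 0.03, 0.02, 0.02]


def _age_class(agegrp: int) -> int:
    if agegrp <= 2:
        return 0
    if agegrp == 3:
        return 1
    if agegrp == 4:
        return 2
    if agegrp <= 12:
        return 3
    return 4


@dataclass
class TrueWorld:
    """The complete ground-truth population and its geography."""

    config: WorldConfig
    geo: GeoHierarchy
    individuals: pd.DataFrame  # person_id, hh_id, area + 7 unified attributes
    households: pd.DataFrame   # hh_id, area, size_cat, n_members

    def joint_distribution(self, province: str | None = None) -> np.ndarray:
        """Empirical 7-way joint distribution of the ground truth."""
        from .census_model import SEED_AXES

        df = self.individuals
        if province is not None:
            df = df[df["area"].str[:2] == str(province)]
        table = np.zeros(tuple(CATEGORY_SIZES[v] for v in SEED_AXES))
        np.add.at(table, tuple(df[v].to_numpy() for v in SEED_AXES), 1.0)
        return table / table.sum()

    def area_counts(self) -> pd.DataFrame:
        """Exact (unrounded) per-area counts in the profile dialect."""
        return _profile_rows(self.individuals, self.households)

    def province_sex_age_counts(self, province: str) -> np.ndarray:
        df = self.individuals
        df = df[df["area"].str[:2] == str(province)]
        out = np.zeros((2, CATEGORY_SIZES["agegrp"]))
        np.add.at(out, (df["sex"].to_numpy(), df["agegrp"].to_numpy()), 1.0)
        return out


def _draw(rng: np.random.Generator, probs: np.ndarray) -> int:
    return int(rng.choice(len(probs), p=np.asarray(probs) / np.sum(probs)))


def gen_world(config: WorldConfig) -> TrueWorld:
    """Generate the ground-truth world; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    people: list[tuple] = []
    hh_rows: list[tuple] = []
    geo_rows: list[tuple] = []
    person_id = 0
    hh_id = 0
    for p in range(config.n_provinces):
        prov = f"{10 + p:02d}"
        for a in range(config.n_areas):
            division = f"{(a % config.n_subdivisions) + 1:02d}"
            area = f"{prov}{division}{a + 1:04d}"
            csd = f"{prov}{division}001"
            geo_rows.append(
                (f"{area}001", area, prov, f"Province {prov}", csd,
                 f"Subdivision {csd}")
            )
            geo_rows.append((f"{area}002", area, prov, f"Province {prov}",
                             csd, f"Subdivision {csd}"))
            target = int(rng.uniform(0.6, 1.4) * config.mean_area_population)
            pop = 0
            while pop < target:
                size_cat = _draw(rng, np.asarray(config.hhsize_dist))
                size = (
                    size_cat + 1 if size_cat < 4
                    else int(rng.choice(config.big_sizes, p=config.big_size_dist))
                )
                members = _gen_household(rng, config, size)
                for (agegrp, sex) in members[:1]:
                    people.append((person_id, hh_id, area, agegrp, sex, 1,
                                   min(size - 1, 4)))
                    person_id += 1
                for (agegrp, sex) in members[1:]:
                    people.append((person_id, hh_id, area, agegrp, sex, 0,
                                   min(size - 1, 4)))
                    person_id += 1
                hh_rows.append((hh_id, area, min(size - 1, 4), size))
                hh_id += 1
                pop += size
    df = pd.DataFrame(
        people,
        columns=["person_id", "hh_id", "area", "agegrp", "sex", "prihm", "hhsize"],
    )
    # age-dependent attributes
    cls = df["agegrp"].map(_age_class).to_numpy()
    n = len(df)
    u = rng.random((n, 3))
    df["hdgree"] = (u[:, 0:1] > np.cumsum(_HDGREE_BY_AGE, axis=1)[cls]).sum(axis=1)
    df["lfact"] = (u[:, 1:2] > np.cumsum(_LFACT_BY_AGE, axis=1)[cls]).sum(axis=1)
    df["totinc"] = (u[:, 2:3] > np.cumsum(_TOTINC_BY_AGE, axis=1)[cls]).sum(axis=1)
    geo = GeoHierarchy(
        pd.DataFrame(
            geo_rows,
            columns=["DBuid", "DAuid", "PRuid", "PRename", "CSDuid", "CSDname"],
        )
    )
    households = pd.DataFrame(
        hh_rows, columns=["hh_id", "area", "size_cat", "n_members"]
    )
    return TrueWorld(config=config, geo=geo, individuals=df, households=households)


def _gen_household(
    rng: np.random.Generator, config: WorldConfig, size: int
) -> list[tuple[int, int]]:
    """(agegrp, sex) for each member; the maintainer comes first."""
    m_age = _draw(rng, _MAINTAINER_AGE)
    m_sex = int(rng.random() < 0.5)
    members = [(m_age, m_sex)]
    if size >= 2:
        if rng.random() < config.couple_prob:
            p_age = int(np.clip(m_age + rng.integers(-1, 2), 4, 17))
            p_sex = 1 - m_sex if rng.random() < 0.95 else m_sex
            members.append((p_age, p_sex))
        else:
            members.append(_child_or_adult(rng, config, force_child=True))
    for _ in range(size - 2):
        members.append(_child_or_adult(rng, config))
    return members


def _child_or_adult(
    rng: np.random.Generator, config: WorldConfig, force_child: bool = False
) -> tuple[int, int]:
    if force_child or rng.random() < config.child_prob:
        return _draw(rng, _CHILD_AGE), int(rng.random() < 0.5)
    return _draw(rng, _OTHER_ADULT_AGE), int(rng.random() < 0.5)


# ---------------------------------------------------------------------------
# emission


# reverse maps: unified category -> representative microdata source code
def _reverse_map(cmap: CategoryMap, variable: str) -> dict[int, int]:
    out: dict[int, int] = {}
    for src in cmap.source_codes(variable):
        uni = cmap.unify_code(variable, src)
        out.setdefault(uni, src)
    return out


_INCOME_RANGES = {0: (0, 19_999), 1: (20_000, 59_999), 2: (60_000, 99_999),
                  3: (100_000, 200_000)}

_AGE_LABELS = [f"{5 * g} to {5 * g + 4} years" for g in range(17)] + [
    "85 years and over"
]
_HHSIZE_LABELS = ["1 person", "2 persons", "3 persons", "4 persons",
                  "5 or more persons"]
_INCOME_LABELS = {0: "Under $10,000 (including loss)",
                  1: "$20,000 to $29,999",
                  2: "$60,000 to $69,999",
                  3: "$100,000 and over"}
_HDGREE_LABELS = {0: "No certificate, diploma or degree",
                  1: "Secondary (high) school diploma or equivalency certificate",
                  2: "Postsecondary certificate, diploma or degree"}
_LFACT_LABELS = {0: "Employed", 1: "Unemployed", 2: "Not in the labour force"}

# how the 85+ cohort splits into the projection file's 5-year bands
_OPEN_BAND_SPLIT = {"85 to 89 years": 0.60, "90 to 94 years": 0.25,
                    "95 to 99 years": 0.12, "100 years and over": 0.03}


def _profile_rows(
    individuals: pd.DataFrame, households: pd.DataFrame
) -> pd.DataFrame:
    """Exact per-area counts in the profile dialect (before rounding)."""
    rows: list[tuple] = []
    hh_by_area = households.groupby("area")
    for area, g in individuals.groupby("area"):
        female = g["sex"].to_numpy() == 0
        rows.append((area, "Population, 2016", len(g),
                     int((~female).sum()), int(female.sum())))
        n_hh = len(hh_by_area.get_group(area)) if area in hh_by_area.groups else 0
        rows.append((area, "Private dwellings occupied by usual residents",
                     n_hh, None, None))
        for grp in range(CATEGORY_SIZES["agegrp"]):
            in_band = g["agegrp"].to_numpy() == grp
            rows.append((area, _AGE_LABELS[grp], int(in_band.sum()),
                         int((in_band & ~female).sum()),
                         int((in_band & female).sum())))
        if area in hh_by_area.groups:
            sizes = hh_by_area.get_group(area)["size_cat"].to_numpy()
            for c in range(5):
                rows.append((area, _HHSIZE_LABELS[c], int((sizes == c).sum()),
                             None, None))
        adults = g[g["agegrp"] >= 3]
        for c, lab in _INCOME_LABELS.items():
            rows.append((area, lab, int((adults["totinc"] == c).sum()), None, None))
        for c, lab in _HDGREE_LABELS.items():
            rows.append((area, lab, int((adults["hdgree"] == c).sum()), None, None))
        for c, lab in _LFACT_LABELS.items():
            rows.append((area, lab, int((adults["lfact"] == c).sum()), None, None))
    return pd.DataFrame(
        rows, columns=["area", "characteristic", "total", "male", "female"]
    )


def _random_round(
    values: pd.Series, base: int, rng: np.random.Generator
) -> pd.Series:
    """Round counts to an adjacent multiple of ``base``, 50/50 up or down.

    Multiples of ``base`` are unchanged, so rounding is unbiased.
    """

    def one(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return v
        v = int(v)
        r = v % base
        if r == 0:
            return v
        return v - r + (base if rng.random() < 0.5 else 0)

    return values.map(one)


def emit_inputs(
    world: TrueWorld, config: WorldConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Write the five input files (plus truth and manifest); returns paths.

    The emission RNG is seeded from ``config.seed`` so the same world and
    config always produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    cmap = CategoryMap()
    paths: dict[str, Path] = {}

    # --- individual microdata (simple random sample, uniform weights)
    ind = world.individuals
    picked = ind[rng.random(len(ind)) < config.individual_fraction].copy()
    paths["individual"] = out / "individual_microdata.csv"
    _write_individual_sample(picked, config, cmap, rng, paths["individual"])

    # --- hierarchical microdata (whole-household sample)
    hh_ids = world.households["hh_id"].to_numpy()
    chosen = set(hh_ids[rng.random(len(hh_ids)) < config.household_fraction])
    hier = ind[ind["hh_id"].isin(chosen)]
    rev_age = _reverse_map(cmap, "agegrp")
    hier_out = pd.DataFrame(
        {
            "hh_id": hier["hh_id"].to_numpy(),
            "person_id": hier["person_id"].to_numpy(),
            "weight": 1.0 / config.household_fraction,
            "agegrp": hier["agegrp"].map(rev_age).to_numpy(),
            "province": hier["area"].str[:2].to_numpy(),
            "prihm": hier["prihm"].to_numpy(),
            "sex": hier["sex"].map({0: 1, 1: 2}).to_numpy(),
        }
    )
    paths["hierarchical"] = out / "hierarchical_microdata.csv"
    hier_out.to_csv(paths["hierarchical"], index=False)

    # --- profile: exact counts, then suppression and random rounding
    truth = _profile_rows(world.individuals, world.households)
    paths["truth_profile"] = out / "truth_profile.csv"
    truth.to_csv(paths["truth_profile"], index=False)
    pop_by_area = world.individuals.groupby("area").size()
    visible = pop_by_area[pop_by_area >= config.suppression_threshold].index
    profile = truth[truth["area"].isin(visible)].copy()
    for c in ("total", "male", "female"):
        profile[c] = _random_round(profile[c], config.rounding_base, rng)
    paths["profile"] = out / "profile.csv"
    profile.to_csv(paths["profile"], index=False)

    # --- geography
    paths["geography"] = out / "geography.csv"
    world.geo.table.to_csv(paths["geography"], index=False)

    # --- projections: true province counts x cumulative growth multipliers
    proj_rows: list[tuple] = []
    for prov in world.geo.provinces():
        base = world.province_sex_age_counts(prov)  # (2, 18) female row 0
        for scen in SCENARIOS:
            rate, tilt = config.scenario_rates[scen]
            g_idx = np.arange(CATEGORY_SIZES["agegrp"])
            annual = 1 + rate + tilt * (g_idx - 8.5) / 8.5
            for year in config.projection_years:
                mult = annual ** (year - 2016)
                target = base * mult[None, :]
                for s, sex_lab in ((0, "Females"), (1, "Males")):
                    for g in range(17):
                        proj_rows.append(
                            (year, prov, scen, sex_lab,
                             f"{5 * g} to {5 * g + 4} years",
                             int(round(target[s, g])))
                        )
                    open_count = target[s, 17]
                    for lab, frac in _OPEN_BAND_SPLIT.items():
                        proj_rows.append(
                            (year, prov, scen, sex_lab, lab,
                             int(round(open_count * frac)))
                        )
    paths["projections"] = out / "projections.csv"
    pd.DataFrame(
        proj_rows,
        columns=["year", "province", "scenario", "sex", "age_group", "value"],
    ).to_csv(paths["projections"], index=False)

    manifest = {
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
            if not isinstance(v, dict)
        },
        "scenario_rates": {k: list(v) for k, v in config.scenario_rates.items()},
        "files": {k: str(v.name) for k, v in paths.items()},
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths


def _write_individual_sample(
    picked: pd.DataFrame,
    config: WorldConfig,
    cmap: CategoryMap,
    rng: np.random.Generator,
    path: Path,
) -> None:
    rev = {v: _reverse_map(cmap, v) for v in ("agegrp", "hdgree", "hhsize", "lfact")}
    under15 = picked["agegrp"].to_numpy() <= 2
    amounts = np.empty(len(picked), dtype=np.int64)
    for band, (lo, hi) in _INCOME_RANGES.items():
        in_band = picked["totinc"].to_numpy() == band
        amounts[in_band] = rng.integers(lo, hi + 1, size=int(in_band.sum()))
    amounts[under15] = 99_999_999
    hdgree_src = picked["hdgree"].map(rev["hdgree"]).to_numpy()
    hdgree_src[under15] = 99
    lfact_src = picked["lfact"].map(rev["lfact"]).to_numpy()
    lfact_src[under15] = 99
    pd.DataFrame(
        {
            "id": picked["person_id"].to_numpy(),
            "weight": 1.0 / config.individual_fraction,
            "agegrp": picked["agegrp"].map(rev["agegrp"]).to_numpy(),
            "hdgree": hdgree_src,
            "hhsize": picked["hhsize"].map(rev["hhsize"]).to_numpy(),
            "lfact": lfact_src,
            "province": picked["area"].str[:2].to_numpy(),
            "prihm": picked["prihm"].to_numpy(),
            "sex": picked["sex"].map({0: 1, 1: 2}).to_numpy(),
            "totinc": amounts,
        }
    ).to_csv(path, index=False)
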