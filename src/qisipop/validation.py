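"""Validation metrics and multi-level comparison reports.

Synthetic counts are compared with observed counts per geographic unit
using three standard measures: Pearson's product-moment correlation *r*,
the range-normalised root mean square error (NRMSE = RMSE / (max(obs) −
min(obs))) and the per-unit relative absolute error (RAE_i = |obs_i −
sim_i| / obs_i, summarised by its five-number summary).  A realism check
reports the share of synthetic individuals whose seven-attribute
combination occurs in the source microdata, and an analytic model gives
the error expected from confidentiality rounding of published counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .census_io import DWELLINGS_LABEL, POPULATION_LABEL
from .census_model import (
    CATEGORY_SIZES,
    SEED_AXES,
    CategoryMap,
    GeoHierarchy,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonSeries",
    "UndefinedMetric",
    "pearson_r",
    "nrmse",
    "rae",
    "rae_summary",
    "realism_fraction",
    "rounding_error_model",
    "population_to_profile",
    "compare_populations",
    "HHTYPE_LABELS",
]

LEVELS = ("area", "subdivision", "province", "national")

HHTYPE_LABELS = {
    0: "Couples without children",
    1: "Couples with children",
    2: "One-parent-family",
    3: "One-person",
    4: "Other kind of household",
}

AGE_LABELS = [f"{5 * g} to {5 * g + 4} years" for g in range(17)] + [
    "85 years and over"
]
HHSIZE_LABELS = ["1 person", "2 persons", "3 persons", "4 persons",
                 "5 or more persons"]


class UndefinedMetric(float):
    """NaN carrying the reason a metric is undefined."""

    def __new__(cls, reason: str):
        obj = super().__new__(cls, float("nan"))
        obj.reason = reason
        return obj


@dataclass
class ComparisonSeries:
    """Observed and synthetic counts for one category across units."""

    label: str
    obs: np.ndarray
    sim: np.ndarray

    def __post_init__(self) -> None:
        self.obs = np.asarray(self.obs, dtype=float)
        self.sim = np.asarray(self.sim, dtype=float)
        if self.obs.shape != self.sim.shape or self.obs.ndim != 1:
            raise ValueError("obs and sim must be 1-D arrays of equal length")

    @property
    def n(self) -> int:
        return len(self.obs)


def pearson_r(series: ComparisonSeries) -> float:
    """Product-moment correlation between observed and synthetic counts.

    Undefined (NaN with a reason) for fewer than two units or a constant
    vector.
    """
    if series.n < 2:
        return UndefinedMetric("fewer than two units")
    if np.ptp(series.obs) == 0 or np.ptp(series.sim) == 0:
        return UndefinedMetric("constant vector")
    if np.array_equal(series.obs, series.sim):
        return 1.0  # exact fixed point, free of float round-off
    return float(stats.pearsonr(series.obs, series.sim).statistic)


def nrmse(series: ComparisonSeries) -> float:
    """Root mean square error normalised by the observed range."""
    if series.n < 2:
        return UndefinedMetric("fewer than two units")
    rng = float(series.obs.max() - series.obs.min())
    if rng == 0:
        return UndefinedMetric("zero observed range")
    return float(np.sqrt(np.mean((series.obs - series.sim) ** 2)) / rng)


def rae(series: ComparisonSeries) -> tuple[np.ndarray, int]:
    """Per-unit relative absolute errors.

    Units with a zero observed count are undefined and excluded; the
    second return value is the number excluded (reported, never silent).
    """
    defined = series.obs != 0
    n_excluded = int((~defined).sum())
    if n_excluded:
        logger.info(
            "%s: %d units with zero observed count excluded from RAE",
            series.label, n_excluded,
        )
    vals = np.abs(series.obs[defined] - series.sim[defined]) / series.obs[defined]
    return vals, n_excluded


def rae_summary(series: ComparisonSeries) -> dict[str, float]:
    """Five-number summary of the RAE (median-unbiased quantiles)."""
    vals, n_excluded = rae(series)
    if len(vals) == 0:
        nan = float("nan")
        return {"min": nan, "q1": nan, "median": nan, "q3": nan, "max": nan,
                "n_excluded": n_excluded}
    q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75], method="median_unbiased")
    return {
        "min": float(vals.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(vals.max()),
        "n_excluded": n_excluded,
    }


def realism_fraction(
    population: pd.DataFrame, seed_records: pd.DataFrame
) -> float:
    """Share of synthetic individuals whose attribute set occurs in microdata.

    Comparison is on the seven synthesis attributes; duplicated individuals
    count independently (multiset semantics).
    """
    if len(population) == 0:
        raise ValueError("empty population")
    if len(seed_records) == 0:
        raise ValueError("empty microdata")
    cols = list(SEED_AXES)
    seen = set(map(tuple, seed_records[cols].to_numpy()))
    tuples = map(tuple, population[cols].to_numpy())
    hits = sum(t in seen for t in tuples)
    return hits / len(population)


def rounding_error_model(
    true_count: float, exact: bool = False
) -> tuple[float, float]:
    """Expected error from 50/50 rounding to adjacent multiples of 5.

    A count with any non-zero residue has expected absolute error
    0.5·r + 0.5·(5−r) = 2.5, so the generic expectation for a published
    count of this magnitude is 2.5 absolute and 2.5/count relative
    (e.g. 0.25 % at 1000, 25 % at 10).  With ``exact=True`` the count's own
    residue is used instead, so multiples of 5 — which rounding leaves
    unchanged — return zero error.
    """
    if true_count <= 0:
        raise ValueError("true_count must be positive")
    if exact and true_count % 5 == 0:
        return 0.0, 0.0
    return 2.5, 2.5 / true_count


# ---------------------------------------------------------------------------
# report


def population_to_profile(population: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a population frame into the profile dialect.

    Produces per-area rows for population (with sex columns), households,
    age (with sex columns), household size, income / degree / labour status
    (ages 15+ only, mirroring the published convention) and — when the
    population has assigned types — households by type.
    """
    cmap = CategoryMap()
    rows: list[tuple] = []
    for area, g in population.groupby("area"):
        male = g["sex"].to_numpy() == 1
        rows.append((area, POPULATION_LABEL, len(g), int(male.sum()),
                     int((~male).sum())))
        maint = g[g["prihm"] == 1]
        rows.append((area, DWELLINGS_LABEL, len(maint), None, None))
        for grp in range(CATEGORY_SIZES["agegrp"]):
            in_band = g["agegrp"].to_numpy() == grp
            rows.append((area, AGE_LABELS[grp], int(in_band.sum()),
                         int((in_band & male).sum()),
                         int((in_band & ~male).sum())))
        for c in range(5):
            rows.append((area, HHSIZE_LABELS[c],
                         int((maint["hhsize"] == c).sum()), None, None))
        adults = g[g["agegrp"] >= 3]
        for var in ("totinc", "hdgree", "lfact"):
            for cat, labels in cmap.profile_labels(var).items():
                rows.append((area, labels[0],
                             int((adults[var] == cat).sum()), None, None))
        typed = maint[maint["hhtype"] >= 0]
        if len(typed):
            for c, lab in HHTYPE_LABELS.items():
                rows.append((area, lab, int((typed["hhtype"] == c).sum()),
                             None, None))
    return pd.DataFrame(
        rows, columns=["area", "characteristic", "total", "male", "female"]
    )


def _unit_of_area(areas: pd.Series, level: str, geo: GeoHierarchy | None) -> pd.Series:
    if level == "area":
        return areas
    if level == "province":
        return areas.str[:2]
    if level == "national":
        return pd.Series("all", index=areas.index)
    if level == "subdivision":
        if geo is None:
            raise ValueError("subdivision level needs a GeoHierarchy")
        lut = geo.areas.set_index("DAuid")["CSDuid"]
        return areas.map(lut)
    raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")


def _category_table(profile: pd.DataFrame) -> pd.DataFrame:
    """Long table (area, category, count) from a profile-dialect frame.

    Sex categories are derived from the male/female columns of the
    population row; income categories sum their constituent labels.
    """
    cmap = CategoryMap()
    out: list[tuple] = []
    pop = profile[profile["characteristic"] == POPULATION_LABEL]
    for _, r in pop.iterrows():
        out.append((r["area"], "Population", r["total"]))
        if not pd.isna(r["male"]):
            out.append((r["area"], "Males", r["male"]))
            out.append((r["area"], "Females", r["female"]))
    label_to_cat: dict[str, str] = {DWELLINGS_LABEL: "Households"}
    for lab in AGE_LABELS:
        label_to_cat[lab] = lab
    for lab in HHSIZE_LABELS:
        label_to_cat[lab] = lab
    for var, pretty in (("totinc", None), ("hdgree", None), ("lfact", None)):
        for cat, labels in cmap.profile_labels(var).items():
            for lab in labels:
                label_to_cat[lab] = f"{var}:{cat}"
    for lab in HHTYPE_LABELS.values():
        label_to_cat[lab] = lab
    rest = profile[profile["characteristic"].isin(label_to_cat)]
    for _, r in rest.iterrows():
        out.append((r["area"], label_to_cat[r["characteristic"]], r["total"]))
    df = pd.DataFrame(out, columns=["area", "category", "count"])
    df["count"] = df["count"].astype(float)
    return df.groupby(["area", "category"], as_index=False)["count"].sum()


def compare_populations(
    population: pd.DataFrame,
    profile: pd.DataFrame,
    level: str = "area",
    geo: GeoHierarchy | None = None,
) -> pd.DataFrame:
    """Compare a synthetic population with observed profile counts.

    Builds one :class:`ComparisonSeries` per category at the requested
    aggregation level and reports r, NRMSE, the RAE five-number summary and
    the aggregate relative error.  Categories absent from the observed
    profile are skipped.  Raises on geography mismatch (synthetic areas
    missing from the observed profile).
    """
    obs_long = _category_table(profile)
    sim_long = _category_table(population_to_profile(population))
    sim_areas = set(sim_long["area"])
    obs_areas = set(obs_long["area"])
    if not sim_areas <= obs_areas:
        raise ValueError(
            f"areas missing from observed profile: {sorted(sim_areas - obs_areas)}"
        )
    obs_long = obs_long[obs_long["area"].isin(sim_areas)].copy()
    obs_long["unit"] = _unit_of_area(obs_long["area"], level, geo)
    sim_long["unit"] = _unit_of_area(sim_long["area"], level, geo)
    obs_units = obs_long.groupby(["category", "unit"])["count"].sum()
    sim_units = sim_long.groupby(["category", "unit"])["count"].sum()
    rows = []
    for category in obs_units.index.get_level_values(0).unique():
        if category not in sim_units.index.get_level_values(0):
            continue
        o = obs_units.loc[category]
        s = sim_units.loc[category].reindex(o.index, fill_value=0.0)
        series = ComparisonSeries(category, o.to_numpy(), s.to_numpy())
        summary = rae_summary(series)
        obs_total = float(series.obs.sum())
        rel = (
            abs(obs_total - float(series.sim.sum())) / obs_total
            if obs_total else float("nan")
        )
        rows.append(
            {
                "category": category,
                "level": level,
                "n_units": series.n,
                "r": pearson_r(series),
                "nrmse": nrmse(series),
                "rae_min": summary["min"],
                "rae_q1": summary["q1"],
                "rae_median": summary["median"],
                "rae_q3": summary["q3"],
                "rae_max": summary["max"],
                "rae_excluded": summary["n_excluded"],
                "rel_error": rel,
            }
        )
    return pd.DataFrame(rows)


def render_report(report: pd.DataFrame) -> str:
    """Human-readable table mirroring the published layout."""
    lines = [
        f"{'Category':<42}{'r':>8}{'NRMSE %':>10}  RAE % min/q1/median/q3/max"
    ]
    for _, r in report.iterrows():
        rae_str = "/".join(
            f"{100 * r[k]:.2f}" if np.isfinite(r[k]) else "—"
            for k in ("rae_min", "rae_q1", "rae_median", "rae_q3", "rae_max")
        )
        r_str = f"{r['r']:.3f}" if np.isfinite(r["r"]) else "—"
        n_str = f"{100 * r['nrmse']:.3f}" if np.isfinite(r["nrmse"]) else "—"
        lines.append(f"{r['category']:<42}{r_str:>8}{n_str:>10}  {rae_str}")
    return "\n".join(lines)
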