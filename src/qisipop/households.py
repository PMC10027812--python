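"""Exact ages, household grouping and household-type inference.

Exact ages are drawn inside each individual's 5-year band (uniform), with a
truncated geometric tail for the open-ended 85+ band (success probability
0.2, capped at 120) reflecting the rapid decline of that cohort.

Household assignment creates one household per primary maintainer, with
capacity given by the maintainer's household-size category, and fills it
with non-maintainers in three phases:

1. individuals whose own household-size attribute matches the household,
   young (drawn age < 19) first, weighted by the composition law estimated
   from the hierarchical microdata;
2. big households (5+) topped up with leftover big-household individuals;
3. remaining vacancies filled with any unassigned non-maintainer (big
   households relaxed to a configurable cap).

Individuals left over keep ``HID = -1``.  Household types (couple with /
without children, one-parent, one-person, other) are then inferred from
member counts and age gaps alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .census_model import CATEGORY_SIZES, HID_UNSET

logger = logging.getLogger(__name__)

__all__ = [
    "AgeDrawConfig",
    "MemberDistribution",
    "Household",
    "draw_age",
    "draw_ages",
    "estimate_member_distribution",
    "assign_households",
    "assign_household_types",
    "household_type",
]

#: drawn age below which an individual counts as "young" for phase-1 priority
YOUNG_AGE_CUT = 19

#: phase-1/2 member capacity per household-size category (index = category);
#: category 4 is "5 or more persons"
CATEGORY_CAPACITY = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class AgeDrawConfig:
    """Parameters of the exact-age draw."""

    geometric_p: float = 0.2    # success probability for the 85+ tail
    max_age: int = 120

    def __post_init__(self) -> None:
        if not 0 < self.geometric_p <= 1:
            raise ValueError("geometric_p must be in (0, 1]")


def draw_age(
    agegrp: int,
    rng: np.random.Generator,
    config: AgeDrawConfig = AgeDrawConfig(),
) -> int:
    """Draw one exact age inside an age band.

    Bands 0–16 are uniform over their 5-year range; band 17 is
    85 + Geometric(p) on {0, 1, 2, …}, truncated at ``max_age``.
    """
    return int(draw_ages(np.asarray([agegrp]), rng, config)[0])


def draw_ages(
    agegrps: np.ndarray,
    rng: np.random.Generator,
    config: AgeDrawConfig = AgeDrawConfig(),
) -> np.ndarray:
    """Vectorised :func:`draw_age`."""
    g = np.asarray(agegrps, dtype=np.int64)
    if ((g < 0) | (g >= CATEGORY_SIZES["agegrp"])).any():
        raise ValueError("age group codes outside 0..17")
    lo = np.where(g < 17, 5 * g, 85)
    hi = np.where(g < 17, 5 * g + 4, 85)
    ages = rng.integers(lo, hi + 1)
    open_band = g == 17
    if open_band.any():
        # numpy's geometric counts trials (>=1); shift to {0,1,...}
        tail = rng.geometric(config.geometric_p, size=int(open_band.sum())) - 1
        ages = ages.copy()
        ages[open_band] = np.minimum(85 + tail, config.max_age)
    return ages.astype(np.int64)


# ---------------------------------------------------------------------------
# composition law from the hierarchical microdata


@dataclass
class MemberDistribution:
    """Law of a non-maintainer's (age group, sex) given the maintainer.

    ``conditional[size_cat][(m_agegrp, m_sex)]`` is an (18, 2) probability
    array over the member's (age group, sex); ``by_size[size_cat]`` is the
    size-level fallback used for conditioning cells unseen in the sample.
    """

    conditional: dict = field(default_factory=dict)
    by_size: dict = field(default_factory=dict)

    def member_probs(self, size_cat: int, m_agegrp: int, m_sex: int) -> np.ndarray:
        probs = self.conditional.get(size_cat, {}).get((m_agegrp, m_sex))
        if probs is None:
            probs = self.by_size.get(size_cat)
        if probs is None:
            probs = np.full((CATEGORY_SIZES["agegrp"], 2),
                            1.0 / (CATEGORY_SIZES["agegrp"] * 2))
        return probs


def estimate_member_distribution(records: pd.DataFrame) -> MemberDistribution:
    """Estimate the member composition law from hierarchical records.

    ``records`` needs columns ``hh_id, weight, agegrp, sex, prihm`` with
    exactly one maintainer per household.  Frequencies are weighted by the
    non-maintainer's record weight; each conditional sums to one.  The
    household-size category is the household's person count, capped at
    category 4 (5+).
    """
    if len(records) == 0:
        raise ValueError("no hierarchical records")
    df = records.copy()
    sizes = df.groupby("hh_id")["prihm"].transform("size")
    df["size_cat"] = np.minimum(sizes - 1, 4).astype(np.int64)
    maint = df[df["prihm"] == 1].set_index("hh_id")
    if maint.index.duplicated().any() or maint.empty:
        raise ValueError("households must have exactly one maintainer")
    members = df[df["prihm"] == 0]
    members = members[members["hh_id"].isin(maint.index)]
    dist = MemberDistribution()
    if members.empty:
        return dist
    m_attrs = maint.loc[members["hh_id"], ["agegrp", "sex"]].to_numpy()
    tab = pd.DataFrame(
        {
            "size_cat": members["size_cat"].to_numpy(),
            "m_agegrp": m_attrs[:, 0],
            "m_sex": m_attrs[:, 1],
            "agegrp": members["agegrp"].to_numpy(),
            "sex": members["sex"].to_numpy(),
            "weight": members["weight"].to_numpy(),
        }
    )
    shape = (CATEGORY_SIZES["agegrp"], 2)
    for size_cat, g_size in tab.groupby("size_cat"):
        acc = np.zeros(shape)
        np.add.at(
            acc,
            (g_size["agegrp"].to_numpy(), g_size["sex"].to_numpy()),
            g_size["weight"].to_numpy(),
        )
        dist.by_size[int(size_cat)] = acc / acc.sum()
        for (mg, ms), g_cond in g_size.groupby(["m_agegrp", "m_sex"]):
            acc = np.zeros(shape)
            np.add.at(
                acc,
                (g_cond["agegrp"].to_numpy(), g_cond["sex"].to_numpy()),
                g_cond["weight"].to_numpy(),
            )
            dist.conditional.setdefault(int(size_cat), {})[(int(mg), int(ms))] = (
                acc / acc.sum()
            )
    return dist


# ---------------------------------------------------------------------------
# household assignment


@dataclass
class Household:
    """One household: a maintainer plus assigned members."""

    hid: int
    area: str
    maintainer: int            # row index of the maintainer
    size_cat: int              # maintainer's household-size category
    members: list = field(default_factory=list)  # row indices, maintainer excluded
    hhtype: int = -1

    @property
    def capacity(self) -> int:
        return CATEGORY_CAPACITY[self.size_cat]

    @property
    def n_members(self) -> int:
        return 1 + len(self.members)

    @property
    def is_full(self) -> bool:
        return self.n_members >= self.capacity


class _Pool:
    """Unassigned non-maintainers with weighted without-replacement draws."""

    def __init__(self, rows: np.ndarray, agegrp: np.ndarray, sex: np.ndarray):
        self.rows = rows
        self.agegrp = agegrp
        self.sex = sex
        self.alive = np.ones(len(rows), dtype=bool)

    def draw(self, probs: np.ndarray, sub: np.ndarray, rng: np.random.Generator) -> int | None:
        """Draw one index from ``sub`` (positions) weighted by member probs."""
        cand = sub[self.alive[sub]]
        if len(cand) == 0:
            return None
        w = probs[self.agegrp[cand], self.sex[cand]]
        total = w.sum()
        if total <= 0:
            w = np.ones(len(cand))
            total = float(len(cand))
        pick = cand[np.searchsorted(np.cumsum(w), rng.random() * total, side="right").clip(max=len(cand) - 1)]
        self.alive[pick] = False
        return int(pick)


def assign_households(
    individuals: pd.DataFrame,
    member_dist: MemberDistribution,
    rng: np.random.Generator,
    big_household_cap: int = 7,
    hid_start: int = 0,
) -> tuple[pd.DataFrame, list[Household]]:
    """Group one area's individuals into households.

    ``individuals`` must carry drawn ages.  Returns the frame with ``HID``
    filled (−1 for leftovers) and the list of households.  An area with
    non-maintainers but zero maintainers leaves everyone unassigned (logged).
    """
    df = individuals.reset_index(drop=True)
    if (df["age"] < 0).any():
        raise ValueError("individuals must have drawn ages before assignment")
    hid = np.full(len(df), HID_UNSET, dtype=np.int64)
    is_maint = df["prihm"].to_numpy() == 1
    maint_rows = np.flatnonzero(is_maint)
    if len(maint_rows) == 0:
        if len(df):
            logger.warning(
                "area %s: no maintainers among %d individuals",
                df["area"].iloc[0] if len(df) else "?", len(df),
            )
        out = df.copy()
        out["HID"] = hid
        return out, []

    area = str(df["area"].iloc[0])
    households = []
    for k, row in enumerate(maint_rows):
        h = Household(
            hid=hid_start + k,
            area=area,
            maintainer=int(row),
            size_cat=int(df["hhsize"].iloc[row]),
        )
        hid[row] = h.hid
        households.append(h)

    free = np.flatnonzero(~is_maint)
    pool = _Pool(
        free,
        df["agegrp"].to_numpy()[free],
        df["sex"].to_numpy()[free],
    )
    # positions (into `free`) by the individual's own household-size category
    pos = np.arange(len(free))
    size_attr = df["hhsize"].to_numpy()[free]
    young = df["age"].to_numpy()[free] < YOUNG_AGE_CUT
    by_size_young = {c: pos[(size_attr == c) & young] for c in range(5)}
    by_size_adult = {c: pos[(size_attr == c) & ~young] for c in range(5)}

    m_agegrp = df["agegrp"].to_numpy()
    m_sex = df["sex"].to_numpy()

    def fill(h: Household, subpools: list[np.ndarray], cap: int) -> None:
        probs = member_dist.member_probs(
            h.size_cat, int(m_agegrp[h.maintainer]), int(m_sex[h.maintainer])
        )
        while h.n_members < cap:
            pick = None
            for sub in subpools:
                pick = pool.draw(probs, sub, rng)
                if pick is not None:
                    break
            if pick is None:
                return
            row = int(free[pick])
            h.members.append(row)
            hid[row] = h.hid

    # phase 1: matching size attribute, young first
    order = rng.permutation(len(households))
    for i in order:
        h = households[i]
        fill(h, [by_size_young[h.size_cat], by_size_adult[h.size_cat]], h.capacity)
    # phase 2: top up big households with leftover big-household individuals
    for i in order:
        h = households[i]
        if h.size_cat == 4 and not h.is_full:
            fill(h, [by_size_young[4], by_size_adult[4]], h.capacity)
    # phase 3: fill any remaining vacancy with anyone unassigned
    all_young = pos[young]
    all_adult = pos[~young]
    for i in order:
        h = households[i]
        cap = big_household_cap if h.size_cat == 4 else h.capacity
        if h.n_members < cap:
            fill(h, [all_young, all_adult], cap)

    unassigned = int((hid[free] == HID_UNSET).sum())
    if unassigned:
        logger.info("area %s: %d individuals left unassigned", area, unassigned)
    out = df.copy()
    out["HID"] = hid
    return out, households


# ---------------------------------------------------------------------------
# household types


def household_type(ages: list[int] | np.ndarray) -> int:
    """Infer a household type code from member ages alone.

    0 couple without children, 1 couple with children, 2 one-parent,
    3 one-person, 4 other.  "More than 16 years" and "aged more than 16"
    are strict; a member aged exactly 16 satisfies neither the >16 nor the
    <16 branch.
    """
    a = sorted((int(x) for x in ages), reverse=True)
    n = len(a)
    if n == 0:
        raise ValueError("empty household")
    if n == 1:
        return 3
    if n == 2:
        if a[0] - a[1] > 16:
            return 2
        if a[0] > 16 and a[1] > 16:
            return 0
        return 4
    if n > 6:
        return 4
    oldest, second = a[0], a[1]
    others = a[2:]
    youngest = a[-1]
    # couple with children: two adult-aged oldest with only minors behind
    # them, or both oldest clearly a generation above the youngest
    if (oldest > 16 and second > 16 and all(x < 16 for x in others)) or (
        oldest - youngest > 16 and second - youngest > 16
    ):
        return 1
    # one parent: oldest a generation above everyone else, all minors
    rest = a[1:]
    if all(oldest - x > 16 for x in rest) and all(x < 16 for x in rest):
        return 2
    return 4


def assign_household_types(
    individuals: pd.DataFrame, households: list[Household]
) -> tuple[pd.DataFrame, list[Household]]:
    """Set ``hhtype`` on every household and its members.

    Requires drawn ages; unassigned individuals (``HID = -1``) keep the
    unset type.
    """
    df = individuals.reset_index(drop=True)
    if (df["age"] < 0).any():
        raise ValueError("individuals must have drawn ages before typing")
    ages = df["age"].to_numpy()
    hhtype = df["hhtype"].to_numpy().copy()
    for h in households:
        rows = [h.maintainer, *h.members]
        h.hhtype = household_type(ages[rows])
        hhtype[rows] = h.hhtype
    out = df.copy()
    out["hhtype"] = hhtype
    return out, households


def assign_types_by_hid(population: pd.DataFrame) -> pd.DataFrame:
    """Type every household in a population frame grouped by ``HID``.

    Convenience for re-typing a population file where the household objects
    are no longer in memory.
    """
    df = population.reset_index(drop=True)
    if (df.loc[df["HID"] != HID_UNSET, "age"] < 0).any():
        raise ValueError("assigned individuals must have drawn ages")
    hhtype = df["hhtype"].to_numpy().copy()
    for hid_val, idx in df.groupby("HID").indices.items():
        if hid_val == HID_UNSET:
            continue
        hhtype[idx] = household_type(df["age"].to_numpy()[idx])
    out = df.copy()
    out["hhtype"] = hhtype
    return out
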