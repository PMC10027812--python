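"""Per-area integral population synthesis (IPF + quasirandom integer sampling).

The synthesizer estimates, for every small area, a seven-way contingency
table over (age group, sex, highest degree, labour force status, household
size, income band, maintainer flag) whose marginals match the published
aggregate counts for the area, then draws an integer population from it.

Two stages:

1. **Iterative proportional fitting** scales a weighted microdata seed table
   against each marginal constraint in turn until all constrained marginals
   are reproduced.  The fit preserves the seed's interaction structure
   (odds ratios) wherever it is not constrained.
2. **Quasirandom integer sampling without replacement** draws one person at
   a time from the fitted table, keeping an integer quota per marginal
   category and refitting the table to the remaining quotas after each draw.
   Every constrained marginal of the sampled population therefore matches
   its integer target *exactly* — no separate integerisation step.

Marginal constraints per area: total population, households (as the
maintainer-flag margin), sex, age group, the age-group × sex joint,
household size, highest degree, labour force status and income band.
Constraint scaling order within an IPF sweep is fixed and declared
(:data:`CONSTRAINT_ORDER`) for reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .census_io import (
    SUPPRESSED,
    AreaProfile,
    DWELLINGS_LABEL,
    POPULATION_LABEL,
)
from .census_model import (
    AGE_UNSET,
    CATEGORY_SIZES,
    HHTYPE_UNSET,
    HID_UNSET,
    SEED_AXES,
    CategoryMap,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SeedTable",
    "MarginalSet",
    "ConvergenceError",
    "SamplingError",
    "UnusableAreaError",
    "CONSTRAINT_ORDER",
    "build_seed",
    "province_distributions",
    "build_raw_marginals",
    "match_marginals",
    "ipf",
    "fit_table",
    "qis_sample",
    "qis_sample_table",
    "synthesize_area",
    "synthesize_province",
]

SEED_SHAPE = tuple(CATEGORY_SIZES[v] for v in SEED_AXES)

#: IPF constraint application order within one sweep: the age×sex joint
#: first, then the single-attribute margins, with the single-axis age and
#: sex margins last (they act as the tie-break when rounding made the raw
#: counts inconsistent; marginal matching reconciles them beforehand).
CONSTRAINT_ORDER: tuple[tuple[str, ...], ...] = (
    ("agegrp", "sex"),
    ("hdgree",),
    ("lfact",),
    ("hhsize",),
    ("totinc",),
    ("prihm",),
    ("agegrp",),
    ("sex",),
)


class ConvergenceError(RuntimeError):
    """IPF did not reach tolerance (e.g. structural zeros vs positive targets)."""

    def __init__(self, residual: float, iterations: int):
        self.residual = residual
        self.iterations = iterations
        super().__init__(
            f"IPF residual {residual:.3g} after {iterations} sweeps"
        )


class SamplingError(RuntimeError):
    """Integer sampling hit an infeasible quota state."""


class UnusableAreaError(ValueError):
    """The area profile lacks the total population count."""


# ---------------------------------------------------------------------------
# seed


@dataclass
class SeedTable:
    """Weighted 7-way contingency table built from microdata records.

    Cells hold summed record weights; cells unobserved in the sample hold
    the smoothing value ``eps`` so rare but real attribute combinations can
    still be synthesized (``eps = 0`` forbids them).
    """

    table: np.ndarray
    eps: float

    def __post_init__(self) -> None:
        if self.table.shape != SEED_SHAPE:
            raise ValueError(
                f"seed shape {self.table.shape} != expected {SEED_SHAPE}"
            )
        if (self.table < 0).any():
            raise ValueError("seed has negative cells")


def build_seed(records: pd.DataFrame, eps: float | None = None) -> SeedTable:
    """Aggregate unified, weighted microdata records into a seed table.

    ``eps`` defaults to 10⁻⁶ × the minimum positive cell weight; pass 0 to
    keep unobserved cells at zero.
    """
    if len(records) == 0:
        raise ValueError("cannot build a seed from zero records")
    table = np.zeros(SEED_SHAPE, dtype=float)
    coords = tuple(records[v].to_numpy(dtype=np.intp) for v in SEED_AXES)
    np.add.at(table, coords, records["weight"].to_numpy(dtype=float))
    if eps is None:
        eps = 1e-6 * table[table > 0].min()
    if eps < 0:
        raise ValueError("eps must be >= 0")
    if eps > 0:
        table[table == 0] = eps
    return SeedTable(table, float(eps))


def province_distributions(seed: SeedTable) -> dict:
    """Province-level category distributions implied by the weighted seed.

    Used to impute missing area subtotals and to direct marginal matching.
    Includes one entry per synthesis variable plus the ``("agegrp","sex")``
    joint.
    """
    out: dict = {}
    total = seed.table.sum()
    for i, var in enumerate(SEED_AXES):
        axes = tuple(j for j in range(len(SEED_AXES)) if j != i)
        out[var] = seed.table.sum(axis=axes) / total
    ia, is_ = SEED_AXES.index("agegrp"), SEED_AXES.index("sex")
    axes = tuple(j for j in range(len(SEED_AXES)) if j not in (ia, is_))
    out[("agegrp", "sex")] = seed.table.sum(axis=axes) / total
    return out


# ---------------------------------------------------------------------------
# marginals


@dataclass
class MarginalSet:
    """Integer target vectors for one small area.

    After :func:`match_marginals`, every vector sums to ``n`` and the
    ``joint`` age×sex table has row sums equal to the age vector and column
    sums equal to the sex vector.
    """

    area: str
    n: int
    households: int
    vectors: dict = field(default_factory=dict)  # var -> 1-D int array
    joint: np.ndarray | None = None              # (18, 2) agegrp × sex
    matched: bool = False

    def constraints(self) -> list[tuple[tuple[int, ...], np.ndarray]]:
        """(axes, target) pairs in the declared IPF order."""
        if not self.matched:
            raise ValueError("marginals must be matched before constraining IPF")
        out: list[tuple[tuple[int, ...], np.ndarray]] = []
        for vars_ in CONSTRAINT_ORDER:
            axes = tuple(SEED_AXES.index(v) for v in vars_)
            if vars_ == ("agegrp", "sex"):
                target = self.joint.astype(float)
            else:
                target = self.vectors[vars_[0]].astype(float)
            out.append((axes, target))
        return out


def _apportion(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` units over ``weights``."""
    w = np.asarray(weights, dtype=float)
    if total < 0:
        raise ValueError("total must be >= 0")
    if w.sum() <= 0:
        w = np.ones_like(w)
    share = total * w / w.sum()
    base = np.floor(share).astype(np.int64)
    left = int(total - base.sum())
    if left:
        order = np.argsort(-(share - base), kind="stable")
        base[order[:left]] += 1
    return base


def _match_vector(vec: np.ndarray, n: int, dist: np.ndarray) -> np.ndarray:
    """Adjust a raw count vector so it sums to ``n``.

    Unit increments (or decrements) are allocated following the province
    distribution by largest remainder; entries never go negative; an
    already-matching vector is returned unchanged.
    """
    v = np.asarray(vec, dtype=np.int64).copy()
    if (v < 0).any():
        raise ValueError("negative marginal entries")
    d = int(n - v.sum())
    if d == 0:
        return v
    if d > 0:
        return v + _apportion(d, dist)
    # decrease: cap removals at current entries, reallocate any shortfall
    need = -d
    while need > 0:
        take = np.minimum(_apportion(need, dist * (v > 0)), v)
        if take.sum() == 0:
            # dist mass sits on empty categories; fall back to plain counts
            take = np.minimum(_apportion(need, (v > 0).astype(float)), v)
        v -= take
        need -= int(take.sum())
        if v.sum() == 0 and need > 0:
            raise ValueError("cannot decrease marginals below zero")
    return v


def _integerize_joint(
    frac: np.ndarray, rows: np.ndarray, cols: np.ndarray
) -> np.ndarray:
    """Round a non-negative matrix to integers with exact row/col sums."""
    base = np.floor(frac).astype(np.int64)
    r = rows - base.sum(axis=1)
    c = cols - base.sum(axis=0)
    if (r < 0).any() or (c < 0).any():  # flooring can't overshoot, defensive
        raise ValueError("infeasible integerisation state")
    frac_part = frac - base
    while r.sum() > 0:
        mask = (r[:, None] > 0) & (c[None, :] > 0)
        if not mask.any():
            raise ValueError("row/col deficits inconsistent")
        flat = np.where(mask, frac_part, -1.0)
        i, j = np.unravel_index(int(np.argmax(flat)), flat.shape)
        base[i, j] += 1
        frac_part[i, j] = max(frac_part[i, j] - 1.0, 0.0)
        r[i] -= 1
        c[j] -= 1
    return base


def build_raw_marginals(
    profile: AreaProfile,
    area_id: str,
    prov_dist: dict,
    cmap: CategoryMap | None = None,
) -> MarginalSet:
    """Aggregate profile rows into unmatched unified marginal vectors.

    Implements the under-15 augmentations (the 0–14 population is added to
    "no degree", "not in labour force" and the lowest income band, whose
    profile rows cover ages 15+ only), converts household counts by size to
    persons by size, and imputes any wholly missing variable from the
    province distribution.
    """
    cmap = cmap or CategoryMap()
    if not profile.has(POPULATION_LABEL):
        raise UnusableAreaError(f"area {area_id}: no total population row")
    n = profile.count(POPULATION_LABEL)
    if n <= 0:
        raise UnusableAreaError(f"area {area_id}: total population {n}")
    if profile.has(DWELLINGS_LABEL):
        households = profile.count(DWELLINGS_LABEL)
    else:
        households = int(round(n * float(prov_dist["prihm"][1])))
    ms = MarginalSet(area=str(area_id), n=n, households=households)

    def labelled_vector(var: str) -> np.ndarray | None:
        labels = cmap.profile_labels(var)
        k = CATEGORY_SIZES[var]
        vec = np.zeros(k, dtype=np.int64)
        seen = False
        for cat, labs in labels.items():
            for lab in labs:
                if profile.has(lab):
                    vec[cat] += profile.count(lab)
                    seen = True
        return vec if seen else None

    # age vector and age×sex joint from the per-age rows
    age_vec = labelled_vector("agegrp")
    joint = np.zeros((CATEGORY_SIZES["agegrp"], 2), dtype=np.int64)
    have_joint = False
    for cat, labs in cmap.profile_labels("agegrp").items():
        for lab in labs:
            if profile.has(lab):
                f, m = profile.sex_counts(lab)
                if f or m:
                    have_joint = True
                joint[cat, 0] += f
                joint[cat, 1] += m
    if age_vec is None:
        age_vec = _apportion(n, prov_dist["agegrp"])
    pop_0_14 = int(age_vec[:3].sum())

    # sex from the male/female columns of the population row
    f, m = profile.sex_counts(POPULATION_LABEL)
    sex_vec = np.array([f, m], dtype=np.int64)
    if sex_vec.sum() == 0:
        sex_vec = _apportion(n, prov_dist["sex"])
    if not have_joint:
        # independence fallback; reconciled to the matched vectors later
        joint = np.outer(age_vec, sex_vec)

    # household size: published as households by size; persons = size × count
    hh_by_size = labelled_vector("hhsize")
    if hh_by_size is None:
        hhsize_vec = _apportion(n, prov_dist["hhsize"])
    else:
        persons_per_cat = np.array([1, 2, 3, 4, 5], dtype=np.int64)
        hhsize_vec = hh_by_size * persons_per_cat

    def fifteen_plus(var: str) -> np.ndarray:
        vec = labelled_vector(var)
        if vec is None:
            return _apportion(n, prov_dist[var])
        vec = vec.copy()
        vec[cmap.under15_category(var)] += pop_0_14
        return vec

    ms.vectors = {
        "agegrp": age_vec,
        "sex": sex_vec,
        "hhsize": hhsize_vec,
        "hdgree": fifteen_plus("hdgree"),
        "lfact": fifteen_plus("lfact"),
        "totinc": fifteen_plus("totinc"),
    }
    ms.joint = joint
    return ms


def match_marginals(raw: MarginalSet, prov_dist: dict) -> MarginalSet:
    """Force every marginal vector to sum to the area population.

    Each vector is adjusted by the minimal total change, allocating ±1
    increments along the province distribution by largest remainder.  The
    age×sex joint is then reconciled to the matched single-axis age and sex
    vectors (2-D fit + margin-preserving integerisation) so the whole
    constraint set is mutually consistent.  Idempotent on matched input.
    """
    if raw.n <= 0:
        raise ValueError(f"area {raw.area}: degenerate population {raw.n}")
    n = raw.n
    households = raw.households
    if households > n:
        logger.warning(
            "area %s: households %d > population %d; capping", raw.area,
            households, n,
        )
        households = n
    out = MarginalSet(area=raw.area, n=n, households=households)
    out.vectors = {
        var: _match_vector(vec, n, prov_dist[var])
        for var, vec in raw.vectors.items()
    }
    out.vectors["prihm"] = np.array([n - households, households], dtype=np.int64)

    age, sex = out.vectors["agegrp"], out.vectors["sex"]
    joint = np.asarray(raw.joint, dtype=float)
    if joint.sum() <= 0:
        joint = np.outer(age, sex).astype(float) / n
    if (
        raw.matched
        and np.array_equal(joint.sum(axis=1), age)
        and np.array_equal(joint.sum(axis=0), sex)
        and np.allclose(joint, np.round(joint))
    ):
        out.joint = joint.astype(np.int64)
    else:
        fitted, _ = fit_table(
            np.maximum(joint, 1e-9 * max(joint.max(), 1.0)),
            [((0,), age.astype(float)), ((1,), sex.astype(float))],
            tol=1e-9,
            max_iter=1000,
        )
        out.joint = _integerize_joint(fitted, age, sex)
    out.matched = True
    return out


# ---------------------------------------------------------------------------
# IPF


def fit_table(
    seed: np.ndarray,
    constraints: list[tuple[tuple[int, ...], np.ndarray]],
    tol: float = 1e-9,
    max_iter: int = 1000,
    history: list | None = None,
) -> tuple[np.ndarray, int]:
    """Iterative proportional fitting of ``seed`` to marginal ``constraints``.

    Each sweep scales the table against every constraint in the given
    order; convergence is declared when the L∞ residual over all constrained
    marginals is ≤ ``tol``.  Structural zeros conflicting with positive
    targets raise :class:`ConvergenceError` carrying the residual.  When a
    list is passed as ``history`` the per-sweep residuals are appended to it.
    """
    T = np.asarray(seed, dtype=float).copy()
    ndim = T.ndim
    # normalise constraint axes to ascending order (matches numpy's sum layout)
    constraints = [
        (
            tuple(sorted(axes)),
            np.transpose(
                np.asarray(target, dtype=float),
                [list(axes).index(a) for a in sorted(axes)],
            )
            if np.asarray(target).ndim > 1
            else np.asarray(target, dtype=float),
        )
        for axes, target in constraints
    ]
    for it in range(1, max_iter + 1):
        for axes, target in constraints:
            other = tuple(a for a in range(ndim) if a not in axes)
            cur = T.sum(axis=other)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(cur > 0, np.asarray(target) / np.where(cur > 0, cur, 1.0), 0.0)
            T = T * _expand(ratio, axes, T.shape)
        residual = 0.0
        for axes, target in constraints:
            other = tuple(a for a in range(ndim) if a not in axes)
            cur = T.sum(axis=other)
            residual = max(residual, float(np.abs(cur - target).max()))
        if history is not None:
            history.append(residual)
        if residual <= tol:
            return T, it
    raise ConvergenceError(residual, max_iter)


def _expand(marg: np.ndarray, axes: tuple[int, ...], shape: tuple[int, ...]) -> np.ndarray:
    """Broadcast a marginal array (axes ascending) back to the full table shape."""
    full_shape = [1] * len(shape)
    for a in axes:
        full_shape[a] = shape[a]
    return np.asarray(marg).reshape(full_shape)


def ipf(
    seed: SeedTable,
    marginals: MarginalSet,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> np.ndarray:
    """Fit the seed table to one area's matched marginals.

    Returns a non-negative table with grand total ``marginals.n`` whose
    constrained marginals are reproduced within ``tol`` (L∞); odds ratios of
    the seed are preserved where unconstrained.
    """
    table, sweeps = fit_table(
        seed.table, marginals.constraints(), tol=tol, max_iter=max_iter
    )
    logger.debug("area %s: IPF converged in %d sweeps", marginals.area, sweeps)
    return table


# ---------------------------------------------------------------------------
# quasirandom integer sampling


def _flat_constraints(
    constraints: list[tuple[tuple[int, ...], np.ndarray]],
    shape: tuple[int, ...],
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(cell→category index, integer quota) per constraint, on the flat table."""
    grids = np.indices(shape).reshape(len(shape), -1)
    out = []
    for axes, target in constraints:
        t = np.asarray(np.round(target), dtype=np.int64)
        if len(axes) == 1:
            idx = grids[axes[0]]
        else:
            idx = np.ravel_multi_index(
                tuple(grids[a] for a in axes),
                tuple(shape[a] for a in axes),
            )
            t = t.reshape(-1)
        out.append((idx.astype(np.intp), t.copy()))
    return out


def qis_sample_table(
    table: np.ndarray,
    constraints: list[tuple[tuple[int, ...], np.ndarray]],
    rng: np.random.Generator,
    refit_tol: float = 1e-6,
    refit_sweeps: int = 2,
    label: str = "?",
) -> np.ndarray:
    """Draw an integer table matching every constrained marginal exactly.

    Sequential sampling without replacement: each person is drawn from the
    current fractional table restricted to cells whose every marginal quota
    is still open; after the draw the quotas are decremented and the table
    is refitted to the remaining quotas with a few IPF sweeps.  The
    exactness contract — integer equality of all constrained marginals — is
    enforced by the quota bookkeeping, not by the random stream.
    """
    shape = np.asarray(table).shape
    flat = np.asarray(table, dtype=float).reshape(-1).copy()
    cons = _flat_constraints(constraints, shape)
    n = int(cons[0][1].sum())
    for idx, quota in cons:
        if quota.sum() != n:
            raise SamplingError(
                f"area {label}: quota sums disagree ({quota.sum()} != {n})"
            )
    counts = np.zeros(flat.size, dtype=np.int64)
    if n == 0:
        return counts.reshape(shape)
    # zero out cells in categories with zero quota
    for idx, quota in cons:
        flat[quota[idx] == 0] = 0.0
    for k in range(n):
        remaining = n - k
        total = flat.sum()
        if total <= 0:
            raise SamplingError(
                f"area {label}: no admissible cells with "
                f"{remaining} persons left"
            )
        cum = np.cumsum(flat)
        cell = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        cell = min(cell, flat.size - 1)
        counts[cell] += 1
        closed = False
        for idx, quota in cons:
            cat = idx[cell]
            quota[cat] -= 1
            if quota[cat] == 0:
                flat[idx == cat] = 0.0
                closed = True
        if remaining == 1:
            break
        # light IPF refit against the remaining quotas; near the end run
        # to convergence so the weights steer away from infeasible corners
        sweeps = refit_sweeps if remaining > 32 else 60
        for _ in range(sweeps):
            residual = 0.0
            for idx, quota in cons:
                cur = np.bincount(idx, weights=flat, minlength=quota.size)
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = np.where(cur > 0, quota / np.where(cur > 0, cur, 1.0), 0.0)
                flat *= ratio[idx]
                residual = max(residual, float(np.abs(cur - quota).max()))
            if residual <= refit_tol * max(1.0, remaining - 1):
                break
        if closed and flat.sum() <= 0 and k < n - 1:
            raise SamplingError(
                f"area {label}: sampling dead end at person {k + 1}/{n}"
            )
    for idx, quota in cons:
        if (quota != 0).any():
            raise SamplingError(
                f"area {label}: unmet quotas after sampling"
            )
    return counts.reshape(shape)


def qis_sample(
    table: np.ndarray,
    marginals: MarginalSet,
    rng: np.random.Generator,
    refit_tol: float = 1e-6,
    refit_sweeps: int = 2,
) -> np.ndarray:
    """:func:`qis_sample_table` against one area's matched marginals."""
    return qis_sample_table(
        table, marginals.constraints(), rng,
        refit_tol=refit_tol, refit_sweeps=refit_sweeps, label=marginals.area,
    )


# ---------------------------------------------------------------------------
# per-area orchestration


def _individuals_from_table(
    int_table: np.ndarray, area_id: str, start_index: int
) -> pd.DataFrame:
    flat = int_table.reshape(-1)
    cells = np.repeat(np.arange(flat.size), flat)
    coords = np.unravel_index(cells, SEED_SHAPE)
    n = cells.size
    df = pd.DataFrame({v: coords[i].astype(np.int64) for i, v in enumerate(SEED_AXES)})
    df.insert(0, "index", np.arange(start_index, start_index + n, dtype=np.int64))
    df["HID"] = HID_UNSET
    df["age"] = AGE_UNSET
    df["area"] = str(area_id)
    df["hhtype"] = HHTYPE_UNSET
    return df


def synthesize_area(
    seed: SeedTable,
    profile: AreaProfile,
    area_id: str,
    rng: np.random.Generator,
    prov_dist: dict | None = None,
    cmap: CategoryMap | None = None,
    tol: float = 1e-9,
    max_iter: int = 1000,
    start_index: int = 0,
    max_retries: int = 3,
) -> pd.DataFrame | None:
    """Synthesize one area's population; ``None`` for a suppressed area.

    One individual per unit of the sampled integer table; attributes come
    from the cell coordinates, the area is set to ``area_id`` and indices
    are sequential from ``start_index``.
    """
    if profile is SUPPRESSED or profile is None:
        logger.info("area %s: suppressed in profile, skipped", area_id)
        return None
    if prov_dist is None:
        prov_dist = province_distributions(seed)
    raw = build_raw_marginals(profile, area_id, prov_dist, cmap=cmap)
    marginals = match_marginals(raw, prov_dist)
    table = ipf(seed, marginals, tol=tol, max_iter=max_iter)
    last: SamplingError | None = None
    for attempt in range(max_retries):
        try:
            int_table = qis_sample(table, _copy_marginals(marginals), rng)
            break
        except SamplingError as exc:  # pragma: no cover - eps>0 makes this rare
            logger.warning("area %s: %s (retry %d)", area_id, exc, attempt + 1)
            last = exc
    else:  # pragma: no cover
        raise last
    return _individuals_from_table(int_table, area_id, start_index)


def _copy_marginals(m: MarginalSet) -> MarginalSet:
    out = MarginalSet(area=m.area, n=m.n, households=m.households)
    out.vectors = {k: v.copy() for k, v in m.vectors.items()}
    out.joint = None if m.joint is None else m.joint.copy()
    out.matched = m.matched
    return out


def synthesize_province(
    seed: SeedTable,
    profile_reader,
    areas: list[str],
    master_seed: int,
    cmap: CategoryMap | None = None,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """Synthesize every listed area, with a per-area RNG substream.

    Substreams derive from ``(master_seed, area code)``, so splitting the
    area list into chunks cannot change the result.
    """
    prov_dist = province_distributions(seed)
    parts: list[pd.DataFrame] = []
    start = 0
    for area in areas:
        rng = np.random.default_rng(np.random.SeedSequence((int(master_seed), int(area))))
        df = synthesize_area(
            seed, profile_reader.area(area), area, rng,
            prov_dist=prov_dist, cmap=cmap, tol=tol, max_iter=max_iter,
            start_index=start,
        )
        if df is None:
            continue
        parts.append(df)
        start += len(df)
    if not parts:
        return _individuals_from_table(np.zeros(SEED_SHAPE, dtype=np.int64), "0" * 8, 0).iloc[:0]
    return pd.concat(parts, ignore_index=True)
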