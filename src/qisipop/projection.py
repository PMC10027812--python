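"""Scenario projection of a base population by per-cell resampling.

For a target (scenario, year, province) slice, the difference between the
projected count and the base count is computed for every (sex, age group)
cell; the base population is then grown by duplicating uniformly sampled
individuals (with replacement, all attributes copied, fresh indices) or
shrunk by deleting uniformly without replacement.  Cell counts match the
targets exactly afterwards.

Projections for different years are independent: each starts from the base
population, never from a previously projected year.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .census_model import AGE_UNSET, CATEGORY_SIZES, HHTYPE_UNSET, HID_UNSET

logger = logging.getLogger(__name__)

__all__ = ["compute_cell_deltas", "resample"]


def compute_cell_deltas(
    population: pd.DataFrame, targets: np.ndarray
) -> dict[tuple[int, int], int]:
    """Signed person difference per (sex, age group) cell.

    ``targets`` is a (2, 18) array of projected counts (females row 0) with
    the 85+ bands already collapsed; values are rounded to whole persons.
    Raises ``KeyError`` if a populated cell has no target entry (NaN).
    """
    t = np.asarray(targets, dtype=float)
    if t.shape != (2, CATEGORY_SIZES["agegrp"]):
        raise ValueError(f"targets shape {t.shape} != (2, 18)")
    base = (
        population.groupby(["sex", "agegrp"]).size()
        if len(population)
        else pd.Series(dtype=np.int64)
    )
    deltas: dict[tuple[int, int], int] = {}
    for s in range(2):
        for g in range(CATEGORY_SIZES["agegrp"]):
            if np.isnan(t[s, g]):
                if base.get((s, g), 0) > 0:
                    raise KeyError(f"no projection target for cell (sex={s}, agegrp={g})")
                continue
            deltas[(s, g)] = int(round(t[s, g])) - int(base.get((s, g), 0))
    return deltas


def resample(
    population: pd.DataFrame,
    deltas: dict[tuple[int, int], int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Duplicate or delete individuals so cell counts match the targets.

    Duplicates are drawn uniformly with replacement from the cell and copied
    in full (area included) with new indices above the current maximum;
    deletions are uniform without replacement.  Individuals in unchanged
    cells keep their indices.  Household-derived fields (``HID``, ``age``,
    ``hhtype``) are reset on the whole output since households are
    re-assigned per projected year.
    """
    pop = population.reset_index(drop=True)
    keep_mask = np.ones(len(pop), dtype=bool)
    dup_rows: list[np.ndarray] = []
    all_zero = all(d == 0 for d in deltas.values())
    cells = pop.groupby(["sex", "agegrp"]).indices if len(pop) else {}
    for (s, g), delta in sorted(deltas.items()):
        if delta == 0:
            continue
        rows = cells.get((s, g), np.array([], dtype=np.intp))
        if delta > 0:
            if len(rows) == 0:
                logger.warning(
                    "cell (sex=%d, agegrp=%d): +%d requested but base cell "
                    "is empty; cannot duplicate", s, g, delta,
                )
                continue
            dup_rows.append(rng.choice(rows, size=delta, replace=True))
        else:
            k = min(-delta, len(rows))
            if k < -delta:
                logger.warning(
                    "cell (sex=%d, agegrp=%d): %d deletions requested, only "
                    "%d present; cell emptied", s, g, -delta, len(rows),
                )
            drop = rng.choice(rows, size=k, replace=False)
            keep_mask[drop] = False
    out = pop[keep_mask]
    if dup_rows:
        extra = pop.iloc[np.concatenate(dup_rows)].copy()
        next_index = int(pop["index"].max()) + 1 if len(pop) else 0
        extra["index"] = np.arange(next_index, next_index + len(extra), dtype=np.int64)
        out = pd.concat([out, extra], ignore_index=True)
    else:
        out = out.reset_index(drop=True)
    if not all_zero:
        out = out.copy()
        out["HID"] = HID_UNSET
        out["age"] = AGE_UNSET
        out["hhtype"] = HHTYPE_UNSET
    return out


def project(
    population: pd.DataFrame,
    targets: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Convenience wrapper: deltas + resample against one projection slice."""
    return resample(population, compute_cell_deltas(population, targets), rng)
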