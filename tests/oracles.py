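"""Independent brute-force oracles, deliberately coded without numpy
vectorisation or any reuse of the package's fitting code.
"""

from __future__ import annotations

import numpy as np


def ipf_oracle(seed, constraints, sweeps=2000, tol=1e-12):
    """Plain per-cell iterative scaling on nested Python loops."""
    table = {idx: float(seed[idx]) for idx in np.ndindex(seed.shape)}
    for _ in range(sweeps):
        worst = 0.0
        for axes, target in constraints:
            sums: dict = {}
            for idx, v in table.items():
                key = tuple(idx[a] for a in axes)
                sums[key] = sums.get(key, 0.0) + v
            for idx in table:
                key = tuple(idx[a] for a in axes)
                if sums[key] > 0:
                    table[idx] *= float(np.asarray(target)[key]) / sums[key]
            for key, s in sums.items():
                worst = max(worst, abs(s - float(np.asarray(target)[key])))
        if worst <= tol:
            break
    out = np.zeros(seed.shape)
    for idx, v in table.items():
        out[idx] = v
    return out


def household_type_oracle(ages) -> int:
    """Literal transcription of the age-gap classification rules.

    One person: one-person household (3).  Two members more than 16 years
    apart: one-parent (2); otherwise both over 16: couple without
    children (0); otherwise other (4).  For 3-6 members: couple with
    children (1) if the two oldest are over 16 and everyone else is under
    16, or if both of the two oldest are more than 16 years older than the
    youngest; else one-parent (2) if the oldest is more than 16 years older
    than every other member and all of them are under 16; else other (4).
    Seven or more members: other (4).
    """
    ages = sorted(ages, reverse=True)
    if len(ages) == 1:
        return 3
    if len(ages) == 2:
        first, second = ages
        if first - second > 16:
            return 2
        if first > 16 and second > 16:
            return 0
        return 4
    if 3 <= len(ages) <= 6:
        oldest = ages[0]
        second = ages[1]
        rest = ages[2:]
        youngest = ages[-1]
        cond_couple_a = oldest > 16 and second > 16 and all(m < 16 for m in rest)
        cond_couple_b = (oldest - youngest > 16) and (second - youngest > 16)
        if cond_couple_a or cond_couple_b:
            return 1
        others = ages[1:]
        if all(oldest - m > 16 for m in others) and all(m < 16 for m in others):
            return 2
        return 4
    return 4


def pearson_two_pass(x, y) -> float:
    """Textbook two-pass product-moment correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x) ** 0.5
    dy = sum((b - my) ** 2 for b in y) ** 0.5
    return num / (dx * dy)


def random_ipf_instance(rng, shape=(3, 4, 2)):
    """A random consistent 3-axis IPF problem (positive seed)."""
    seed = rng.uniform(0.2, 2.0, size=shape)
    hidden = rng.uniform(0.2, 3.0, size=shape)
    constraints = []
    for axis in range(len(shape)):
        other = tuple(a for a in range(len(shape)) if a != axis)
        constraints.append(((axis,), hidden.sum(axis=other)))
    return seed, constraints
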