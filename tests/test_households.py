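"""Age drawing, composition estimation, assignment and household typing."""

import numpy as np
import pandas as pd
import pytest

from qisipop.households import (
    AgeDrawConfig,
    assign_household_types,
    assign_households,
    draw_age,
    draw_ages,
    estimate_member_distribution,
    household_type,
)

from .oracles import household_type_oracle


class TestDrawAge:
    def test_uniform_band_frequencies(self):
        rng = np.random.default_rng(0)
        ages = draw_ages(np.zeros(100_000, dtype=int), rng)
        assert set(np.unique(ages)) == {0, 1, 2, 3, 4}
        freq = np.bincount(ages) / len(ages)
        sigma = np.sqrt(0.2 * 0.8 / len(ages))
        assert np.abs(freq - 0.2).max() < 3 * sigma

    def test_open_band_geometric_start(self):
        rng = np.random.default_rng(1)
        ages = draw_ages(np.full(100_000, 17), rng)
        p85 = (ages == 85).mean()
        expected = 0.2 / (1 - 0.8 ** 36)   # renormalised tail reference
        sigma = np.sqrt(expected * (1 - expected) / len(ages))
        assert abs(p85 - expected) < 4 * sigma

    def test_open_band_truncated_at_max(self):
        rng = np.random.default_rng(2)
        ages = draw_ages(np.full(100_000, 17), rng)
        assert ages.max() <= 120
        assert ages.min() >= 85

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AgeDrawConfig(geometric_p=0.0)

    def test_scalar_wrapper_in_band(self):
        rng = np.random.default_rng(3)
        for g in range(17):
            a = draw_age(g, rng)
            assert 5 * g <= a <= 5 * g + 4


def _hier(rows):
    return pd.DataFrame(
        rows, columns=["hh_id", "person_id", "weight", "agegrp", "sex", "prihm"]
    )


class TestMemberDistribution:
    def test_single_household_point_mass(self):
        rec = _hier([(1, 1, 10.0, 16, 1, 1), (1, 2, 10.0, 16, 0, 0)])
        dist = estimate_member_distribution(rec)
        probs = dist.member_probs(1, 16, 1)
        assert probs[16, 0] == 1.0
        assert probs.sum() == pytest.approx(1.0)

    def test_conditionals_normalise(self):
        rng = np.random.default_rng(4)
        rows = []
        for hh in range(200):
            size = rng.integers(2, 6)
            rows.append((hh, hh * 10, 5.0, rng.integers(4, 18), rng.integers(2), 1))
            for m in range(size - 1):
                rows.append((hh, hh * 10 + m + 1, 5.0, rng.integers(0, 18),
                             rng.integers(2), 0))
        dist = estimate_member_distribution(_hier(rows))
        for size_cat, conds in dist.conditional.items():
            for probs in conds.values():
                assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        for probs in dist.by_size.values():
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_recovers_known_composition_law(self):
        """Members generated from a fixed conditional law are re-estimated
        within multinomial error."""
        rng = np.random.default_rng(5)
        law = np.zeros((18, 2))
        law[0, 0] = 0.5
        law[8, 1] = 0.3
        law[13, 0] = 0.2
        n = 3000
        rows = []
        for hh in range(n):
            rows.append((hh, hh * 10, 1.0, 10, 0, 1))
            flat = rng.choice(36, p=law.reshape(-1))
            rows.append((hh, hh * 10 + 1, 1.0, flat // 2, flat % 2, 0))
        dist = estimate_member_distribution(_hier(rows))
        probs = dist.member_probs(1, 10, 0)
        for (g, s), p in {(0, 0): 0.5, (8, 1): 0.3, (13, 0): 0.2}.items():
            sigma = np.sqrt(p * (1 - p) / n)
            assert abs(probs[g, s] - p) < 4 * sigma

    def test_no_households_raises(self):
        with pytest.raises(ValueError):
            estimate_member_distribution(_hier([]))

    def test_fallback_for_unseen_conditioning_cell(self):
        rec = _hier([(1, 1, 10.0, 16, 1, 1), (1, 2, 10.0, 16, 0, 0)])
        dist = estimate_member_distribution(rec)
        # unseen maintainer cell falls back to the size-level law
        assert (dist.member_probs(1, 5, 0) == dist.by_size[1]).all()


def _area_pop(rows):
    df = pd.DataFrame(
        rows, columns=["prihm", "hhsize", "agegrp", "sex", "age"]
    )
    df["index"] = np.arange(len(df))
    df["HID"] = -1
    df["area"] = "10010001"
    df["hdgree"] = 0
    df["lfact"] = 2
    df["totinc"] = 0
    df["hhtype"] = -1
    return df


@pytest.fixture(scope="module")
def flat_dist():
    rec = _hier([(1, 1, 10.0, 10, 1, 1), (1, 2, 10.0, 10, 0, 0)])
    return estimate_member_distribution(rec)


class TestAssignHouseholds:
    def test_single_person_household_complete(self, flat_dist):
        pop = _area_pop([(1, 0, 10, 0, 52)])
        out, hhs = assign_households(pop, flat_dist, np.random.default_rng(0))
        assert len(hhs) == 1 and hhs[0].is_full
        assert out["HID"].iloc[0] == hhs[0].hid

    def test_pairing_two_person_household(self, flat_dist):
        pop = _area_pop([(1, 1, 10, 0, 52), (0, 1, 10, 1, 50)])
        out, hhs = assign_households(pop, flat_dist, np.random.default_rng(0))
        assert (out["HID"] == hhs[0].hid).all()

    def test_capacity_bound_leaves_leftovers(self, flat_dist):
        pop = _area_pop([(1, 1, 10, 0, 52)] + [(0, 1, 10, 1, 50)] * 3)
        out, hhs = assign_households(pop, flat_dist, np.random.default_rng(0))
        assert hhs[0].n_members == 2
        assert (out["HID"] == -1).sum() == 2

    def test_no_maintainers_all_unassigned(self, flat_dist, caplog):
        pop = _area_pop([(0, 1, 10, 0, 30)] * 4)
        out, hhs = assign_households(pop, flat_dist, np.random.default_rng(0))
        assert hhs == [] and (out["HID"] == -1).all()

    def test_conservation_and_uniqueness(self, flat_dist):
        rng = np.random.default_rng(6)
        rows = []
        for _ in range(400):
            prihm = int(rng.random() < 0.4)
            hhsize = int(rng.integers(0, 5))
            agegrp = int(rng.integers(0, 18))
            age = int(85 if agegrp == 17 else 5 * agegrp + rng.integers(0, 5))
            rows.append((prihm, hhsize, agegrp, int(rng.integers(2)), age))
        pop = _area_pop(rows)
        out, hhs = assign_households(pop, flat_dist, np.random.default_rng(7))
        assigned = out[out["HID"] >= 0]
        assert len(assigned) + (out["HID"] == -1).sum() == len(pop)
        # one household per maintainer, each individual in at most one
        assert len(hhs) == (pop["prihm"] == 1).sum()
        members = [m for h in hhs for m in [h.maintainer, *h.members]]
        assert len(members) == len(set(members)) == len(assigned)
        for h in hhs:
            assert h.n_members <= 7
            if h.size_cat < 4:
                assert h.n_members <= h.size_cat + 1

    def test_requires_drawn_ages(self, flat_dist):
        pop = _area_pop([(1, 0, 10, 0, -1)])
        with pytest.raises(ValueError):
            assign_households(pop, flat_dist, np.random.default_rng(0))


class TestHouseholdType:
    @pytest.mark.parametrize(
        "ages,expected",
        [
            ([45], 3),
            ([45, 10], 2),
            ([45, 40], 0),
            ([40, 38, 10], 1),
            ([40, 38, 30], 4),
            ([40, 10, 8], 2),
            ([16, 16], 4),          # exactly 16 satisfies neither strict rule
            ([50, 30, 20, 10], 1),  # both oldest >16 above the youngest
            ([80, 79, 78, 77, 76, 75, 74], 4),  # 7+ members
        ],
    )
    def test_rule_examples(self, ages, expected):
        assert household_type(ages) == expected

    def test_agrees_with_literal_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10_000):
            size = int(rng.integers(1, 8))
            ages = rng.integers(0, 101, size).tolist()
            assert household_type(ages) == household_type_oracle(ages), ages

    def test_assign_types_sets_members_and_objects(self, flat_dist):
        pop = _area_pop([(1, 1, 10, 0, 52), (0, 1, 10, 1, 50)])
        out, hhs = assign_households(pop, flat_dist, np.random.default_rng(0))
        typed, hhs = assign_household_types(out, hhs)
        assert hhs[0].hhtype == 0
        assert (typed["hhtype"] == 0).all()

    def test_unset_ages_rejected(self, flat_dist):
        pop = _area_pop([(1, 0, 10, 0, 52)])
        out, hhs = assign_households(pop, flat_dist, np.random.default_rng(0))
        out.loc[0, "age"] = -1
        with pytest.raises(ValueError):
            assign_household_types(out, hhs)
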