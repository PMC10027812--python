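"""Seed building, marginal construction/matching, IPF and integer sampling."""

import numpy as np
import pandas as pd
import pytest

from qisipop import census_io
from qisipop.census_io import AreaProfile
from qisipop.census_model import CATEGORY_SIZES, SEED_AXES
from qisipop.synthesis import (
    ConvergenceError,
    MarginalSet,
    build_raw_marginals,
    build_seed,
    fit_table,
    match_marginals,
    province_distributions,
    qis_sample_table,
    synthesize_area,
)

from .conftest import marginal_counts
from .oracles import ipf_oracle, random_ipf_instance

SEED_SHAPE = tuple(CATEGORY_SIZES[v] for v in SEED_AXES)


def _record(weight=1.0, **attrs):
    base = dict(agegrp=8, sex=0, hdgree=2, lfact=0, hhsize=3, totinc=0,
                prihm=0, weight=weight)
    base.update(attrs)
    return base


class TestBuildSeed:
    def test_single_record_cell_and_smoothing(self):
        df = pd.DataFrame([_record(weight=37.0)])
        seed = build_seed(df)
        assert seed.table[8, 0, 2, 0, 3, 0, 0] == 37.0
        others = seed.table.copy()
        others[8, 0, 2, 0, 3, 0, 0] = seed.eps
        assert (others == seed.eps).all()
        assert seed.eps == pytest.approx(1e-6 * 37.0)

    def test_same_cell_weights_sum(self):
        df = pd.DataFrame([_record(weight=2.0), _record(weight=3.0)])
        assert build_seed(df).table[8, 0, 2, 0, 3, 0, 0] == 5.0

    def test_eps_zero_keeps_zeros(self):
        df = pd.DataFrame([_record()])
        seed = build_seed(df, eps=0.0)
        assert (seed.table > 0).sum() == 1

    def test_no_records(self):
        with pytest.raises(ValueError):
            build_seed(pd.DataFrame(columns=[*SEED_AXES, "weight"]))


# a profile mirroring a published dissemination-area extract: total 1278,
# rounded band counts that miss the total (rounding noise), and
# 15+-only income/degree/labour rows
_EXTRACT_ROWS = [
    ("Population, 2016", 1278, 560, 715),
    ("Private dwellings occupied by usual residents", 440, None, None),
    ("0 to 4 years", 90, 40, 45),
    ("5 to 9 years", 90, 45, 50),
    ("10 to 14 years", 100, 45, 50),
    ("15 to 19 years", 85, 40, 45),
    ("20 to 24 years", 95, 50, 50),
    ("25 to 29 years", 75, 25, 50),
    ("30 to 34 years", 95, 45, 50),
    ("35 to 39 years", 90, 40, 50),
    ("40 to 44 years", 105, 45, 60),
    ("45 to 49 years", 105, 40, 60),
    ("50 to 54 years", 100, 45, 55),
    ("55 to 59 years", 60, 25, 35),
    ("60 to 64 years", 50, 15, 35),
    ("65 to 69 years", 50, 20, 30),
    ("70 to 74 years", 35, 15, 25),
    ("75 to 79 years", 25, 10, 10),
    ("80 to 84 years", 10, 5, 10),
    ("85 years and over", 5, 0, 5),
    ("1 person", 85, None, None),
    ("2 persons", 120, None, None),
    ("3 persons", 85, None, None),
    ("4 persons", 85, None, None),
    ("5 or more persons", 70, None, None),
    ("Under $10,000 (including loss)", 140, None, None),
    ("$10,000 to $19,999", 190, None, None),
    ("$20,000 to $29,999", 100, None, None),
    ("$30,000 to $39,999", 95, None, None),
    ("$40,000 to $49,999", 90, None, None),
    ("$50,000 to $59,999", 70, None, None),
    ("$60,000 to $69,999", 60, None, None),
    ("$70,000 to $79,999", 45, None, None),
    ("$80,000 to $89,999", 45, None, None),
    ("$90,000 to $99,999", 30, None, None),
    ("$100,000 and over", 90, None, None),
    ("No certificate, diploma or degree", 170, None, None),
    ("Secondary (high) school diploma or equivalency certificate", 305, None, None),
    ("Postsecondary certificate, diploma or degree", 540, None, None),
    ("Employed", 690, None, None),
    ("Unemployed", 55, None, None),
    ("Not in the labour force", 270, None, None),
]


@pytest.fixture(scope="module")
def extract_profile():
    rows = pd.DataFrame(
        _EXTRACT_ROWS, columns=["characteristic", "total", "male", "female"]
    ).set_index("characteristic").astype(float)
    return AreaProfile("35204599", rows)


@pytest.fixture(scope="module")
def uniform_prov_dist():
    dist = {v: np.full(CATEGORY_SIZES[v], 1 / CATEGORY_SIZES[v])
            for v in SEED_AXES}
    dist[("agegrp", "sex")] = np.full((18, 2), 1 / 36)
    return dist


class TestRawMarginals:
    def test_under15_augmentations(self, extract_profile, uniform_prov_dist):
        ms = build_raw_marginals(extract_profile, "35204599", uniform_prov_dist)
        # ages 0-14 sum to 280; income band 0 = 140 + 190 + 280
        assert ms.vectors["totinc"][0] == 610
        assert ms.vectors["hdgree"][0] == 450
        assert ms.vectors["lfact"][2] == 550
        assert ms.n == 1278 and ms.households == 440

    def test_households_to_persons_conversion(self, extract_profile,
                                              uniform_prov_dist):
        ms = build_raw_marginals(extract_profile, "35204599", uniform_prov_dist)
        assert list(ms.vectors["hhsize"]) == [85, 240, 255, 340, 350]


class TestMatchMarginals:
    def test_age_vector_adjusted_minimally(self, extract_profile,
                                           uniform_prov_dist):
        raw = build_raw_marginals(extract_profile, "35204599", uniform_prov_dist)
        age_before = raw.vectors["agegrp"].copy()
        deficit = 1278 - age_before.sum()
        assert deficit != 0  # rounded band counts do not hit the total
        matched = match_marginals(raw, uniform_prov_dist)
        age_after = matched.vectors["agegrp"]
        assert age_after.sum() == 1278
        assert np.abs(age_after - age_before).sum() == abs(deficit)
        for var in ("sex", "hhsize", "hdgree", "lfact", "totinc", "prihm"):
            assert matched.vectors[var].sum() == 1278
            assert (matched.vectors[var] >= 0).all()

    def test_joint_reconciled_to_single_axis_vectors(self, extract_profile,
                                                     uniform_prov_dist):
        raw = build_raw_marginals(extract_profile, "35204599", uniform_prov_dist)
        m = match_marginals(raw, uniform_prov_dist)
        assert (m.joint.sum(axis=1) == m.vectors["agegrp"]).all()
        assert (m.joint.sum(axis=0) == m.vectors["sex"]).all()

    def test_idempotent(self, extract_profile, uniform_prov_dist):
        raw = build_raw_marginals(extract_profile, "35204599", uniform_prov_dist)
        m1 = match_marginals(raw, uniform_prov_dist)
        m2 = match_marginals(m1, uniform_prov_dist)
        for var in m1.vectors:
            assert (m1.vectors[var] == m2.vectors[var]).all()
        assert (m1.joint == m2.joint).all()

    def test_zero_vector_gets_province_distribution(self):
        ms = MarginalSet(area="x", n=10, households=4)
        ms.vectors = {
            "agegrp": np.zeros(18, dtype=np.int64),
            "sex": np.array([5, 5]),
            "hhsize": np.array([10, 0, 0, 0, 0]),
            "hdgree": np.array([10, 0, 0]),
            "lfact": np.array([10, 0, 0]),
            "totinc": np.array([10, 0, 0, 0]),
        }
        ms.joint = np.zeros((18, 2))
        dist = {v: None for v in ()}
        prov = {
            "agegrp": np.r_[[0.5, 0.5], np.zeros(16)],
            "sex": np.array([0.5, 0.5]),
            "hhsize": np.array([1.0, 0, 0, 0, 0]),
            "hdgree": np.array([1.0, 0, 0]),
            "lfact": np.array([1.0, 0, 0]),
            "totinc": np.array([1.0, 0, 0, 0]),
            "prihm": np.array([0.6, 0.4]),
        }
        m = match_marginals(ms, prov)
        assert list(m.vectors["agegrp"][:2]) == [5, 5]

    def test_degenerate_area(self):
        ms = MarginalSet(area="x", n=0, households=0)
        with pytest.raises(ValueError):
            match_marginals(ms, {})


class TestIPF:
    def test_independence_seed_closed_form(self):
        table, _ = fit_table(
            np.ones((2, 2)),
            [((0,), np.array([3.0, 1.0])), ((1,), np.array([2.0, 2.0]))],
        )
        assert np.allclose(table, [[1.5, 1.5], [0.5, 0.5]], atol=1e-9)

    def test_consistent_seed_is_fixed_point(self):
        rng = np.random.default_rng(3)
        seed = rng.uniform(0.5, 2.0, size=(3, 4))
        cons = [((0,), seed.sum(axis=1)), ((1,), seed.sum(axis=0))]
        table, sweeps = fit_table(seed, cons)
        assert np.allclose(table, seed, atol=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            seed, cons = random_ipf_instance(rng)
            ours, _ = fit_table(seed, cons, tol=1e-12, max_iter=5000)
            ref = ipf_oracle(seed, cons)
            assert np.abs(ours - ref).max() < 1e-8

    def test_structural_zero_conflict_raises(self):
        seed = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ConvergenceError) as exc:
            fit_table(seed, [((0,), np.array([1.0, 1.0])),
                             ((1,), np.array([1.0, 1.0]))], max_iter=50)
        assert exc.value.residual > 0

    def test_residual_non_increasing_over_sweeps(self):
        rng = np.random.default_rng(5)
        seed, cons = random_ipf_instance(rng, shape=(4, 3, 2))

        residuals: list = []
        fit_table(seed, cons, tol=1e-12, max_iter=500, history=residuals)
        assert len(residuals) > 3
        assert all(b <= a + 1e-12 for a, b in zip(residuals, residuals[1:]))


class TestQisSample:
    CONS_2X2 = [((0,), np.array([3, 1])), ((1,), np.array([2, 2]))]
    TABLE_2X2 = np.array([[1.5, 1.5], [0.5, 0.5]])

    def test_marginals_exact_on_2x2(self):
        rng = np.random.default_rng(0)
        t = qis_sample_table(self.TABLE_2X2, self.CONS_2X2, rng)
        assert t.sum() == 4
        assert (t.sum(axis=1) == [3, 1]).all()
        assert (t.sum(axis=0) == [2, 2]).all()

    def test_zero_population(self):
        rng = np.random.default_rng(0)
        t = qis_sample_table(np.ones((2, 2)),
                             [((0,), np.array([0, 0])), ((1,), np.array([0, 0]))],
                             rng)
        assert (t == 0).all()

    def test_expected_counts_proportional(self):
        """Over many draws the mean table approaches the fractional table."""
        rng = np.random.default_rng(99)
        total = np.zeros((2, 2))
        n_rep = 2000
        for _ in range(n_rep):
            cons = [((0,), np.array([3, 1])), ((1,), np.array([2, 2]))]
            total += qis_sample_table(self.TABLE_2X2, cons, rng)
        mean00 = total[0, 0] / n_rep
        sigma = 0.5 / np.sqrt(n_rep)   # the two feasible tables differ by 1
        assert abs(mean00 - 1.5) < 4 * sigma


class TestSynthesizeArea:
    def test_exact_marginal_match(self, seed_table, profile_reader,
                                  matched_marginals, base_population):
        for area, m in matched_marginals.items():
            got = marginal_counts(base_population, area)
            for var in ("agegrp", "sex", "hdgree", "lfact", "hhsize",
                        "totinc", "prihm"):
                assert (got[var] == m.vectors[var]).all(), (area, var)
            assert (got["joint"] == m.joint).all(), area
            assert got["prihm"][1] == m.households

    def test_suppressed_area_skipped(self, seed_table):
        rng = np.random.default_rng(0)
        out = synthesize_area(seed_table, census_io.SUPPRESSED, "10019999", rng)
        assert out is None

    def test_sequential_indices_and_area(self, base_population, province_areas):
        assert (base_population["index"].to_numpy()
                == np.arange(len(base_population))).all()
        assert set(base_population["area"]) <= set(province_areas)

    def test_eps_zero_stays_on_seed_support(self, big_microdata, big_inputs_dir):
        """With no smoothing, every synthesized person occupies a cell
        observed in the microdata sample."""
        seed0 = build_seed(big_microdata, eps=0.0)
        prov_dist = province_distributions(seed0)
        reader = census_io.ProfileReader(big_inputs_dir / "profile.csv")
        area = reader.areas[0]
        rng = np.random.default_rng(1)
        pop = synthesize_area(seed0, reader.area(area), area, rng,
                              prov_dist=prov_dist)
        support = set(map(tuple, np.argwhere(seed0.table > 0)))
        cells = set(map(tuple, pop[list(SEED_AXES)].to_numpy()))
        assert cells <= support

    def test_eps_zero_with_unsupported_marginal_raises(self, microdata,
                                                       profile_reader,
                                                       province_areas):
        """The sparse small-world sample misses some age-sex cells, so an
        unsmoothed seed conflicts with positive targets and IPF reports it."""
        seed0 = build_seed(microdata, eps=0.0)
        prov_dist = province_distributions(seed0)
        area = province_areas[0]
        rng = np.random.default_rng(1)
        with pytest.raises(ConvergenceError):
            synthesize_area(seed0, profile_reader.area(area), area, rng,
                            prov_dist=prov_dist)
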