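"""Shared fixtures: one small generated world and its pipeline outputs.

Everything is generated at test time from the fixture module; building the
world and synthesizing its ten areas takes a few seconds, so the expensive
objects are session-scoped and reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from qisipop import census_io, fixtures, synthesis


@pytest.fixture(scope="session")
def world_config():
    return fixtures.WorldConfig(seed=1, n_areas=10, mean_area_population=500)


@pytest.fixture(scope="session")
def world(world_config):
    return fixtures.gen_world(world_config)


@pytest.fixture(scope="session")
def inputs_dir(world, world_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("inputs")
    fixtures.emit_inputs(world, world_config, out)
    return out


@pytest.fixture(scope="session")
def microdata(inputs_dir):
    return census_io.read_individual_microdata(
        inputs_dir / "individual_microdata.csv", "10"
    )


@pytest.fixture(scope="session")
def seed_table(microdata):
    return synthesis.build_seed(microdata)


@pytest.fixture(scope="session")
def profile_reader(inputs_dir):
    return census_io.ProfileReader(inputs_dir / "profile.csv")


@pytest.fixture(scope="session")
def province_areas(inputs_dir):
    geo = census_io.read_geography(inputs_dir / "geography.csv")
    return geo.areas_of_province("10")


@pytest.fixture(scope="session")
def base_population(seed_table, profile_reader, province_areas):
    """Step-1 output for the whole fixture province."""
    return synthesis.synthesize_province(
        seed_table, profile_reader, province_areas, master_seed=42
    )


@pytest.fixture(scope="session")
def matched_marginals(seed_table, profile_reader, province_areas):
    """Matched marginal sets for every non-suppressed fixture area."""
    prov_dist = synthesis.province_distributions(seed_table)
    out = {}
    for area in province_areas:
        profile = profile_reader.area(area)
        if profile is census_io.SUPPRESSED:
            continue
        raw = synthesis.build_raw_marginals(profile, area, prov_dist)
        out[area] = synthesis.match_marginals(raw, prov_dist)
    return out


@pytest.fixture(scope="session")
def big_world_config():
    """A full province (~50k persons) whose 2.7% sample covers all
    age × sex cells, making ε = 0 synthesis feasible."""
    return fixtures.WorldConfig(seed=3, n_areas=100, mean_area_population=500)


@pytest.fixture(scope="session")
def big_world(big_world_config):
    return fixtures.gen_world(big_world_config)


@pytest.fixture(scope="session")
def big_inputs_dir(big_world, big_world_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("inputs_big")
    fixtures.emit_inputs(big_world, big_world_config, out)
    return out


@pytest.fixture(scope="session")
def big_microdata(big_inputs_dir):
    return census_io.read_individual_microdata(
        big_inputs_dir / "individual_microdata.csv", "10"
    )


def marginal_counts(population: pd.DataFrame, area: str) -> dict:
    """Observed per-area marginal counts of a synthesized population."""
    from qisipop.census_model import CATEGORY_SIZES

    sub = population[population["area"] == area]
    out = {
        var: np.bincount(sub[var], minlength=CATEGORY_SIZES[var])
        for var in ("agegrp", "sex", "hdgree", "lfact", "hhsize", "totinc", "prihm")
    }
    joint = np.zeros((CATEGORY_SIZES["agegrp"], 2), dtype=np.int64)
    np.add.at(joint, (sub["agegrp"].to_numpy(), sub["sex"].to_numpy()), 1)
    out["joint"] = joint
    return out
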