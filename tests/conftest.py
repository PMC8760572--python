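import numpy as np
import pandas as pd
import pytest

from crvsddm import AgeGrid, RateSchedule, build_life_table
from crvsddm.simulate import ScenarioTruth, make_ddm_scenario

# two-sex study conditions used by the end-to-end checks: a growing
# population with a ~3-year female advantage in e15 and completeness in
# the low-0.8s, observed through two censuses ten years apart
FEMALE_TRUTH = ScenarioTruth(r=0.01, alpha=2.9e-4, beta=0.067, c=0.84,
                             sex="female")
MALE_TRUTH = ScenarioTruth(r=0.01, alpha=3.8e-4, beta=0.066, c=0.80,
                           sex="male")


@pytest.fixture(scope="session")
def grid():
    return AgeGrid.standard(0, 80)


@pytest.fixture(scope="session")
def scenario():
    """Deterministic single-sex scenario factory."""

    def make(**kwargs):
        return make_ddm_scenario(ScenarioTruth(**kwargs))

    return make


@pytest.fixture(scope="session")
def adult_lifetable(grid):
    """Life table from the default female Gompertz schedule (35q15 ~ 0.11)."""
    truth = ScenarioTruth()
    M = truth.hazard(grid.starts + 2.5)
    return build_life_table(RateSchedule(grid=grid, sex="female", M=M))


@pytest.fixture(scope="session")
def two_sex_files(tmp_path_factory):
    """Census and deaths CSVs for the two-sex scenario, plus truth tables."""
    from crvsddm.io import census_pair_to_frame, death_series_to_frame

    tmp = tmp_path_factory.mktemp("two_sex")
    cframes, dframes, true_lt = [], [], {}
    for truth in (FEMALE_TRUTH, MALE_TRUTH):
        data = make_ddm_scenario(truth)
        cframes.append(census_pair_to_frame(data.census_pair))
        dframes.append(death_series_to_frame(data.death_series))
        true_lt[truth.sex] = build_life_table(data.true_rates())
    census = tmp / "census.csv"
    deaths = tmp / "deaths.csv"
    pd.concat(cframes, ignore_index=True).to_csv(census, index=False)
    pd.concat(dframes, ignore_index=True).to_csv(deaths, index=False)
    return {"census": census, "deaths": deaths, "true_lt": true_lt, "dir": tmp}


@pytest.fixture(scope="session")
def registry_series():
    """Published MINSA / RENIEC annual totals as tidy year,sex,count pairs."""
    from crvsddm.io import peru_registry_counts

    df = peru_registry_counts()
    a = df[["year", "sex", "minsa"]].rename(columns={"minsa": "count"})
    b = df[["year", "sex", "reniec"]].rename(columns={"reniec": "count"})
    return a, b
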