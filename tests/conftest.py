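import numpy as np
import pandas as pd
import pytest

from massai import engine, synth
from massai.io import SimulationConfig


@pytest.fixture(scope="session")
def landscape():
    return synth.gen_landscape(60, 60, seed=1)


@pytest.fixture(scope="session")
def survey(landscape):
    hh, plots, _ = synth.gen_survey(60, seed=1, landscape=landscape)
    return hh, plots


@pytest.fixture(scope="session")
def truth_tables():
    tables, decisions = synth.gen_behavioural_truth(1)
    return tables, decisions


@pytest.fixture(scope="session")
def small_world(landscape, survey, truth_tables):
    hh, plots = survey
    cfg = SimulationConfig(T=5, replications=2, master_seed=7,
                           scenarios=("current", "zero"),
                           record_plot_detail=True)
    return engine.build_world(cfg, landscape, hh, plots, truth_tables[0])


@pytest.fixture(scope="session")
def small_output(small_world):
    return engine.run_experiment(small_world)
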