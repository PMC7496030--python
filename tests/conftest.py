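"""Shared fixtures: bundled chains and reusable simulated study results.

The expensive simulated scenarios are session-scoped so the whole suite pays
for each study once.
"""
from __future__ import annotations

import pandas as pd
import pytest

from mampep import bundled_chains, quantify_components
from mampep.msio import read_mzml, write_mzml
from mampep.rollup import attribute_definitions, rollup_attributes
from mampep.simulate import (
    ScenarioConfig,
    build_component_table,
    make_ground_truth,
    simulate_run,
    simulate_study,
)


@pytest.fixture(scope="session")
def chains():
    return bundled_chains()


@pytest.fixture(scope="session")
def table1_truth():
    return make_ground_truth("nist_table1", lab="Ireland")


@pytest.fixture(scope="session")
def table1_components(table1_truth, chains):
    return build_component_table(table1_truth, chains)


@pytest.fixture(scope="session")
def noiseless_run(table1_truth, table1_components):
    """One noiseless full-workbook run of the synthetic mAb digest."""
    scenario = ScenarioConfig(seed=8671, noise_cv=0.0, replicates=1)
    return simulate_run(table1_truth, table1_components, scenario)


@pytest.fixture(scope="session")
def noiseless_quant(noiseless_run, table1_components, tmp_path_factory):
    """Noiseless run quantified after an mzML round trip (full file pipeline)."""
    path = tmp_path_factory.mktemp("runs") / "noiseless.mzML"
    write_mzml(noiseless_run, path)
    run = read_mzml(path)
    return quantify_components(run, table1_components)


@pytest.fixture(scope="session")
def table1_attribute_means(table1_truth, table1_components):
    """Mean attribute values over a noisy triplicate study (CV 0.02, n=3)."""
    scenario = ScenarioConfig(seed=8671, noise_cv=0.02, replicates=3)
    frames = [
        quantify_components(run, table1_components).components
        for run in simulate_study(table1_truth, table1_components, scenario)
    ]
    attr_df = rollup_attributes(pd.concat(frames, ignore_index=True),
                                attribute_definitions(table1_components))
    return attr_df.groupby("attribute")["value"].mean()
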