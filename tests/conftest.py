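import dataclasses

import numpy as np
import pytest

import greyresid as gr


@pytest.fixture(scope="session")
def covid():
    """Corrected case-count fixture (monotone cumulative series)."""
    return gr.covid_fixture("corrected")


@pytest.fixture(scope="session")
def covid_raw():
    return gr.covid_fixture("raw")


@pytest.fixture(scope="session")
def covid_gm(covid):
    """GM(1,1) fitted on the corrected training series, with simulation and residuals."""
    model = gr.fit_gm(covid.train)
    sim = gr.simulate(model, covid.train.size)
    res = gr.residuals(covid.train, sim)
    return model, sim, res


@pytest.fixture(scope="session")
def fast_config():
    """Scaled-down pipeline configuration for the test suite.

    Structure identical to the defaults; only the iteration budgets are
    reduced (1500 training epochs, population 60 over 5 generations) so the
    suite runs in minutes.
    """
    return gr.PipelineConfig(
        net=gr.NetworkConfig(max_epochs=1500),
        pemea=gr.PEMEAConfig(M=60, iterations=5),
        ga=gr.GAConfig(iterations=50),
    )


def with_seed(config, seed, **kwargs):
    return dataclasses.replace(config, seed=seed, **kwargs)
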