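import numpy as np
import pytest

import tracerscreen as ts
from tracerscreen.cli import ProcessingParams, build_demo_truth


@pytest.fixture(scope="session")
def std_ruleset():
    return ts.standard_tracer_ruleset()


@pytest.fixture(scope="session")
def rev_ruleset():
    return ts.reversed_tracer_ruleset()


@pytest.fixture(scope="session")
def small_truth():
    """5 compliant compounds + 5 single-rule decoys, standard approach."""
    return build_demo_truth("standard", 5, 5, seed=7)


@pytest.fixture(scope="session")
def small_run(small_truth):
    return ts.generate_run(small_truth, sample_id="s1")


@pytest.fixture(scope="session")
def open_params():
    """Processing parameters with the rt window opened to the synthetic span."""
    return ProcessingParams(rt_window=(0.0, 1e6))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def gaussian_eic(rt, apex, sigma, height, mz=300.0, ppm=5.0):
    intensity = height * np.exp(-((rt - apex) ** 2) / (2.0 * sigma**2))
    return ts.EIC(target_mz=mz, ppm_window=ppm, rt=np.asarray(rt, float), intensity=intensity)
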