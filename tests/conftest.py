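import numpy as np
import pytest

from placenergy import RunConfig, simulate_run


@pytest.fixture(scope="session")
def default_runs():
    """Ten independent seeds of the reference configuration.

    Shared by the acceptance checks on pipeline scale, locating stability and
    the small-vs-large field contrasts, so the expensive default simulations
    run once per session.
    """
    return {seed: simulate_run(RunConfig(seed=seed)) for seed in range(10)}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config(tmp_path):
    """A fast, fully-featured configuration for plumbing tests."""
    return RunConfig(
        **{"seed": 7, "outdir": str(tmp_path / "run"), "env.n_steps": 200,
           "net.n_cells": 25}
    )
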