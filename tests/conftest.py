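import numpy as np
import pandas as pd
import pytest

from corridorpa.config import RunConfig
from corridorpa.synthetic import CorridorConfig, generate_corridor


@pytest.fixture(scope="session")
def small_corridor():
    """A 160-cell corridor (2.5 km cells) shared across unit tests."""
    cfg = CorridorConfig(cell_size=2500.0, seed=42)
    return generate_corridor(cfg)


@pytest.fixture(scope="session")
def tiny_corridor():
    """A fast few-factor corridor for tests that need many regenerations."""
    cfg = CorridorConfig(
        cell_size=2500.0, seed=7,
        factor_counts={"service": 2, "living": 2, "ecology": 2,
                       "built_env": 2, "socioeconomic": 2},
        redundant_counts={"service": 0, "living": 0, "ecology": 0,
                          "built_env": 0, "socioeconomic": 0})
    return generate_corridor(cfg)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default pipeline run (1000 cells) with artifacts on disk.

    Session-scoped because the end-to-end chain is the expensive part;
    several tests read different aspects of the same run.
    """
    from corridorpa.pipeline import run_all

    outdir = tmp_path_factory.mktemp("run_a")
    cfg = RunConfig(seed=1)
    res = run_all(cfg, outdir=outdir)
    return res, outdir
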