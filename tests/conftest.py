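import pathlib

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from ancestry_burden.synthetic_data import (  # noqa: E402
    SimulationConfig,
    build_panel,
    build_synthetic_kb,
    simulate_all,
)


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory) -> dict:
    """One shared synthetic cohort (seed 11, n=4000) with its derived objects."""
    config = SimulationConfig(seed=11, n_participants=4000)
    outdir = tmp_path_factory.mktemp("sim")
    paths = simulate_all(config, outdir)
    labels_df = pd.read_csv(paths["ancestry"], sep="\t", dtype=str)
    return {
        "config": config,
        "paths": paths,
        "panel": build_panel(config),
        "kb": build_synthetic_kb(config),
        "labels": dict(zip(labels_df["participant_id"], labels_df["ancestry"])),
        "truth": pd.read_csv(paths["truth"], sep="\t"),
    }
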