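import pandas as pd
import pytest

from spotscreen.cli import RunConfig, run_pipeline
from spotscreen.synthetic_data import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        n_isolates=16,
        noise_sigma=0.05,
        frac_cooperative=0.12,
        frac_competitive=0.12,
    )


@pytest.fixture(scope="session")
def tiny_experiment(tiny_config):
    return simulate_experiment(tiny_config)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_experiment, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    tiny_experiment.write_bundle(out)
    return out


@pytest.fixture(scope="session")
def tiny_run(tiny_bundle, tmp_path_factory):
    """Full pipeline output on the tiny synthetic experiment."""
    out = tmp_path_factory.mktemp("run")
    manifest = run_pipeline(RunConfig(bundle_dir=tiny_bundle, out_dir=out))
    return out, manifest


@pytest.fixture(scope="session")
def tiny_interactions(tiny_run) -> pd.DataFrame:
    out, _ = tiny_run
    return pd.read_csv(out / "interactions.csv")
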