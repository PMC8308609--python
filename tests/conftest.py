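import pytest

from anemochory.calibration import launch_records_from_tables
from anemochory.synthetic_data import (
    GeneratorSpec,
    generate_launch_experiment,
    generate_traits,
)


@pytest.fixture(scope="session")
def gen_spec():
    """Generator at the study's default conditions, fixed seed."""
    return GeneratorSpec(seed=42)


@pytest.fixture(scope="session")
def north_traits(gen_spec):
    """Synthetic natural-propagule trait table (n = 70, northern targets)."""
    return generate_traits(gen_spec, n=70, group="north")


@pytest.fixture(scope="session")
def launch_tables(gen_spec):
    return generate_launch_experiment(gen_spec)


@pytest.fixture(scope="session")
def launch_records(launch_tables):
    launch_df, wind_df = launch_tables
    return launch_records_from_tables(launch_df, wind_df)
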