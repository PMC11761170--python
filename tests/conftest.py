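import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The hand-authored 2-group, 10-individual micro dataset."""
    from apesoc import synthetic_data

    d = tmp_path_factory.mktemp("fixture_small")
    path, truth = synthetic_data.fixture_small(d)
    return path, truth


@pytest.fixture(scope="session")
def fixture_pipeline(fixture_dir):
    """Loaded registry, events, scans and node set of the micro dataset."""
    from apesoc import obs_data

    path, truth = fixture_dir
    registry, events, scans, covariates = obs_data.validate_dataset(path)
    nodes = obs_data.derive_node_set(registry)
    return registry, events, scans, covariates, nodes, truth


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """One generated study at the default (full-scale) configuration."""
    from apesoc import obs_data, synthetic_data

    d = tmp_path_factory.mktemp("default_study")
    cfg = synthetic_data.SimConfig(seed=20240301)
    path, truth = synthetic_data.generate_study(cfg, d)
    registry, events, scans, covariates = obs_data.validate_dataset(path)
    nodes = obs_data.derive_node_set(registry)
    return cfg, registry, events, scans, covariates, nodes, truth


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A reduced-scale generated study for fast structural checks."""
    from apesoc import obs_data, synthetic_data

    d = tmp_path_factory.mktemp("small_study")
    cfg = synthetic_data.SimConfig(seed=11, months=12, scans_per_month=25)
    path, truth = synthetic_data.generate_study(cfg, d)
    registry, events, scans, covariates = obs_data.validate_dataset(path)
    nodes = obs_data.derive_node_set(registry)
    return cfg, registry, events, scans, covariates, nodes, truth
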