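import pytest

from crossreg.pipeline_cli import run_all
from crossreg.synthetic_data import SimulationConfig, generate_panel


@pytest.fixture(scope="session")
def panel(tmp_path_factory):
    """One default synthetic panel shared by read-only tests."""
    root = tmp_path_factory.mktemp("panel") / "p"
    return generate_panel(SimulationConfig(seed=7), root)


@pytest.fixture(scope="session")
def pipeline_run(panel, tmp_path_factory):
    """Full pipeline run on the shared panel: (tables, out_dir)."""
    out = tmp_path_factory.mktemp("run") / "r"
    tables = run_all(panel.run_config, out)
    return tables, out
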