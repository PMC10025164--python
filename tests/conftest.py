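import pytest

import lysoenrich as le


@pytest.fixture(scope="session")
def default_study():
    """One default six-line study, shared across tests (seed 1)."""
    return le.simulate_study(le.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """Full pipeline executed on the default study (same seed as above)."""
    out = tmp_path_factory.mktemp("pipeline")
    return le.run_simulated(le.SimulationConfig(seed=1), out)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Directory with the hand-computed unit fixtures."""
    out = tmp_path_factory.mktemp("fixtures")
    le.emit_fixtures(out)
    return out


@pytest.fixture()
def simple_design():
    """One cell line, four replicates with label switching (L, L, H, H)."""
    return le.StudyDesign(
        cell_lines=("L1",),
        replicates_per_line=4,
        channel_of_spions={
            ("L1", 1): "light",
            ("L1", 2): "light",
            ("L1", 3): "heavy",
            ("L1", 4): "heavy",
        },
    )
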