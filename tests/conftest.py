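import pytest
from hypothesis import HealthCheck, settings

from amomarker import (PanelConfig, design_marker_panel,
                       find_diagnostic_snps, generate_monitoring_panel,
                       generate_reference_panel)
from amomarker.monitoring import run_authentication
from amomarker.synthetic_data import INGROUP_SPECIES

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_panel():
    """The default reference panel (seed 42), shared across the suite."""
    return generate_reference_panel(PanelConfig(seed=42))


@pytest.fixture(scope="session")
def its_snps(default_panel):
    return find_diagnostic_snps(default_panel["ITS"], INGROUP_SPECIES)


@pytest.fixture(scope="session")
def multiplex_panel(default_panel):
    return design_marker_panel(default_panel["ITS"])


@pytest.fixture(scope="session")
def monitoring_panel(default_panel):
    return generate_monitoring_panel(default_panel)


@pytest.fixture(scope="session")
def monitoring_report(default_panel, multiplex_panel, monitoring_panel):
    return run_authentication(default_panel["ITS"], multiplex_panel,
                              monitoring_panel.records,
                              monitoring_panel.manifest)
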