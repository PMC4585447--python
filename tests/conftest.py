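import pytest

from cftrscreen.simulate import (AmpliconPanel, SimulationConfig, build_catalog,
                                 build_reference, design_panel)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1, n_samples=4)


@pytest.fixture(scope="session")
def reference(default_config):
    """(model, sequence) for the default toy gene."""
    return build_reference(default_config)


@pytest.fixture(scope="session")
def model(reference):
    return reference[0]


@pytest.fixture(scope="session")
def seq(reference):
    return reference[1]


@pytest.fixture(scope="session")
def panel(model):
    return design_panel(model)


@pytest.fixture(scope="session")
def catalog(model, seq, panel):
    return build_catalog(model, seq, panel)


@pytest.fixture(scope="session")
def tract_subpanel(model, panel):
    """Single-amplicon panel over the TG-T tract: cheap spanning-read
    simulation for tract genotyping tests."""
    tract = model.tgt_tract
    region = tract.region
    amp = next(a for a in panel.amplicons
               if a.insert[0] <= region[0] and region[1] <= a.insert[1])
    return AmpliconPanel(amplicons=(amp,), target_regions=(amp.insert,))
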