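import numpy as np
import pytest

from tme_spectra.core_data import DEFAULT_PANEL, Marker, PanelConfig


@pytest.fixture(scope="session")
def panel3() -> PanelConfig:
    """Tiny 3-channel panel for I/O and geometry tests."""
    return PanelConfig(
        markers=[
            Marker("DNA", 0, "nuclear"),
            Marker("CK", 1, "lineage"),
            Marker("CD3", 2, "lineage"),
        ],
        gate_thresholds={"CK": 1.0, "CD3": 1.0},
        pixel_size_um=1.0,
    )


@pytest.fixture(scope="session")
def default_panel() -> PanelConfig:
    return DEFAULT_PANEL


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
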