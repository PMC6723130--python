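import numpy as np
import pytest

from umivar.experiments import synthetic_panel
from umivar.panel import Probe, ProbePanel


@pytest.fixture(scope="session")
def toy_panel() -> ProbePanel:
    """Two small probes with hand-checkable sequences."""
    return ProbePanel(
        [
            Probe("pA", "chr1", 100, 131, "+", "ACGTACGTACGTACGTACGTACGTACGTACGT"),
            Probe("pB", "chr2", 500, 531, "-", "TTTTCCCCGGGGAAAATTTTCCCCGGGGAAAA"),
        ],
        genome_label="toy",
    )


@pytest.fixture(scope="session")
def sim_panel() -> ProbePanel:
    """One random 126 bp probe: the standard 150 bp-read layout."""
    return synthetic_panel(n_probes=1, region_length=126, seed=2024)


@pytest.fixture(scope="session")
def panel32() -> ProbePanel:
    return synthetic_panel(n_probes=32, region_length=126, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def panel_file(tmp_path, sim_panel):
    path = tmp_path / "panel.tsv"
    sim_panel.write(path)
    return path
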