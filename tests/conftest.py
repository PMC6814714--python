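import pytest

from cysfoot.sequence_io import ProteinRecord
from cysfoot.synthetic_data import (
    ALPHA_E_CATENIN_CYS_SITES,
    SimulationDesign,
    make_toy_protein,
)


@pytest.fixture(scope="session")
def toy_protein() -> ProteinRecord:
    """Deterministic 906-residue protein with the 12 catenin cysteine sites."""
    return make_toy_protein(906, ALPHA_E_CATENIN_CYS_SITES, seed=11)


@pytest.fixture
def two_condition_design(toy_protein) -> SimulationDesign:
    """Two conditions differing at two sites; modest depth for fast tests."""
    probs_a = {p: 0.3 for p in toy_protein.cys_positions}
    probs_b = dict(probs_a)
    probs_b[438] = 0.7
    probs_b[526] = 0.6
    return SimulationDesign(
        protein=toy_protein,
        site_probs={"unsheared": probs_a, "sheared": probs_b},
        replicates=5,
        mean_depth=60.0,
        localization_failure_rate=0.1,
        seed=42,
    )
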