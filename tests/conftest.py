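import pytest

from erf_survey import synthetic_data as sd
from erf_survey.io_formats import ProteinRecord

AP2_ERF_SEGMENT = "GVRRRPWGKWAAEIRDPAKKG"
AP2_DREB_SEGMENT = "GVRRRPWGKWSAEVGEPAKKG"


@pytest.fixture(scope="session")
def small_proteome():
    """120-protein synthetic proteome with planted architectures."""
    records, rows, truth = sd.generate_proteome(120, seed=11)
    return records, rows, truth


@pytest.fixture(scope="session")
def standin_set():
    """Synthetic stand-in for the 76-member deposited ERF set."""
    return sd.zmerf_standin(seed=11)


@pytest.fixture()
def erf_protein():
    return ProteinRecord("erf1", "M" * 100 + AP2_ERF_SEGMENT + "M" * 179)
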