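import pytest

from salixtw import datasets
from salixtw.stem import attach_tension_volumes, build_segments
from salixtw.synthetic import DEFAULT_PALETTE


@pytest.fixture(scope="session")
def tora_profile():
    return datasets.tora_profile()


@pytest.fixture(scope="session")
def bjorn_profile():
    return datasets.bjorn_profile()


@pytest.fixture(scope="session")
def tora_segments(tora_profile):
    return attach_tension_volumes(
        build_segments(tora_profile), datasets.tora_tension_volumes()
    )


@pytest.fixture(scope="session")
def bjorn_segments(bjorn_profile):
    return attach_tension_volumes(
        build_segments(bjorn_profile), datasets.bjorn_tension_volumes()
    )


@pytest.fixture(scope="session")
def stain_palette():
    return {
        "tw": DEFAULT_PALETTE["tw"],
        "section_other": DEFAULT_PALETTE["normal_wood"],
    }
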