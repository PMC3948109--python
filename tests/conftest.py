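import numpy as np
import pytest

from tag_elucidator import AdductSpec, FattyAcyl, TagStructure


@pytest.fixture
def sodium():
    return AdductSpec("Na")


@pytest.fixture
def potassium():
    return AdductSpec("K")


@pytest.fixture
def lithium():
    return AdductSpec("Li")


@pytest.fixture
def oleic_tag():
    """TG(18:1(n-9,cis)/5:1(n-2)/5:1(n-2)) with the long chain at sn-1."""
    return TagStructure(
        acyls=(
            FattyAcyl(18, 1, (9,), ("cis",)),
            FattyAcyl(5, 1, (2,), branched=True),
            FattyAcyl(5, 1, (2,), branched=True),
        ),
        sn_assignment="long-chain-at-sn-1/3",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
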