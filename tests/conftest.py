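import pytest

from ooadrift import table1_fixture


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def table1_oriented(table1):
    """Fixture with rs1535882 re-expressed in the regressed allele.

    The printed frequency column for rs1535882 counts the allele
    complementary to the one the distance regression was reported on (the
    slope magnitude matches with the sign flipped, and
    arcsin(sqrt(1-p)) = pi/2 - arcsin(sqrt(p)) flips a slope sign exactly).
    """
    return table1.complemented(["rs1535882"])
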