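from fractions import Fraction

import pytest

from goalpursuit import TaskSpec, backward_induction, build_design


@pytest.fixture(scope="session")
def consultant_spec() -> TaskSpec:
    """Two projects of three tasks each, ten weekly stages, p = (0.8, 0.3)."""
    return TaskSpec("approach", 10, (3, 3), Fraction(4, 5), Fraction(3, 10))


@pytest.fixture(scope="session")
def consultant_table(consultant_spec):
    return backward_induction(consultant_spec, exact=True)


@pytest.fixture(scope="session")
def full_design():
    """The calibrated 24-condition factorial (shared across tests)."""
    return build_design()
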