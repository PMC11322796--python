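from datetime import date, datetime

import pytest

from weartrial.core import Study
from weartrial.fixtures import phase1_questionnaire, phase2_questionnaire


@pytest.fixture
def study() -> Study:
    return Study(id_prefix="SM")


@pytest.fixture
def t0() -> datetime:
    return datetime(2020, 1, 6, 9, 0)


@pytest.fixture
def d0() -> date:
    return date(2020, 3, 1)


@pytest.fixture
def q1():
    return phase1_questionnaire()


@pytest.fixture
def q2():
    return phase2_questionnaire()
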