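import pytest

from scirapnano import load_builtin_bank, load_case_study_fixture
from scirapnano.bank import Criterion, CriteriaBank, Part, RatingScale


@pytest.fixture(scope="session")
def bank_v2():
    return load_builtin_bank("2.0")


@pytest.fixture(scope="session")
def bank_v1():
    return load_builtin_bank("1.0-skeleton")


@pytest.fixture(scope="session")
def case_study():
    return load_case_study_fixture()


def make_tiny_bank(n_rq: int = 3, n_mq: int = 2, n_rel: int = 1, version: str = "tiny") -> CriteriaBank:
    """A minimal hand-built bank for unit tests that need full control."""

    def crit(part, i, **kw):
        scale = RatingScale.RELEVANCE if part is Part.REL else RatingScale.QUALITY
        return Criterion(id=i, part=part, section="S", text=f"criterion {part.value}{i}",
                         rating_scale=scale, **kw)

    return CriteriaBank(
        tool_name="tiny",
        version=version,
        criteria={
            Part.RQ: tuple(crit(Part.RQ, i) for i in range(1, n_rq + 1)),
            Part.MQ: tuple(crit(Part.MQ, i) for i in range(1, n_mq + 1)),
            Part.REL: tuple(crit(Part.REL, i) for i in range(1, n_rel + 1)),
        },
    )


@pytest.fixture
def tiny_bank():
    return make_tiny_bank()
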