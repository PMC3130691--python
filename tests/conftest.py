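import pytest

from drbank.model import (
    CharSpan,
    RelationRecord,
    SenseLabel,
    SpanSet,
    build_class_mapping,
    build_taxonomy,
)


@pytest.fixture(scope="session")
def taxonomy():
    return build_taxonomy()


@pytest.fixture(scope="session")
def mapping():
    return build_class_mapping()


def make_explicit(
    conn=(50, 54),
    arg1=(0, 40),
    arg2=(55, 90),
    sense1=SenseLabel("Conjunction"),
    sense2=None,
    **kw,
):
    return RelationRecord(
        rel_type="Explicit",
        conn_spans=SpanSet([CharSpan(*conn)]),
        arg1_spans=SpanSet([CharSpan(*arg1)]),
        arg2_spans=SpanSet([CharSpan(*arg2)]),
        sense1=sense1,
        sense2=sense2,
        **kw,
    )


@pytest.fixture
def doc_text():
    return "x" * 200
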