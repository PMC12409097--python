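import pytest

from aspenrich.fragments import default_registry, lookup


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def frag_by_label(registry):
    def _get(label, analyte="aspartic acid 3TMS"):
        return lookup(registry, analyte, label)

    return _get


@pytest.fixture(scope="session")
def positional_fragments(frag_by_label):
    """The four-coverage fragment set feeding the positional equations."""
    return {
        "E1234": frag_by_label(349),
        "E234": frag_by_label(232),
        "E23": frag_by_label(216),
        "E34": frag_by_label(203),
    }
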