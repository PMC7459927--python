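import pytest

from waistload import standard_profile


@pytest.fixture(scope="session")
def std():
    """Standard 50th-percentile Chinese male profile (published constants)."""
    return standard_profile()


@pytest.fixture(scope="session")
def std_derived():
    """Same worker, constants recomputed unrounded from the segment table."""
    return standard_profile(mode="derived")
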