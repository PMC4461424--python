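import os
import sys

import pytest

sys.path.insert(0, os.path.dirname(__file__))

from mockotu import pipeline as pl  # noqa: E402


@pytest.fixture(scope="session")
def fixtures():
    """The canonical fixture set (36-nt indel pair, 47:43 alleles, ...)."""
    return pl.standard_fixtures(seed=11)
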