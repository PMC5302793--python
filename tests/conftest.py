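import random

import pytest

from paleochron import tree_from_string


@pytest.fixture
def rng():
    return random.Random(20260101)


@pytest.fixture
def three_tip_basic():
    """The canonical worked example: ((A,B),C) with ages 10/20/30."""
    from paleochron import calibrate_basic
    tree = tree_from_string("((A,B),C);")
    return calibrate_basic(tree, {"A": 10.0, "B": 20.0, "C": 30.0})
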