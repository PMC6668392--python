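import numpy as np
import pytest

import patchdyn as pdn

BOTH_KINDS = (pdn.HEX6, pdn.SQUARE4)


@pytest.fixture(params=BOTH_KINDS)
def kind(request):
    return request.param


def random_ls(kind, side, p, rng):
    """Random landscape helper used across the suite."""
    return pdn.random_landscape(pdn.Lattice(kind, side), p, rng)
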