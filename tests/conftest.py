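import numpy as np
import pytest

from divrates import read_newick


@pytest.fixture
def cherry_tree():
    """((A:1,B:1):1,C:2); root at 2 Ma, ultrametric."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def six_tip_two_class_tree():
    """Ultrametric 6-tip tree used for hand-enumerated slicing checks.

    Root at 20 Ma; left clade (a1,a2,a3) with crown structure at 12/5 Ma,
    right clade (b1,b2,b3) at 10/4 Ma.
    """
    return read_newick(
        "(((a1:5,a2:5):7,a3:12):8,((b1:4,b2:4):6,b3:10):10);"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
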