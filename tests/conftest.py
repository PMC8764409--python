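import io

import numpy as np
import pandas as pd
import pytest
import skbio


@pytest.fixture
def small_table():
    """3 samples x 4 taxa with simple integer counts."""
    return pd.DataFrame(
        [[5, 0, 3, 2], [1, 1, 0, 8], [0, 4, 4, 2]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3", "t4"],
    )


@pytest.fixture
def star_tree():
    """Four tips, each on a branch of length 1 from the root."""
    return skbio.TreeNode.read(io.StringIO("(t1:1,t2:1,t3:1,t4:1):0;"))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_tree(newick: str) -> skbio.TreeNode:
    return skbio.TreeNode.read(io.StringIO(newick))
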