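import numpy as np
import pandas as pd
import pytest

from chronosoil.io import read_newick


@pytest.fixture
def balanced_four_tip_tree():
    """((A:1,B:1):1,(C:1,D:1):1); — patristic A-B = 2, A-C = 4."""
    return read_newick(["((A:1,B:1):1,(C:1,D:1):1);"])


@pytest.fixture
def star_four_tip_tree():
    """Star phylogeny: every tip pair at distance 2."""
    return read_newick(["(A:1,B:1,C:1,D:1);"])


@pytest.fixture
def toy_table():
    return pd.DataFrame(
        [[5, 3, 0, 2], [0, 1, 7, 2], [4, 4, 1, 1]],
        index=["S1", "S2", "S3"],
        columns=["A", "B", "C", "D"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
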