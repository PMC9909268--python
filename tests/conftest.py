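import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from soilcomm import simulate as sim


@pytest.fixture(scope="session")
def toy_tree():
    """Fixed 4-tip tree: ((A:1,B:2):0.5,(C:1.5,D:0.5):1);"""
    return TreeNode.read(["((A:1,B:2):0.5,(C:1.5,D:0.5):1)root;"])


@pytest.fixture(scope="session")
def star_tree_5():
    """Equidistant star: all tip-to-tip patristic distances equal 2."""
    return TreeNode.read(["(A:1,B:1,C:1,D:1,E:1)root;"])


@pytest.fixture(scope="session")
def small_design():
    return sim.generate_design(2, ["CK", "N"], ["A", "B"], ["summer", "autumn"])


@pytest.fixture(scope="session")
def random_table():
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 50, size=(6, 8))
    counts[0, :] = [3, 0, 1, 0, 5, 0, 0, 2]
    return pd.DataFrame(
        counts,
        index=[f"S{i}" for i in range(6)],
        columns=[f"ASV_{j + 1}" for j in range(8)],
    )
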