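import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import leukomap as lm


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_ct():
    """4 cells x 3 genes with values straddling the background level."""
    data = pd.DataFrame(
        [[25.0, 28.0, 31.4],
         [20.0, 27.5, 28.0],
         [26.0, 22.0, 24.0],
         [28.0, 28.0, 14.0]],
        index=["c1", "c2", "c3", "c4"],
        columns=["gA", "gB", "gC"],
    )
    return lm.CtMatrix(data)


@pytest.fixture
def chain_tree():
    """Three-node chain A - B - C with 2-gene centroids."""
    cent = pd.DataFrame(
        [[0.0, 0.0], [2.0, 2.0], [4.0, 4.0]],
        index=[0, 1, 2], columns=["g1", "g2"],
    )
    return lm.ReferenceTree(centroids=cent, edges=[(0, 1), (1, 2)],
                            branch={0: "hsc", 1: "gmp", 2: "dc"})


@pytest.fixture
def zero_noise_dataset():
    """Default-size synthetic dataset in the noise-free limit."""
    spec = lm.SyntheticSpec(seed=11, noise_sd=0.0)
    return spec, lm.generate_dataset(spec)
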