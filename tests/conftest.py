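import numpy as np
import pandas as pd
import pytest

from ribodrop.containers import CountMatrix


def make_count_matrix(ctl: np.ndarray, mut: np.ndarray) -> CountMatrix:
    """Build a CountMatrix from explicit per-group count arrays (genes x n)."""
    ctl = np.atleast_2d(ctl)
    mut = np.atleast_2d(mut)
    genes = [f"g{i}" for i in range(ctl.shape[0])]
    samples = [f"c{j}" for j in range(ctl.shape[1])] + [f"m{j}" for j in range(mut.shape[1])]
    counts = pd.DataFrame(np.hstack([ctl, mut]), index=genes, columns=samples)
    design = pd.Series(
        ["control"] * ctl.shape[1] + ["mutant"] * mut.shape[1], index=samples
    )
    return CountMatrix(counts, design)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
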