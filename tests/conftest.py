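import numpy as np
import pytest

from dcgrn import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240214)


@pytest.fixture
def small_expression(rng):
    """8 samples x 4 genes with one regulator/target pair and two decoys."""
    x = rng.uniform(0, 2, size=8)
    y = x**2 / (1 + x**2)
    decoy1 = rng.normal(size=8)
    decoy2 = rng.normal(size=8)
    return ExpressionMatrix(
        values=np.column_stack([x, y, decoy1, decoy2]),
        gene_names=["reg", "tgt", "d1", "d2"],
    )
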