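import numpy as np
import pandas as pd
import pytest

from mirmint import CountMatrix, SampleMetadata


@pytest.fixture
def tiny_counts() -> CountMatrix:
    return CountMatrix(
        pd.DataFrame(
            [[5, 0], [1, 3]],
            index=["miR-a", "miR-b"],
            columns=["S1", "S2"],
            dtype=np.int64,
        )
    )


@pytest.fixture
def six_sample_meta() -> SampleMetadata:
    return SampleMetadata(
        ("c1", "c2", "c3", "r1", "r2", "r3"),
        ("control",) * 3 + ("restricted",) * 3,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240307)
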