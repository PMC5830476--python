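import numpy as np
import pandas as pd
import pytest

from wfstox import ADELabelMatrix, FeatureMatrix, GeneratorConfig, generate


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset drawn at the generator's default study conditions."""
    return generate(GeneratorConfig(seed=11))


@pytest.fixture
def tiny_features():
    data = pd.DataFrame(
        [[1, 0, 1], [0, 1, np.nan], [1, 1, 0], [0, 0, 0]],
        index=["c1", "c2", "c3", "c4"],
        columns=["f1", "f2", "f3"],
    )
    return FeatureMatrix(data, "assay")


@pytest.fixture
def tiny_labels():
    data = pd.DataFrame(
        [[1, 0], [1, 1], [0, 1], [0, 0]],
        index=["c1", "c2", "c3", "c4"],
        columns=["ade1", "ade2"],
    )
    return ADELabelMatrix(data)
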