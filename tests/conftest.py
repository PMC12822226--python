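import numpy as np
import pandas as pd
import pytest

from sdcfe import OmicsMatrix


@pytest.fixture
def two_class_toy() -> tuple[OmicsMatrix, pd.Series]:
    """One gene, two balanced classes: A=[0,2], B=[4,6]."""
    m = OmicsMatrix(
        values=pd.DataFrame({"g1": [0.0, 2.0, 4.0, 6.0]},
                            index=["s1", "s2", "s3", "s4"])
    )
    y = pd.Series(["A", "A", "B", "B"], index=m.sample_ids)
    return m, y


@pytest.fixture
def random_matrix() -> OmicsMatrix:
    rng = np.random.default_rng(11)
    vals = pd.DataFrame(
        rng.normal(5, 2, size=(20, 8)),
        index=[f"s{i}" for i in range(20)],
        columns=[f"g{j}" for j in range(8)],
    )
    return OmicsMatrix(values=vals)


def make_matrix(arr, sample_ids=None, feature_ids=None, tag="other") -> OmicsMatrix:
    arr = np.asarray(arr, dtype=float)
    sample_ids = sample_ids or [f"s{i}" for i in range(arr.shape[0])]
    feature_ids = feature_ids or [f"g{j}" for j in range(arr.shape[1])]
    return OmicsMatrix(
        values=pd.DataFrame(arr, index=sample_ids, columns=feature_ids),
        omics_tag=tag,
    )
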