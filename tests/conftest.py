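import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from stagescreen.data_model import (
    ExpressionMatrix,
    GeneCatalog,
    ScreenConfig,
    StageAxis,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def axis():
    return StageAxis()


@pytest.fixture
def small_matrix(axis):
    """3 genes x 7 stages with assorted magnitudes."""
    data = pd.DataFrame(
        [
            [0.0, 1.5, 3.25, 10.0, 55.125, 20.0, 5.0],
            [100.0, 80.0, 60.0, 40.0, 20.0, 10.0, 5.0],
            [7.0, 7.0, 7.0, 7.0, 7.0, 7.0, 7.0],
        ],
        index=["g1", "g2", "g3"],
        columns=list(axis.stages),
    )
    return ExpressionMatrix("AC", axis, data)


@pytest.fixture
def toy_screen_setup(axis):
    """2 TFs x 3 structural genes: TF1 tracks SG1/SG2, mirrors SG3; TF2 flat."""
    sg1 = np.array([5.0, 8, 12, 20, 30, 44, 60])
    sg2 = 2.0 * sg1
    sg3 = 70.0 - sg1                      # exact negative affine image
    tf1 = sg1.copy()
    tf2 = np.full(7, 10.0)
    data = pd.DataFrame(
        np.vstack([tf1, tf2, sg1, sg2, sg3]),
        index=["TF1", "TF2", "SG1", "SG2", "SG3"],
        columns=list(axis.stages),
    )
    m = ExpressionMatrix("AC", axis, data)
    catalog = GeneCatalog(pathways={"ascorbate": ["SG1", "SG2", "SG3"]},
                          tf_ids=["TF1", "TF2"],
                          tf_family={"TF1": "MYB", "TF2": "NAC"})
    return m, catalog


@pytest.fixture
def default_cfg():
    return ScreenConfig()
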