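import numpy as np
import pandas as pd
import pytest

from cortexscore import AnalysisConfig, preset, simulate_cohort_study
from cortexscore.grouping import GroupWindows

# 5 vertices x 9 images, values chosen away from 0.2 mm bin boundaries
TOY_VALUES = np.array(
    [
        [2.53, 2.47, 2.61, 2.37, 2.33, 2.45, 2.11, 2.17, 2.29],
        [2.91, 2.83, 2.77, 2.69, 2.75, 2.63, 2.51, 2.57, 2.43],
        [2.05, 2.13, 2.09, 2.27, 2.21, 2.15, 2.39, 2.31, 2.47],
        [2.65, 2.59, 2.71, 2.55, 2.49, 2.67, 2.73, 2.81, 2.87],
        [2.35, 2.41, 2.29, 2.19, 2.25, 2.07, 1.93, 1.99, 2.03],
    ]
)
TOY_IMAGES = ["CN1", "CN2", "CN3", "MCI1", "MCI2", "MCI3", "AD1", "AD2", "AD3"]
TOY_VERTICES = ["v1", "v2", "v3", "v4", "v5"]


@pytest.fixture()
def toy_matrix() -> pd.DataFrame:
    return pd.DataFrame(TOY_VALUES.copy(), index=TOY_VERTICES, columns=TOY_IMAGES)


@pytest.fixture()
def toy_metadata() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "image_id": TOY_IMAGES,
            "subject_id": [i.rstrip("123") + str(j % 3) for j, i in enumerate(TOY_IMAGES)],
            "cohort": ["CN"] * 3 + ["MCI"] * 3 + ["AD"] * 3,
            "sex": ["F"] * 9,
            "age": [72.0] * 9,
            "acquisition_label": ["MPRAGE"] * 9,
        }
    )


@pytest.fixture()
def single_window() -> GroupWindows:
    return GroupWindows((("A", 0.0, 6.0),))


@pytest.fixture(scope="session")
def separated_study():
    """The 'separated' preset at seed 1: 300 vertices, 100 images/cohort."""
    return simulate_cohort_study(preset("separated", seed=1))


@pytest.fixture(scope="session")
def separated_fit(separated_study):
    from cortexscore import fit_pipeline

    matrix, metadata, _truth = separated_study
    return fit_pipeline(matrix, metadata, AnalysisConfig())
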