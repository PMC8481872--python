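import numpy as np
import pandas as pd
import pytest

import metabotime as mt


@pytest.fixture(scope="session")
def mimic():
    """The packaged study-mimic dataset: 125 features, 2 x 3 x 5 design."""
    cfg = mt.study_mimic_config(seed=42)
    matrix, design, truth = mt.generate_dataset(cfg)
    return cfg, matrix, design, truth


@pytest.fixture(scope="session")
def mimic_normalized(mimic):
    _, matrix, design, truth = mimic
    normalized, info = mt.normalize_matrix(matrix, method="auto")
    return normalized, design, truth, info


@pytest.fixture()
def toy():
    """Hand-checkable dataset: 1 feature, k=2 timepoints, 2 replicates per arm.

    Untreated profiles (1, 2) and (3, 6); treated profiles (2, 5) and (4, 7).
    By hand: condition means are (2, 4) and (3, 6), so d = (1, 2); the summed
    outer products of residuals are [[2, 4], [4, 8]] + [[2, 2], [2, 2]], and
    with f = 2 the pooled covariance is S = [[2, 3], [3, 5]].
    """
    design = mt.StudyDesign(pd.DataFrame({
        "sample_id": ["u_t3_r1", "u_t3_r2", "u_t12_r1", "u_t12_r2",
                      "t_t3_r1", "t_t3_r2", "t_t12_r1", "t_t12_r2"],
        "condition": ["untreated"] * 4 + ["treated"] * 4,
        "time_h": [3, 3, 12, 12, 3, 3, 12, 12],
        "replicate": [1, 2, 1, 2, 1, 2, 1, 2],
    }))
    values = np.array([[1, 3, 2, 6, 2, 4, 5, 7]], dtype=float)
    matrix = mt.IntensityMatrix(
        feature_ids=["M1"], sample_ids=design.sample_ids, values=values
    )
    expected_d = np.array([1.0, 2.0])
    expected_S = np.array([[2.0, 3.0], [3.0, 5.0]])
    return matrix, design, expected_d, expected_S
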