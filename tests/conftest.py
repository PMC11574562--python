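import numpy as np
import pandas as pd
import pytest

import metaboscreen as ms


@pytest.fixture(scope="session")
def small_library():
    return ms.generate_library(60, 0.2, seed=1)


@pytest.fixture(scope="session")
def small_cohort(small_library):
    cfg = ms.CohortConfig(
        n_cancer_per_type={"breast": 20, "lung": 20}, n_normal=40,
        n_metabolites=60, n_signature=8, effect_size=0.8, seed=7)
    peaks, meta, truth = ms.generate_cohort(cfg, small_library)
    return cfg, peaks, meta, truth


@pytest.fixture(scope="session")
def small_matrix(small_cohort, small_library):
    _, peaks, meta, truth = small_cohort
    anchors = ms.detect_vlm_anchors(peaks, ppm_window=45, min_presence=0.7)
    corrected = ms.correct_all(peaks, anchors)
    return ms.build_feature_matrix(corrected, small_library)


def make_matrix(values, feature_ids=None, sample_ids=None, transform_log=None):
    """Small helper: raw ndarray/list -> FeatureMatrix with simple ids."""
    arr = np.asarray(values, float)
    feature_ids = feature_ids or [f"M{j+1:02d}" for j in range(arr.shape[1])]
    sample_ids = sample_ids or [f"S{i+1:02d}" for i in range(arr.shape[0])]
    df = pd.DataFrame(arr, index=sample_ids, columns=feature_ids)
    df.index.name = "sample_id"
    return ms.FeatureMatrix(df, transform_log=list(transform_log or []))
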