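import numpy as np
import pytest

from ictalkit.features import FeatureConfig, build_feature_matrix
from ictalkit.preprocess import SegmentSet, preprocess_recording
from ictalkit.synth import SynthParams, generate_cohort_recordings


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_params():
    """A small but fully structured world: 3 positive + 1 free subject,
    6 channels, 120 s sessions, 1 seizure of ~20 s per positive subject."""
    return SynthParams(
        n_subjects=3, n_seizure_free=1, session_length_s=120.0, n_channels=6,
        seizures_per_subject=1, seizure_len_s=(18.0, 22.0),
        focus_channels=["T7-P7", "FP1-F3"], seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_params):
    recordings, intervals = generate_cohort_recordings(tiny_params)
    return recordings, intervals


@pytest.fixture(scope="session")
def tiny_feature_matrices(tiny_params, tiny_cohort):
    """(positive FeatureMatrix, free FeatureMatrix, intervals) at small scale."""
    recordings, intervals = tiny_cohort
    positive_ids = {f"sub{i + 1:02d}" for i in range(tiny_params.n_subjects)}
    pos_sets, free_sets = [], []
    for rec in recordings:
        segs = preprocess_recording(rec, intervals)
        (pos_sets if rec.subject_id in positive_ids else free_sets).append(segs)
    cfg = FeatureConfig()
    pos_fm = build_feature_matrix(SegmentSet.concatenate(pos_sets), cfg)
    free_fm = build_feature_matrix(SegmentSet.concatenate(free_sets), cfg)
    return pos_fm, free_fm, intervals
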