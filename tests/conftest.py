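import numpy as np
import pytest

import swallowkit as sk


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """A 4-subject cohort at 2 kHz, small enough for per-module tests."""
    return sk.CohortSpec(n_subjects=4, swallows_per_subject=3, fs=2000.0, seed=7)


@pytest.fixture(scope="session")
def one_recording(small_spec):
    subject = sk.SubjectMeta(subject_id="S000", sex="female", age=33.0)
    rec, truth = sk.gen_recording(small_spec, subject, seed=11)
    return rec, truth


@pytest.fixture(scope="session")
def preprocessed_recording(small_spec, one_recording):
    rec, truth = one_recording
    models = sk.baseline_ar_models(small_spec)
    clean = sk.preprocess_recording(rec, models)
    return clean, truth
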