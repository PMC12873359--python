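from datetime import datetime

import numpy as np
import pytest

from restact.io import EpochSeries
from restact.synth import CosinorTruth, SynthConfig


def make_series(counts, start="2024-01-01 00:00", epoch_length=1, subject_id="S1"):
    return EpochSeries(subject_id, datetime.fromisoformat(start),
                       np.asarray(counts, dtype=np.int64), epoch_length)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def clean_config():
    """Generator settings with no night suppression, a strictly positive
    envelope and tight count noise, so extraction recovers the generated
    bout durations almost exactly."""
    truth = {
        "UE": CosinorTruth(300.0, 100.0, 2.86, 40.0, 3.04),
        "VPA": CosinorTruth(300.0, 100.0, 2.88, 40.0, 2.84),
    }
    return SynthConfig(
        n_subjects_per_group=3, n_days=8, seed=11,
        cosinor_truth=truth, night_suppression=1.0, count_dispersion=50.0,
    )


@pytest.fixture
def smooth_bout_config():
    """High-duty-cycle settings (short rests, longer active bouts) for tight
    cosinor parameter recovery."""
    truth = {
        "UE": CosinorTruth(300.0, 100.0, 2.86, 40.0, 3.04),
        "VPA": CosinorTruth(300.0, 100.0, 2.88, 40.0, 2.84),
    }
    return SynthConfig(
        n_subjects_per_group=3, n_days=10, seed=7,
        cosinor_truth=truth, night_suppression=1.0, count_dispersion=50.0,
        rest_gamma={"UE": 2.0, "VPA": 2.0}, rest_min=2, rest_max=30,
        active_alpha=0.3, active_beta=1.0,
    )
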