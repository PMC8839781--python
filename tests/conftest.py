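import numpy as np
import pandas as pd
import pytest

from erdspec.io import FeatureSet, RawRecording
from erdspec.synthdata import CohortConfig


@pytest.fixture
def small_config():
    """Tiny cohort: 1 subject/group, 5 stimuli x 3 reps, short ISIs."""
    return CohortConfig(
        n_subjects_per_group=1, reps_per_stimulus=3, isi_range=(1.0, 1.5), seed=7
    )


@pytest.fixture
def noise_recording():
    """60 s of 4-channel white noise with a handful of events."""
    rng = np.random.default_rng(11)
    fs = 256.0
    x = rng.standard_normal((4, int(60 * fs)))
    events = pd.DataFrame(
        {"onset_s": [10.0, 20.0, 30.0, 40.0], "label": ["stim1"] * 4}
    )
    return RawRecording(x, fs, ["Fz", "Cz", "Pz", "Oz"], events)


def make_feature_set(rng, n_per_cell=6, dim=16, cell_means=None, n_subjects=2):
    """FeatureSet with the four study cells; optional per-cell mean offsets."""
    cell_means = cell_means or {}
    vectors, rows = [], []
    for group in ("tinnitus", "control"):
        for session in ("S1", "S2"):
            mu = cell_means.get((group, session), 0.0)
            for j in range(n_per_cell):
                vectors.append(rng.standard_normal(dim) + mu)
                rows.append(
                    {"subject": j % n_subjects, "group": group, "session": session}
                )
    return FeatureSet(np.asarray(vectors), pd.DataFrame(rows))


@pytest.fixture
def feature_set():
    return make_feature_set(np.random.default_rng(3))
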