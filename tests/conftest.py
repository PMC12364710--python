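import numpy as np
import pytest

import capbrain as cb


@pytest.fixture(scope="session")
def small_scenes():
    return cb.make_scenes(n_scenes=60, d=16, n_captions=5, caption_noise=0.2,
                          m=6, seed=123)


@pytest.fixture(scope="session")
def small_cohort():
    """Three participants, moderate noise, session nuisances on."""
    return cb.make_cohort(
        n_participants=3, n_shared=40, n_unique=60, grid_shape=(6, 5, 4),
        n_regions=2, d=16, snr=10, caption_noise=0.2, n_reps=3, n_sessions=2,
        gain_range=(0.8, 1.2), offset_range=(-0.5, 0.5), seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Three identical participants, no noise, no nuisances, no jitter."""
    return cb.make_cohort(
        n_participants=3, n_shared=40, n_unique=40, grid_shape=(6, 4, 3),
        n_regions=2, d=12, noise_sd=0.0, snr=None, caption_noise=0.0,
        participant_weight_jitter=0.0, n_reps=3, n_sessions=1, seed=21,
    )


def cohort_xy(cohort, participant):
    """(X_train, Y_train, X_test, Y_test, avg, is_shared) for one participant."""
    part = cohort.participants[participant]
    avg = cb.preprocess_betas(part.trials)
    pos = {s: i for i, s in enumerate(cohort.scenes.scene_ids)}
    X = cohort.scenes.mean_embedding[[pos[s] for s in avg.stimulus_ids]]
    is_shared = np.isin(avg.stimulus_ids, cohort.shared_ids)
    return (X[~is_shared], avg.values[~is_shared], X[is_shared],
            avg.values[is_shared], avg, is_shared)
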