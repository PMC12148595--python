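import numpy as np
import pandas as pd
import pytest

from imaes import DesignSpec, EffectSpec, GroundTruthGeometry, generate_ratings


@pytest.fixture(scope="session")
def small_design():
    return DesignSpec(n_subjects=6, n_stimuli_per_type=5, n_runs=2, seed=11)


@pytest.fixture(scope="session")
def small_ratings(small_design):
    return generate_ratings(small_design, EffectSpec())


@pytest.fixture(scope="session")
def noiseless_geometry():
    return GroundTruthGeometry(
        w_mod=1.0, w_exp=0.5, w_type=0.5, noise_sd=0.0, subject_sd=0.0
    )


def make_pair_table(perception, imagery, vividness=7):
    """One subject, one stimulus, both modalities, given rating triples."""
    return pd.DataFrame(
        {
            "subject_id": ["s1", "s1"],
            "stimulus_id": ["art-01", "art-01"],
            "stimulus_type": ["art", "art"],
            "modality": ["perception", "imagery"],
            "run": [1, 1],
            "pleasure": [perception[0], imagery[0]],
            "beauty": [perception[1], imagery[1]],
            "moving": [perception[2], imagery[2]],
            "vividness": [np.nan, float(vividness)],
        }
    )
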