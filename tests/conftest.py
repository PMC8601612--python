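import numpy as np
import pandas as pd
import pytest

from vpwm import FeatureSpace, SubjectDataset, TaskDesign, generate_subject

VP_TRUE = dict(J1_bar=60.0, a=1.0, tau=30.0, kappa_r=50.0)


@pytest.fixture(scope="session")
def color_space():
    return FeatureSpace(360.0)


@pytest.fixture(scope="session")
def vp_subject():
    """A VP-generated subject at the main color design (160 trials)."""
    design = TaskDesign(360.0, (1, 3), 80, 180)
    return generate_subject("VP", VP_TRUE, design, seed=42, subject_id="vp42", group="HC")


@pytest.fixture(scope="session")
def big_vp_subject():
    """A VP-generated subject with 4x the trials, for recovery-style checks."""
    design = TaskDesign(360.0, (1, 3), 320, 180)
    return generate_subject("VP", VP_TRUE, design, seed=7, subject_id="vp7", group="HC")


def make_dataset(errors_deg, set_size=1, space=None, subject="s", group="G"):
    """Dataset with the given signed errors (stimulus fixed at 0 deg)."""
    space = space or FeatureSpace(360.0)
    errors_deg = np.asarray(errors_deg, dtype=float)
    df = pd.DataFrame(
        {
            "set_size": set_size,
            "stimulus_deg": 0.0,
            "response_deg": np.mod(errors_deg, space.period_deg),
        }
    )
    return SubjectDataset(subject, group, space, df)
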