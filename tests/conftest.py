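import warnings

import numpy as np
import pytest

from valconf.data import FixationRecord, RatingRecord, SubjectDataset, Trial
from valconf.glam import GLAMParams

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def base_params():
    return GLAMParams(k=1.5, sigma=0.4, tau=8.0, theta=0.6)


def make_trial(trial_id=1, v_upper=0.7, v_lower=0.5, var_upper=0.01,
               var_lower=0.02, choice="upper", rt_s=1.0, confidence=0.6,
               g_upper=0.5, **kw):
    return Trial(trial_id=trial_id, item_upper=f"a{trial_id}",
                 item_lower=f"b{trial_id}", v_upper=v_upper, v_lower=v_lower,
                 var_upper=var_upper, var_lower=var_lower, choice=choice,
                 rt_s=rt_s, confidence=confidence, g_upper=g_upper, **kw)


@pytest.fixture
def tiny_dataset():
    """Three hand-built trials with fixations, one lacking a lower fixation."""
    trials = [make_trial(1, rt_s=0.8), make_trial(2, v_upper=0.4, rt_s=1.2,
                                                  choice="lower"),
              make_trial(3, rt_s=0.5)]
    fx = {
        1: [FixationRecord(1, "upper", 0, 600),
            FixationRecord(1, "lower", 600, 1000)],
        2: [FixationRecord(2, "upper", 0, 500),
            FixationRecord(2, "lower", 500, 1000),
            FixationRecord(2, "elsewhere", 1000, 1200)],
        3: [FixationRecord(3, "upper", 0, 500)],   # never fixates lower
    }
    ratings = []
    for t in trials:
        for item, v in ((t.item_upper, t.v_upper), (t.item_lower, t.v_lower)):
            ratings.append(RatingRecord(item, 1, v - 0.01))
            ratings.append(RatingRecord(item, 2, v + 0.01))
    return SubjectDataset(subject_id="s01", ratings=ratings, trials=trials,
                          fixations=fx)


@pytest.fixture(scope="session")
def small_session():
    """One synthetic session at the default study conditions (cached)."""
    from valconf.synth import GeneratorConfig, generate_dataset
    cfg = GeneratorConfig(seed=42, max_trials=150)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def normative_session():
    """Session whose confidence reports come from the probability-correct
    readout (needed when a test asserts readout-driven signatures)."""
    from valconf.synth import GeneratorConfig, generate_dataset
    cfg = GeneratorConfig(seed=43, max_trials=200,
                          confidence_source="normative")
    return generate_dataset(cfg)
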