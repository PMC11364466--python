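import warnings

import matplotlib
import numpy as np
import pandas as pd
import pytest

matplotlib.use("Agg")

from camwm.prep import compute_trial_errors
from camwm.synth import CohortConfig, generate_activity, generate_behavior


@pytest.fixture(scope="session")
def small_cohort():
    """Two-study cohort, 8 participants, with injected outliers."""
    cfg = CohortConfig(n_studies=2, participants_per_study=(4, 4),
                       trials_per_participant=40, outlier_rate=0.05, seed=101)
    trials, truth = generate_behavior(cfg)
    return compute_trial_errors(trials), truth


@pytest.fixture(scope="session")
def cohort155():
    """Full-size cohort matching the multi-study design (155 participants)."""
    cfg = CohortConfig(seed=202)
    trials, truth = generate_behavior(cfg)
    return trials, truth


@pytest.fixture(scope="session")
def true_measures(cohort155):
    _, truth = cohort155
    m = truth.participants.rename(columns={"sigma_M_true": "memory_inexactness"}).copy()
    m["prototype_bias"] = 1.0 - m["lambda_true"]
    return m[["participant_id", "study_id", "memory_inexactness", "prototype_bias"]]


@pytest.fixture()
def quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture()
def toy_trials():
    """Hand-built 12-trial table: 9 compliant, 1 angular violation, 1 amplitude
    violation, 1 quadrant-only violation (|error| <= 45 but wrong quadrant)."""
    rows = []
    # 9 compliant trials across quadrants
    for i, (tgt, resp) in enumerate([(30, 35), (60, 50), (120, 130), (150, 149),
                                     (200, 210), (240, 236), (300, 305), (330, 322),
                                     (75, 80)]):
        rows.append(dict(study_id="s1", participant_id=f"p{i % 3}", trial=i,
                         target_angle_deg=tgt, target_amp_dva=6.0,
                         response_angle_deg=resp, response_amp_dva=6.0))
    # trial 9: angular violation (error = +50 within quadrant-ish; quadrant also wrong)
    rows.append(dict(study_id="s1", participant_id="p0", trial=9,
                     target_angle_deg=30, target_amp_dva=6.0,
                     response_angle_deg=80, response_amp_dva=6.0))
    # trial 10: amplitude violation only (ratio 0.4)
    rows.append(dict(study_id="s1", participant_id="p1", trial=10,
                     target_angle_deg=120, target_amp_dva=6.0,
                     response_angle_deg=125, response_amp_dva=2.4))
    # trial 11: quadrant-only violation (target 80 in Q1, response 95 in Q2, |err| = 15)
    rows.append(dict(study_id="s1", participant_id="p2", trial=11,
                     target_angle_deg=80, target_amp_dva=6.0,
                     response_angle_deg=95, response_amp_dva=6.0))
    return pd.DataFrame(rows)
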