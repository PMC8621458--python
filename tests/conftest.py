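import logging

import numpy as np
import pytest

import fatiguekit as fk
from fatiguekit.modeling import FeatureMatrix
from fatiguekit.synthetic import EffectSpec, generate_cohort

# rank-deficiency warnings are expected under LOO with many features
logging.getLogger("fatiguekit.modeling").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def schedule():
    """Default 120-stimulus oddball schedule (96 frequent / 24 non-frequent)."""
    return fk.generate_stimulus_schedule(seed=123)


@pytest.fixture(scope="session")
def quiet_bundle(schedule):
    """Synthetic session at the P300-recovery noise condition: every band at
    1 uV RMS (<= planted amplitude / 5) under a 6 uV P300."""
    profile = fk.SubjectProfile(
        band_amplitude={b: np.full(8, 1.0) for b in fk.BANDS})
    return fk.synthesize_recording(profile, schedule, seed=42), profile


@pytest.fixture(scope="session")
def default_bundle(schedule):
    """Synthetic session at the default background level."""
    profile = fk.SubjectProfile()
    return fk.synthesize_recording(profile, schedule, seed=7), profile


@pytest.fixture(scope="session")
def noiseless_cohort():
    """14-subject cohort with a noiseless planted 3-feature linear law."""
    return generate_cohort(14, EffectSpec(noise_sd=0.0), seed=101)


@pytest.fixture(scope="session")
def noiseless_matrix(noiseless_cohort):
    return fk.assemble_feature_matrix(
        dict(noiseless_cohort.measured_features), noiseless_cohort.fas_by_subject)


def exactly_linear_matrix(m=14, k=3, seed=0, noise_sd=0.0):
    """FeatureMatrix whose FAS totals are exactly linear in k named features
    (plus decoy noise columns); an analytic construction used as the oracle
    for perfect-recovery properties.

    Each planted feature is individually (almost) perfectly correlated with
    the FAS total — small jitter orthogonal to the slope vector breaks exact
    collinearity without disturbing the linear law — so correlation-based
    selection keeps all k features in every training fold.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    slopes = np.linspace(-12.0, -6.0, k)
    fas_target = rng.uniform(12.0, 48.0, m)
    base = 1.5 + (fas_target[:, None] - 30.0) / (k * slopes[None, :])
    jitter = rng.normal(0.0, 0.01, size=(m, k))
    jitter -= np.outer(jitter @ slopes, slopes) / (slopes @ slopes)
    values = base + jitter
    names = [f"ratio_f{i}_g{i}_C3" for i in range(k)]
    X = pd.DataFrame(values, columns=names, index=[f"S{i:02d}" for i in range(m)])
    fas = 30.0 - slopes.sum() * 1.5 + values @ slopes + rng.normal(0, noise_sd, m)
    for j in range(2 * k):
        X[f"np_noise{j}_O1"] = rng.standard_normal(m)
    return FeatureMatrix(X=X, fas=pd.Series(fas, index=X.index))
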