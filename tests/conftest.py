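"""Shared fixtures: small synthetic sessions with planted ground truth.

Everything is generated programmatically and seeded; session-scoped
fixtures cache the expensive EEG simulations and cross-validation runs.
"""
import numpy as np
import pytest

from smrpipe.preprocess import bandpass_fir
from smrpipe.synthetic import (RunPlan, SessionPlan, default_sources,
                               generate_session)

#: planted mu ERD depth used by the shared session
MU_DEPTH = 0.5
#: source amplitude / background RMS = 3 (the SNR the recovery claims use)
AMPLITUDE = 30.0
NOISE = 10.0


@pytest.fixture(scope="session")
def mu_sources():
    return default_sources(mu_depth=MU_DEPTH, amplitude=AMPLITUDE)


@pytest.fixture(scope="session")
def mu_session(mu_sources):
    """Three FR runs with two planted mu sources at SNR 3."""
    plan = SessionPlan("s01", 2, [RunPlan("FR")] * 3)
    return generate_session(plan, mu_sources, noise_level=NOISE, seed=42)


@pytest.fixture(scope="session")
def mu_session_filtered(mu_session):
    return bandpass_fir(mu_session, 3.0, 48.0)


@pytest.fixture(scope="session")
def mu_covariances(mu_session_filtered):
    """Per-condition covariance sets after outlier rejection."""
    from smrpipe.preprocess import reject_outlier_trials, trial_covariances

    cond = mu_session_filtered.trial_info["condition"].to_numpy()
    out = {}
    for label in ("imagery", "visual_attention"):
        covs = trial_covariances(
            mu_session_filtered.select(cond == label))
        out[label] = reject_outlier_trials(covs)
    return out


@pytest.fixture(scope="session")
def mu_decomposition(mu_covariances):
    from smrpipe.ged import crossval_ged

    return crossval_ged(mu_covariances["imagery"],
                        mu_covariances["visual_attention"], k=10, seed=0)


@pytest.fixture(scope="session")
def separable_session():
    """Two runs with a deep, clean ERD: classes separable by construction."""
    plan = SessionPlan("s01", 2, [RunPlan("FR")] * 2)
    sources = default_sources(mu_depth=0.8, amplitude=AMPLITUDE)
    return generate_session(plan, sources, noise_level=5.0, seed=3)


@pytest.fixture(scope="session")
def separable_cv(separable_session):
    from smrpipe.classify import cv_5x2

    return cv_5x2(separable_session, "erd", seed=0)


@pytest.fixture(scope="session")
def shuffled_cv(separable_session):
    """Same data with labels shuffled: no class information left."""
    from smrpipe.classify import cv_5x2

    rng = np.random.default_rng(11)
    eeg = separable_session.select(np.arange(separable_session.n_trials))
    eeg.trial_info["condition"] = rng.permutation(
        eeg.trial_info["condition"].to_numpy())
    return cv_5x2(eeg, "erd", seed=1)
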