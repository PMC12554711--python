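"""Shared fixtures: small synthetic cohorts sized for fast simulation studies."""

from __future__ import annotations

import numpy as np
import pytest

from tmseeg.features import FeatureParams, extract_feature_table
from tmseeg.pipeline import preprocess_cohort
from tmseeg.synthetic import SyntheticConfig, generate_cohort

# Simulation-study problem sizes used throughout the suite: short (20 s)
# recordings and a 512-sample entropy cap keep a full cohort pass fast while
# preserving every structural property of the default 300 s configuration.
FAST_DURATION = 20.0
FAST_PARAMS = FeatureParams(entropy_max_samples=512)


def make_cohort(n_subjects=15, effect_size=0.0, seed=0, duration=FAST_DURATION, **kw):
    cfg = SyntheticConfig(
        n_subjects=n_subjects, duration=duration, effect_size=effect_size, seed=seed, **kw
    )
    return cfg, *generate_cohort(cfg)


def cohort_features(pairs, params=FAST_PARAMS):
    return extract_feature_table(preprocess_cohort(pairs, {}), params)


@pytest.fixture(scope="session")
def planted_cohort():
    """One 15-subject cohort with a strong planted alpha@P3 ~ PSQI link."""
    cfg, pairs, scales = make_cohort(effect_size=0.06, seed=3)
    return cfg, pairs, scales


@pytest.fixture(scope="session")
def planted_features(planted_cohort):
    _, pairs, scales = planted_cohort
    return cohort_features(pairs), scales


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250923)
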