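"""Shared fixtures: synthetic cohorts, trivial reference classifiers.

Expensive end-to-end artifacts (the null-cohort bootstrap, the separated-
cohort cross-validation) are session-scoped so multiple tests share one
computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from eegtbi.data import Recording
from eegtbi.evaluation import run_bootstrap_cv, cross_validate, make_fold_plan
from eegtbi.synthetic import CohortSpec, desk_prep_config, generate_cohort
from eegtbi.trainer import desk_scale_classifier

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# trivial classifiers used as evaluation-machinery references
# ---------------------------------------------------------------------------

class MarkerOracleClassifier:
    """Reads the class planted in the segment mean; always correct on
    marker cohorts."""

    def get_params(self, deep=True):
        return {}

    def set_params(self, **params):
        return self

    def fit(self, X, y):
        return self

    def predict(self, X):
        X = np.asarray(X)
        means = X.mean(axis=(1, 2))
        return np.where(means > 0.5, "tbi", "healthy").astype(object)


class CoinFlipClassifier:
    """Seeded Bernoulli(1/2) predictions, independent of the input."""

    def __init__(self, random_state=0):
        self.random_state = random_state

    def get_params(self, deep=True):
        return {"random_state": self.random_state}

    def set_params(self, **params):
        self.random_state = params.get("random_state", self.random_state)
        return self

    def fit(self, X, y):
        self._n_fits = getattr(self, "_n_fits", 0) + 1
        return self

    def predict(self, X):
        rng = np.random.default_rng(self.random_state)
        flips = rng.random(np.asarray(X).shape[0]) < 0.5
        return np.where(flips, "tbi", "healthy").astype(object)


class AlwaysHealthyClassifier:
    def get_params(self, deep=True):
        return {}

    def set_params(self, **params):
        return self

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], "healthy", dtype=object)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def make_marker_cohort(n_per_class: int = 15, n_segments: int = 10,
                       fs: int = 8, n_channels: int = 4) -> list[Recording]:
    """Tiny cohort whose class is planted in the signal mean (0 or 1)."""
    labels = ("Fpz", "AF7", "AF8", "CPz")[:n_channels]
    cohort = []
    rng = np.random.default_rng(99)
    for label, level in (("healthy", 0.0), ("tbi", 1.0)):
        for i in range(n_per_class):
            sig = level + 0.01 * rng.standard_normal((n_channels,
                                                      n_segments * fs))
            cohort.append(Recording(signal=sig, fs=fs, channel_labels=labels,
                                    subject_id=f"{label}-{i + 1:02d}",
                                    class_label=label))
    return cohort


@pytest.fixture(scope="session")
def marker_cohort():
    return make_marker_cohort()


@pytest.fixture(scope="session")
def null_cohort():
    """Desk-scale cohort with no class effect (15+15, fixed seed)."""
    spec = CohortSpec.desk_scale(seed=7)
    cohort, _ = generate_cohort(spec)
    return spec, cohort


@pytest.fixture(scope="session")
def separated_cohort():
    """Desk-scale cohort with the configured biomarker effect: alpha
    amplitude x0.4 and theta amplitude x1.5 in the injured class."""
    spec = CohortSpec.desk_scale(seed=1, alpha_attenuation=0.4, theta_gain=1.5)
    cohort, _ = generate_cohort(spec)
    return spec, cohort


@pytest.fixture(scope="session")
def null_bootstrap(null_cohort):
    """Scaled-down (20-iteration) bootstrap of the CNN on the null cohort."""
    spec, cohort = null_cohort
    return run_bootstrap_cv(cohort, desk_scale_classifier(random_state=0),
                            n_iterations=20, base_seed=123,
                            prep=desk_prep_config(spec))


@pytest.fixture(scope="session")
def effect_cv(separated_cohort):
    """Threefold cross-validation of the CNN on the separated cohort,
    using the literal 15+15 fold assignment."""
    spec, cohort = separated_cohort
    plan = make_fold_plan(cohort, k=3, scheme="literal_threefold")
    return cross_validate(cohort, plan, desk_scale_classifier(random_state=0),
                          prep=desk_prep_config(spec))
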