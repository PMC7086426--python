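"""The four feature-engineered comparison pipelines and MRMR selection.

Each pipeline couples a published preprocessing + spectral-feature recipe
with a conventional classifier:

* Gaussian Naive Bayes on per-electrode beta power and delta/theta/gamma
  orthogonalized-envelope connectivity (notch, 100 Hz low-pass, 0.5 Hz
  high-pass preprocessing);
* AdaBoost over decision stumps on log10 average PSD of delta/theta/alpha/
  gamma for the AF7-Fpz and AF8-Fpz frontal derivations (0.1-100 Hz
  band-pass);
* an RBF SVM on the top-10 MRMR-selected features out of per-electrode
  theta/alpha/beta1/beta2/beta3 band powers plus per-1 Hz bin powers from
  1-30 Hz (0.5-30 Hz band-pass);
* an RBF SVM on per-electrode alpha band power alone.

All four present the same scikit-learn estimator surface as the CNN —
``fit``/``predict`` on raw ``(n_segments, n_channels, n_samples)`` stacks —
so they drop into the same cross-validation and bootstrap machinery.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass

from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import mutual_info_score
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import MontageError
from .features import (
    BANDS,
    band_power,
    bandpass_filter,
    highpass_filter,
    lowpass_filter,
    mean_envelope_connectivity,
    notch_filter,
    per_hz_band_powers,
    welch_psd,
)


@dataclass
class FeatureVector:
    """One segment's named features with provenance."""

    values: np.ndarray
    names: tuple[str, ...]
    subject_id: str = "unknown"
    class_label: str = "unknown"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.names = tuple(self.names)
        if self.values.shape != (len(self.names),):
            raise ValueError("values and names length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


# ---------------------------------------------------------------------------
# MRMR
# ---------------------------------------------------------------------------

def _discretize(col: np.ndarray, bins: int = 4) -> np.ndarray:
    """Equal-frequency discretization into at most ``bins`` codes."""
    qs = np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(qs, col, side="right")


def mrmr_select(features, y=None, n_keep: int = 10, bins: int = 4) -> list[int]:
    """Greedy minimal-redundancy maximal-relevance feature ranking.

    ``features`` is either a list of :class:`FeatureVector` (labels taken
    from them) or an ``(n_samples, n_features)`` array with ``y`` given.
    Relevance and redundancy are mutual information on equal-frequency
    discretized features (4 bins).  At each step the candidate maximizing
    ``relevance - mean redundancy to the selected set`` is added; ties break
    to the lowest feature index; constant features are never candidates.
    """
    if y is None:
        X = np.stack([fv.values for fv in features])
        y = np.asarray([fv.class_label for fv in features])
    else:
        X = np.asarray(features, dtype=np.float64)
        y = np.asarray(y)
    n_features = X.shape[1]
    if n_keep > n_features:
        raise ValueError(f"n_keep={n_keep} exceeds {n_features} features")
    if len(np.unique(y)) < 2:
        raise ValueError("MRMR needs at least two classes")

    codes = np.stack([_discretize(X[:, j], bins) for j in range(n_features)],
                     axis=1)
    candidates = [j for j in range(n_features) if np.ptp(X[:, j]) > 0]
    relevance = np.full(n_features, -np.inf)
    for j in candidates:
        relevance[j] = mutual_info_score(y, codes[:, j])

    selected: list[int] = []
    redundancy_sum = np.zeros(n_features)
    while len(selected) < n_keep:
        pool = [j for j in candidates if j not in selected]
        if not pool:  # all informative features taken; fall back to the rest
            pool = [j for j in range(n_features) if j not in selected]
            selected.append(min(pool))
            continue
        if selected:
            scores = [relevance[j] - redundancy_sum[j] / len(selected)
                      for j in pool]
        else:
            scores = [relevance[j] for j in pool]
        best = pool[int(np.argmax(scores))]  # argmax takes the first maximum
        selected.append(best)
        for j in candidates:
            if j not in selected:
                redundancy_sum[j] += mutual_info_score(codes[:, best],
                                                       codes[:, j])
    return selected


class MRMRSelector(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer keeping the top MRMR-ranked features."""

    def __init__(self, n_features: int = 10, bins: int = 4):
        self.n_features = n_features
        self.bins = bins

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        n_keep = min(self.n_features, X.shape[1])
        self.selected_idx_ = mrmr_select(X, y, n_keep=n_keep, bins=self.bins)
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.selected_idx_]


# ---------------------------------------------------------------------------
# pipeline skeleton
# ---------------------------------------------------------------------------

class _SpectralClassifier(ClassifierMixin, BaseEstimator):
    """Shared surface: per-segment spectral features + a sklearn model."""

    def _features(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def feature_names(self) -> tuple[str, ...]:
        raise NotImplementedError

    def _make_model(self):
        raise NotImplementedError

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError(
                f"X must be (n_segments, n_channels, n_samples), got {X.shape}"
            )
        return X

    def fit(self, X, y):
        X = self._validate(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        feats = self._features(X)
        self.model_ = self._make_model().fit(feats, y)
        self.n_features_in_ = feats.shape[1]
        return self

    def predict(self, X):
        return self.model_.predict(self._features(self._validate(X)))

    def predict_proba(self, X):
        return self.model_.predict_proba(self._features(self._validate(X)))

    def transform_features(self, X) -> tuple[np.ndarray, tuple[str, ...]]:
        """Feature matrix and names, for inspection or export."""
        return self._features(self._validate(X)), self.feature_names()

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.two_d_array = False
        return tags


def _find_channel(labels: tuple[str, ...], name: str) -> int:
    lowered = [c.lower() for c in labels]
    if name.lower() not in lowered:
        raise MontageError(f"required channel {name!r} missing from montage")
    return lowered.index(name.lower())


class NaiveBayesSpectralClassifier(_SpectralClassifier):
    """Gaussian Naive Bayes on beta power + envelope connectivity.

    Preprocessing per segment: mains notch (default 50 Hz), 100 Hz low-pass
    (skipped above Nyquist), 0.5 Hz high-pass.  Features: per-electrode beta
    band power, plus the per-electrode mean orthogonalized log-envelope
    connectivity in delta, theta, and gamma.
    """

    _conn_bands = ("delta", "theta", "gamma")

    def __init__(self, fs: float = 1000.0, channel_labels: tuple[str, ...] = (),
                 notch_hz: float = 50.0):
        self.fs = fs
        self.channel_labels = channel_labels
        self.notch_hz = notch_hz

    def _preprocess(self, seg: np.ndarray) -> np.ndarray:
        x = notch_filter(seg, self.fs, self.notch_hz)
        x = lowpass_filter(x, self.fs, 100.0)
        return highpass_filter(x, self.fs, 0.5)

    def _features(self, X: np.ndarray) -> np.ndarray:
        rows = []
        for seg in X:
            x = self._preprocess(seg)
            parts = [band_power(x, self.fs, "beta")]
            for band in self._conn_bands:
                parts.append(mean_envelope_connectivity(x, band, self.fs))
            rows.append(np.concatenate(parts))
        return np.stack(rows)

    def feature_names(self) -> tuple[str, ...]:
        chans = self.channel_labels or tuple(
            f"ch{i}" for i in range(len(self.channel_labels)))
        names = [f"beta_power_{c}" for c in chans]
        for band in self._conn_bands:
            names += [f"{band}_connectivity_{c}" for c in chans]
        return tuple(names)

    def _make_model(self):
        return GaussianNB()


class AdaBoostFrontalClassifier(_SpectralClassifier):
    """AdaBoost over decision stumps on frontal log-PSD features.

    Segments are band-pass filtered 0.1-100 Hz (high edge clipped below
    Nyquist when needed); the AF7-Fpz and AF8-Fpz bipolar derivations give
    log10 average PSD in delta, theta, alpha, and gamma: 8 features.
    """

    _bands = ("delta", "theta", "alpha", "gamma")

    def __init__(self, fs: float = 1000.0, channel_labels: tuple[str, ...] = (),
                 n_estimators: int = 50, random_state: int = 0):
        self.fs = fs
        self.channel_labels = channel_labels
        self.n_estimators = n_estimators
        self.random_state = random_state

    def _features(self, X: np.ndarray) -> np.ndarray:
        labels = tuple(self.channel_labels)
        i_af7 = _find_channel(labels, "AF7")
        i_af8 = _find_channel(labels, "AF8")
        i_fpz = _find_channel(labels, "Fpz")
        rows = []
        for seg in X:
            x = bandpass_filter(seg, self.fs, 0.1, 100.0)
            derivs = np.stack([x[i_af7] - x[i_fpz], x[i_af8] - x[i_fpz]])
            freqs, psd = welch_psd(derivs, self.fs)
            feats = []
            for d in range(2):
                for band in self._bands:
                    b = BANDS[band]
                    mask = (freqs >= b.low_hz) & (freqs < min(b.high_hz,
                                                              self.fs / 2))
                    feats.append(np.log10(psd[d, mask].mean() + 1e-30))
            rows.append(np.asarray(feats))
        return np.stack(rows)

    def feature_names(self) -> tuple[str, ...]:
        return tuple(
            f"log10_psd_{band}_{deriv}"
            for deriv in ("AF7-Fpz", "AF8-Fpz") for band in self._bands
        )

    def _make_model(self):
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=self.n_estimators,
            random_state=self.random_state,
        )


class SVMMRMRClassifier(_SpectralClassifier):
    """RBF SVM on the top MRMR-selected spectral features.

    Segments are band-pass filtered 0.5-30 Hz; per electrode the feature set
    is the theta/alpha/beta1/beta2/beta3 band-power averages plus the 29
    per-1 Hz bin powers between 1 and 30 Hz.  Features are standardized on
    the training fold, reduced to the top ``n_features`` by MRMR, and fed to
    an RBF SVM.
    """

    _bands = ("theta", "alpha", "beta1", "beta2", "beta3")

    def __init__(self, fs: float = 1000.0, channel_labels: tuple[str, ...] = (),
                 n_features: int = 10, C: float = 1.0):
        self.fs = fs
        self.channel_labels = channel_labels
        self.n_features = n_features
        self.C = C

    def _features(self, X: np.ndarray) -> np.ndarray:
        rows = []
        for seg in X:
            x = bandpass_filter(seg, self.fs, 0.5, 30.0)
            parts = [band_power(x, self.fs, band) for band in self._bands]
            parts.append(per_hz_band_powers(x, self.fs, 1.0, 30.0).ravel())
            rows.append(np.concatenate(parts))
        return np.stack(rows)

    def feature_names(self) -> tuple[str, ...]:
        chans = tuple(self.channel_labels)
        names = [f"{band}_power_{c}" for band in self._bands for c in chans]
        names += [f"power_{lo}to{lo + 1}Hz_{c}" for c in chans
                  for lo in range(1, 30)]
        return tuple(names)

    def _make_model(self):
        return Pipeline([
            ("scale", StandardScaler()),
            ("mrmr", MRMRSelector(n_features=self.n_features)),
            ("svm", SVC(kernel="rbf", C=self.C)),
        ])


class SVMAlphaPowerClassifier(_SpectralClassifier):
    """RBF SVM on per-electrode alpha band power alone."""

    def __init__(self, fs: float = 1000.0, channel_labels: tuple[str, ...] = (),
                 C: float = 1.0):
        self.fs = fs
        self.channel_labels = channel_labels
        self.C = C

    def _features(self, X: np.ndarray) -> np.ndarray:
        return np.stack([band_power(seg, self.fs, "alpha") for seg in X])

    def feature_names(self) -> tuple[str, ...]:
        return tuple(f"alpha_power_{c}" for c in self.channel_labels)

    def _make_model(self):
        return Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", C=self.C)),
        ])


def features_to_frame(estimator: _SpectralClassifier, X):
    """Feature matrix as a named-column DataFrame (for TSV export)."""
    import pandas as pd

    values, names = estimator.transform_features(X)
    return pd.DataFrame(values, columns=list(names))


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

PIPELINE_NAMES = ("cnn", "naive_bayes", "adaboost", "svm_mrmr", "svm_alpha")


def make_pipeline(name: str, fs: float, channel_labels: tuple[str, ...],
                  random_state: int = 0, **kwargs):
    """Instantiate a classifier by name with the cohort's geometry."""
    if name == "cnn":
        from .trainer import CNNClassifier

        return CNNClassifier(random_state=random_state, **kwargs)
    if name == "naive_bayes":
        return NaiveBayesSpectralClassifier(fs=fs, channel_labels=channel_labels,
                                            **kwargs)
    if name == "adaboost":
        return AdaBoostFrontalClassifier(fs=fs, channel_labels=channel_labels,
                                         random_state=random_state, **kwargs)
    if name == "svm_mrmr":
        return SVMMRMRClassifier(fs=fs, channel_labels=channel_labels, **kwargs)
    if name == "svm_alpha":
        return SVMAlphaPowerClassifier(fs=fs, channel_labels=channel_labels,
                                       **kwargs)
    raise ValueError(f"unknown pipeline {name!r}; choose from {PIPELINE_NAMES}")
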