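"""Spectral features, envelope connectivity, MRMR, and baseline pipelines."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.metrics import mutual_info_score

from eegtbi.baselines import (
    AdaBoostFrontalClassifier,
    FeatureVector,
    MRMRSelector,
    NaiveBayesSpectralClassifier,
    PIPELINE_NAMES,
    SVMAlphaPowerClassifier,
    SVMMRMRClassifier,
    make_pipeline,
    mrmr_select,
    _discretize,
)
from eegtbi.errors import FrequencyError, MontageError, UndefinedMetricError
from eegtbi.features import (
    BANDS,
    band_power,
    envelope_connectivity,
    mean_envelope_connectivity,
    per_hz_band_powers,
)
from eegtbi.montage import WAVEGUARD_64, select_channels

FS = 128.0


def sinusoid(freq, fs=FS, seconds=2.0, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


# ---------------------------------------------------------------------------
# band power
# ---------------------------------------------------------------------------

def test_band_power_concentrates_on_the_tone():
    x = sinusoid(10.0)
    total = sum(band_power(x, FS, b)[0]
                for b in ("delta", "theta", "alpha", "beta"))
    assert band_power(x, FS, "alpha")[0] / total > 0.95
    assert band_power(x, FS, "delta")[0] / total < 0.01


def test_band_power_white_noise_scales_with_bandwidth():
    rng = np.random.default_rng(0)
    ratios = []
    for _ in range(20):
        x = rng.standard_normal(int(4 * FS))
        total = np.var(x)
        band = BANDS["beta"]
        expected = total * (band.high_hz - band.low_hz) / (FS / 2)
        ratios.append(band_power(x, FS, band)[0] / expected)
    assert np.mean(ratios) == pytest.approx(1.0, abs=0.2)


def test_band_power_rejects_bands_beyond_nyquist():
    with pytest.raises(FrequencyError):
        band_power(sinusoid(10.0), FS, "gamma")  # 70 Hz > 64 Hz Nyquist


def test_band_powers_nonnegative_and_finite():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((5, int(FS)))
    for b in ("delta", "theta", "alpha", "beta"):
        p = band_power(x, FS, b)
        assert np.all(p >= 0) and np.all(np.isfinite(p))


def test_per_hz_band_powers_shape():
    x = np.random.default_rng(2).standard_normal((3, int(FS)))
    out = per_hz_band_powers(x, FS, 1.0, 30.0)
    assert out.shape == (3, 29)


# ---------------------------------------------------------------------------
# envelope connectivity
# ---------------------------------------------------------------------------

def test_identical_channels_orthogonalize_to_zero_connectivity():
    x = np.random.default_rng(3).standard_normal(int(4 * FS))
    assert envelope_connectivity(x, x, "theta", FS) == pytest.approx(0.0)


def test_independent_noise_connectivity_small_and_bounded():
    rng = np.random.default_rng(4)
    values = [
        envelope_connectivity(rng.standard_normal(int(4 * FS)),
                              rng.standard_normal(int(4 * FS)), "theta", FS)
        for _ in range(15)
    ]
    assert all(-1.0 <= v <= 1.0 for v in values)
    assert abs(np.mean(values)) < 0.15


def test_constant_envelope_raises():
    with pytest.raises(UndefinedMetricError):
        envelope_connectivity(sinusoid(10.0, seconds=4.0),
                              np.random.default_rng(5).standard_normal(
                                  int(4 * FS)),
                              "alpha", FS)


def test_mean_connectivity_matches_pairwise_reference():
    rng = np.random.default_rng(6)
    block = rng.standard_normal((4, int(4 * FS)))
    vec = mean_envelope_connectivity(block, "theta", FS)
    for i in range(4):
        pairwise = [envelope_connectivity(block[i], block[j], "theta", FS)
                    for j in range(4) if j != i]
        assert vec[i] == pytest.approx(np.mean(pairwise), abs=1e-6)


# ---------------------------------------------------------------------------
# MRMR
# ---------------------------------------------------------------------------

def test_mrmr_ranks_the_label_copy_first():
    rng = np.random.default_rng(7)
    y = np.repeat([0, 1], 20)
    X = rng.standard_normal((40, 6))
    X[:, 4] = y  # exact copy of the class label
    assert mrmr_select(X, y, n_keep=1) == [4]


def test_mrmr_defers_duplicate_informative_feature():
    """Of two identical informative columns only one is taken before noise;
    the duplicate is maximally redundant.  Ties break to the lower index."""
    rng = np.random.default_rng(8)
    y = np.repeat([0, 1], 30)
    noise = rng.standard_normal((60, 3))
    informative = y + 0.05 * rng.standard_normal(60)
    X = np.column_stack([noise[:, 0], informative, informative, noise[:, 1:]])
    order = mrmr_select(X, y, n_keep=3)
    assert order[0] == 1           # first informative copy, lowest index
    assert order[1] != 2           # duplicate not taken second
    assert 2 not in order[:2]


def test_mrmr_full_selection_returns_all_indices():
    rng = np.random.default_rng(9)
    y = np.repeat([0, 1], 10)
    X = rng.standard_normal((20, 5))
    assert sorted(mrmr_select(X, y, n_keep=5)) == [0, 1, 2, 3, 4]


def test_mrmr_agrees_with_bruteforce_greedy():
    """Independent re-implementation of the greedy criterion by exhaustive
    scoring at each step, on a small random table."""
    rng = np.random.default_rng(10)
    y = rng.integers(0, 2, size=40)
    X = rng.standard_normal((40, 7))
    X[:, 2] += y
    X[:, 5] += 0.5 * y

    codes = np.stack([_discretize(X[:, j]) for j in range(7)], axis=1)
    rel = [mutual_info_score(y, codes[:, j]) for j in range(7)]
    chosen = []
    for _ in range(4):
        best, best_score = None, -np.inf
        for j in range(7):
            if j in chosen:
                continue
            red = np.mean([mutual_info_score(codes[:, j], codes[:, s])
                           for s in chosen]) if chosen else 0.0
            score = rel[j] - red
            if score > best_score + 1e-12:
                best, best_score = j, score
        chosen.append(best)
    assert mrmr_select(X, y, n_keep=4) == chosen


def test_mrmr_selector_transformer():
    rng = np.random.default_rng(11)
    y = np.repeat(["a", "b"], 15)
    X = rng.standard_normal((30, 12))
    sel = MRMRSelector(n_features=4).fit(X, y)
    assert len(sel.selected_idx_) == 4
    assert sel.transform(X).shape == (30, 4)


def test_feature_vector_validation():
    with pytest.raises(ValueError):
        FeatureVector(values=np.array([1.0, np.inf]), names=("a", "b"))
    with pytest.raises(ValueError):
        FeatureVector(values=np.array([1.0]), names=("a", "b"))


# ---------------------------------------------------------------------------
# baseline pipelines
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def segment_stacks():
    """Small two-class segment stacks with an alpha-power difference."""
    rng = np.random.default_rng(12)
    labels = select_channels(8)
    n, c, t = 24, 8, int(FS)
    base = rng.standard_normal((n, c, t))
    alpha = np.stack([np.tile(sinusoid(10.0, seconds=1.0), (c, 1))] * n)
    y = np.array(["healthy", "tbi"] * (n // 2))
    X = base + np.where((y == "healthy")[:, None, None], 3.0, 0.5) * alpha
    return X, y, labels


def test_adaboost_feature_count_and_power_scaling(segment_stacks):
    X, y, labels = segment_stacks
    clf = AdaBoostFrontalClassifier(fs=FS, channel_labels=labels)
    feats, names = clf.transform_features(X)
    assert feats.shape[1] == len(names) == 8  # 2 derivations x 4 bands
    # doubling the amplitude raises every log10 PSD feature by log10(4)
    feats2, _ = clf.transform_features(2.0 * X)
    np.testing.assert_allclose(feats2 - feats, np.log10(4.0), atol=0.02)


def test_adaboost_requires_frontal_channels(segment_stacks):
    X, y, _ = segment_stacks
    clf = AdaBoostFrontalClassifier(fs=FS, channel_labels=("C3", "C4", "Cz"))
    with pytest.raises(MontageError):
        clf.fit(X[:, :3, :], y)


def test_naive_bayes_feature_dimensionality(segment_stacks):
    X, y, labels = segment_stacks
    clf = NaiveBayesSpectralClassifier(fs=FS, channel_labels=labels)
    feats, names = clf.transform_features(X[:4])
    # per-electrode beta power + 3 bands of mean connectivity
    assert feats.shape[1] == len(names) == 8 * (1 + 3)
    assert np.all(np.isfinite(feats))


def test_svm_mrmr_feature_construction(segment_stacks):
    X, y, labels = segment_stacks
    clf = SVMMRMRClassifier(fs=FS, channel_labels=labels, n_features=10)
    feats, names = clf.transform_features(X[:4])
    assert feats.shape[1] == len(names) == 8 * (5 + 29)
    clf.fit(X, y)
    # exactly 10 features reach the SVM
    assert len(clf.model_.named_steps["mrmr"].selected_idx_) == 10


def test_svm_mrmr_full_montage_feature_arithmetic():
    """On the 63-channel clinical montage the pre-selection feature space is
    63 x (5 + 29) = 2142."""
    labels = tuple(c for c in WAVEGUARD_64 if c != "CPz")
    clf = SVMMRMRClassifier(fs=1000.0, channel_labels=labels)
    assert len(clf.feature_names()) == 63 * 34 == 2142


def test_svm_alpha_feature_count_equals_electrodes(segment_stacks):
    X, y, labels = segment_stacks
    clf = SVMAlphaPowerClassifier(fs=FS, channel_labels=labels)
    feats, names = clf.transform_features(X[:4])
    assert feats.shape[1] == len(names) == 8


def test_alpha_pipeline_separates_alpha_effect(segment_stacks):
    X, y, labels = segment_stacks
    clf = SVMAlphaPowerClassifier(fs=FS, channel_labels=labels).fit(X, y)
    assert np.mean(clf.predict(X) == y) > 0.9


def test_all_pipelines_share_the_estimator_contract(segment_stacks):
    X, y, labels = segment_stacks
    for name in PIPELINE_NAMES:
        if name == "cnn":
            continue  # covered by the trainer tests; too slow here
        est = make_pipeline(name, fs=FS, channel_labels=labels)
        fitted = clone(est).fit(X, y)
        pred = fitted.predict(X)
        assert pred.shape == (X.shape[0],)
        assert set(pred) <= {"healthy", "tbi"}
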