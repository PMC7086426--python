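"""Numerics of the numpy network and the SGD training regime."""

import numpy as np
import pytest

import eegtbi.network as nw
from eegtbi.errors import ShapeError, TrainingError
from eegtbi.evaluation import prepare_cohort
from eegtbi.model_io import load_model, save_model
from eegtbi.network import Network, SGDMomentum, softmax
from eegtbi.synthetic import CohortSpec, desk_prep_config, generate_cohort
from eegtbi.topology import (
    FeatureMapShape,
    LayerSpec,
    TopologySpec,
    build_reference_topology,
)
from eegtbi.trainer import (
    CNNClassifier,
    TrainConfig,
    TrainedModel,
    desk_scale_classifier,
    iterations_per_epoch,
    predict,
    train,
)


def tiny_topology(h=8, w=16, filters=2):
    return TopologySpec(
        input_shape=FeatureMapShape(h, w, 1),
        layers=(
            LayerSpec("convolution", f=3, s=1, filters=filters,
                      post_ops=("batch_norm", "relu")),
            LayerSpec("average_pool", f=2, s=2),
            LayerSpec("fully_connected", activation="softmax"),
        ),
    )


def tiny_data(n=24, h=8, w=16, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat(["healthy", "tbi"], n // 2)
    X = rng.normal(size=(n, h, w))
    X[y == "tbi"] += 1.0  # mean offset: trivially separable
    return X, y


def test_train_config_defaults_match_reference_regime():
    cfg = TrainConfig()
    assert cfg.learning_rate == 0.0001
    assert cfg.momentum == 0.9
    assert cfg.l2_regularization == 0.0005
    assert cfg.mini_batch_size == 128
    assert cfg.epochs == 30


@pytest.mark.parametrize("n, batch, expected",
                         [(680, 128, 6), (128, 128, 1), (129, 128, 2)])
def test_iterations_per_epoch(n, batch, expected):
    assert iterations_per_epoch(n, batch) == expected


def test_gradients_match_finite_differences():
    """Backpropagation agrees with central differences in double precision
    (biases feeding batch normalization excluded: their true gradient is 0)."""
    old_dtype = nw._DTYPE
    nw._DTYPE = np.float64
    try:
        spec = tiny_topology()
        net = Network(spec, np.random.default_rng(0))
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5, 8, 16, 1))
        y = np.array([0, 1, 0, 1, 1])

        def loss():
            value, _ = net.train_step(x, y, l2=0.01)
            return value

        loss()
        checks = [(p, p.grad.copy()) for p in net.parameters()
                  if not (p.name == "b" and p.value.shape == (2,)
                          and p is net.layers[0].b)]
        for p, grad in checks:
            flat_v, flat_g = p.value.reshape(-1), grad.reshape(-1)
            for idx in rng.choice(flat_v.size, size=min(flat_v.size, 5),
                                  replace=False):
                eps, old = 1e-6, flat_v[idx]
                flat_v[idx] = old + eps
                up = loss()
                flat_v[idx] = old - eps
                down = loss()
                flat_v[idx] = old
                numeric = (up - down) / (2 * eps)
                assert numeric == pytest.approx(flat_g[idx], rel=1e-4,
                                                abs=1e-7)
    finally:
        nw._DTYPE = old_dtype


def test_softmax_normalizes():
    logits = np.random.default_rng(0).normal(scale=10, size=(7, 2))
    probs = softmax(logits)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(probs >= 0)


def test_zero_learning_rate_leaves_parameters_unchanged():
    net = Network(tiny_topology(), np.random.default_rng(0))
    before = [p.value.copy() for p in net.parameters()]
    opt = SGDMomentum(net.parameters(), learning_rate=0.0, momentum=0.9)
    x = np.random.default_rng(1).normal(size=(4, 8, 16, 1)).astype(np.float32)
    net.train_step(x, np.array([0, 1, 0, 1]), l2=0.1)
    opt.step()
    for p, b in zip(net.parameters(), before):
        np.testing.assert_array_equal(p.value, b)


def test_same_seed_same_trajectory():
    X, y = tiny_data()
    fits = [
        CNNClassifier(topology=tiny_topology(), epochs=4, batch_size=8,
                      learning_rate=0.01, random_state=5).fit(X, y)
        for _ in range(2)
    ]
    assert fits[0].training_log_[-1]["loss"] == fits[1].training_log_[-1]["loss"]
    np.testing.assert_array_equal(fits[0].predict_proba(X),
                                  fits[1].predict_proba(X))


def test_heavy_l2_shrinks_weights_monotonically():
    """With the decay term dominating the data gradient, the weight norm
    contracts every epoch (momentum off to avoid overshoot oscillation)."""
    X, y = tiny_data()
    clf = CNNClassifier(topology=tiny_topology(), epochs=6, batch_size=8,
                        learning_rate=0.001, momentum=0.0,
                        l2_regularization=10.0, random_state=0).fit(X, y)
    norms = [entry["weight_norm"] for entry in clf.training_log_]
    assert all(b < a for a, b in zip(norms, norms[1:]))


def test_predict_proba_normalized_and_pure():
    X, y = tiny_data()
    clf = CNNClassifier(topology=tiny_topology(), epochs=3, batch_size=8,
                        learning_rate=0.01, random_state=0).fit(X, y)
    doubled = np.concatenate([X[:1], X[:1]])
    probs = clf.predict_proba(doubled)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    np.testing.assert_array_equal(probs[0], probs[1])


def test_single_class_and_shape_mismatch_errors():
    X, y = tiny_data()
    with pytest.raises(TrainingError):
        CNNClassifier(topology=tiny_topology(), epochs=1).fit(
            X, np.full(len(y), "healthy"))
    clf = CNNClassifier(topology=tiny_topology(), epochs=1,
                        batch_size=8).fit(X, y)
    with pytest.raises(ShapeError):
        clf.predict(np.zeros((2, 9, 16)))
    with pytest.raises(ShapeError):
        CNNClassifier(topology=tiny_topology(), epochs=1).fit(
            np.zeros((4, 9, 16)), ["healthy", "tbi", "healthy", "tbi"])


def test_auto_topology_selects_reference_for_clinical_geometry():
    clf = CNNClassifier(topology="auto")
    assert clf._resolve_topology(63, 1000) == build_reference_topology()
    compact = clf._resolve_topology(19, 128)
    assert compact.input_shape.as_tuple() == (19, 128, 1)


def test_training_learns_separated_cohort_and_nulls_on_permuted_labels():
    """On a cohort with halved injured-class alpha amplitude the network
    fits its training set; with permuted labels held-out accuracy drops to
    chance."""
    spec = CohortSpec.desk_scale(seed=2, alpha_attenuation=0.5,
                                 theta_gain=1.5, n_per_class=10)
    cohort, _ = generate_cohort(spec)
    prepared = prepare_cohort(cohort, desk_prep_config(spec))
    ids = list(prepared)
    train_ids = [s for s in ids if int(s.split("-")[1]) <= 6]
    test_ids = [s for s in ids if s not in train_ids]
    X_train = np.concatenate([prepared[s][0] for s in train_ids])
    y_train = np.concatenate([np.full(prepared[s][0].shape[0], prepared[s][1])
                              for s in train_ids])
    X_test = np.concatenate([prepared[s][0] for s in test_ids])
    y_test = np.concatenate([np.full(prepared[s][0].shape[0], prepared[s][1])
                             for s in test_ids])

    clf = desk_scale_classifier(random_state=0).fit(X_train, y_train)
    assert clf.training_log_[-1]["train_accuracy"] > 90.0

    null_accs = []
    for perm_seed in (0, 1):
        permuted = np.random.default_rng(perm_seed).permutation(y_train)
        null_clf = desk_scale_classifier(random_state=0).fit(X_train, permuted)
        null_accs.append(100.0 * np.mean(null_clf.predict(X_test) == y_test))
    assert 40.0 <= np.mean(null_accs) <= 60.0


def test_functional_wrappers_and_model_roundtrip(tmp_path):
    X, y = tiny_data()
    cfg = TrainConfig(learning_rate=0.01, mini_batch_size=8, epochs=3, seed=1)
    model = train(tiny_topology(), X, y, cfg)
    assert len(model.training_log) == cfg.epochs
    probs, labels = predict(model, X)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert set(labels) <= {"healthy", "tbi"}

    path = tmp_path / "model.npz"
    save_model(model, path)
    restored = load_model(path)
    probs2, labels2 = predict(restored, X)
    np.testing.assert_allclose(probs2, probs, atol=1e-6)
    np.testing.assert_array_equal(labels2, labels)
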