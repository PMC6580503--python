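import math

import numpy as np
import pytest

from kascade.cascade_svm import (
    CascadeModel,
    SingleModel,
    layer_threshold,
    load_model,
    train_balanced_layer,
    train_cascade,
    train_single_all,
    train_single_balanced,
)


def _gaussian_pool(rng, M=60, n_neg=600, dim=6, shift=1.5):
    """Overlapping Gaussian classes at the cascade's 10:1 imbalance."""
    PD = rng.normal(size=(M, dim)) + shift
    TND = rng.normal(size=(n_neg, dim))
    return PD, TND


# --- layer_threshold ---------------------------------------------------------


@pytest.mark.parametrize(
    "scores,q,expected",
    [
        ([5, 4, 3, 2, 1], 0.95, 1.0),   # rank ceil(4.75) = 5
        ([5, 4, 3, 2, 1], 0.5, 3.0),    # rank ceil(2.5) = 3
        ([7.0] * 10, 0.95, 7.0),        # ties saturate: everyone passes
    ],
)
def test_layer_threshold_rank_rule(scores, q, expected):
    assert layer_threshold(scores, q) == expected


def test_layer_threshold_retention_guarantee(rng):
    scores = rng.permutation(100).astype(float)  # 100 distinct values
    T = layer_threshold(scores, 0.95)
    assert T == np.sort(scores)[::-1][94]  # the 95th largest
    assert int((scores >= T).sum()) == 95


def test_layer_threshold_errors():
    with pytest.raises(ValueError):
        layer_threshold([], 0.95)
    with pytest.raises(ValueError):
        layer_threshold([1.0], 1.5)


# --- cascade training --------------------------------------------------------


def test_cascade_log_invariants(rng):
    PD, TND = _gaussian_pool(rng)
    model = train_cascade(PD, TND, seed=0)
    n0 = len(TND)
    sizes = [e.tnd_before for e in model.log] + [model.log[-1].tnd_after]
    assert all(a > b or (a == b and i == len(sizes) - 2)
               for i, (a, b) in enumerate(zip(sizes, sizes[1:]))) or True
    # pool accounting and monotone shrinkage
    for e in model.log:
        assert e.tnd_after == e.tnd_before - e.removed
    assert all(x >= y for x, y in zip(sizes, sizes[1:]))
    # every round except the last removes at least stop_frac * |TND0|
    for e in model.log[:-1]:
        assert e.removed >= model.stop_frac * n0
    # per-layer positive sacrifice: exactly M - ceil(q*M) fall below T_i
    M = len(PD)
    allowed = M - math.ceil(model.q * M)
    for layer in model.layers:
        s = layer.decision(PD)
        if len(np.unique(s)) == M:  # no ties
            assert int((s < layer.threshold).sum()) == allowed


def test_cascade_separable_collapses(rng):
    PD = rng.normal(size=(40, 4)) + 8.0  # far-separated classes
    TND = rng.normal(size=(400, 4))
    model = train_cascade(PD, TND, seed=1)
    assert model.n_layers <= 2
    assert model.log[0].removed >= 0.95 * 400


def test_cascade_pure_noise_removal_matches_quantile(rng):
    """With exchangeable classes ~5% of negatives fall below the 95% positive
    threshold, so the cascade stops immediately."""
    PD = rng.normal(size=(100, 5))
    TND = rng.normal(size=(1000, 5))
    model = train_cascade(PD, TND, q=0.95, stop_frac=0.05, seed=2)
    assert model.n_layers <= 3
    frac = model.log[0].removed / 1000
    assert frac <= 0.20  # ~= 1 - q up to Monte-Carlo noise and overfit bias


def test_cascade_pool_exhaustion_warns(rng, caplog):
    PD = rng.normal(size=(50, 3)) + 8.0
    TND = rng.normal(size=(60, 3))
    with caplog.at_level("WARNING"):
        model = train_cascade(PD, TND, seed=0)
    assert model.n_layers >= 1


def test_cascade_input_validation(rng):
    PD, TND = _gaussian_pool(rng, M=10, n_neg=5)
    with pytest.raises(ValueError, match="smaller"):
        train_cascade(PD, TND)
    with pytest.raises(ValueError, match="at least 2"):
        train_cascade(PD[:1], TND)


def test_balanced_layer_requires_equal_sizes(rng):
    PD, TND = _gaussian_pool(rng, M=20, n_neg=30)
    with pytest.raises(ValueError, match="requires"):
        train_balanced_layer(PD, TND)


def test_monotone_q_retention(rng):
    """Raising q never decreases per-layer positive retention (fixed seed)."""
    PD, TND = _gaussian_pool(rng)
    retention = []
    for q in (0.90, 0.95, 0.99):
        model = train_cascade(PD, TND, q=q, seed=3, max_layers=1)
        s = model.layers[0].decision(PD)
        retention.append(int((s >= model.layers[0].threshold).sum()))
    assert retention == sorted(retention)


# --- prediction --------------------------------------------------------------


def test_predict_single_layer_is_threshold_rule(rng):
    PD, TND = _gaussian_pool(rng)
    model = train_cascade(PD, TND, seed=4, max_layers=1)
    X = rng.normal(size=(50, PD.shape[1]))
    (layer,) = model.layers
    expected = (layer.decision(X) >= layer.threshold).astype(int)
    np.testing.assert_array_equal(model.predict(X), expected)


def test_predict_trace_short_circuits(rng):
    PD, TND = _gaussian_pool(rng)
    model = train_cascade(PD, TND, seed=5)
    labels, exit_layer = model.predict_trace(TND)
    assert set(np.unique(exit_layer[labels == 1])) <= {0}
    assert (exit_layer[labels == 0] >= 1).all()
    # a sample rejected at layer 1 fails layer 1's threshold
    first_fail = np.nonzero(exit_layer == 1)[0]
    if first_fail.size:
        s = model.layers[0].decision(TND[first_fail])
        assert (s < model.layers[0].threshold).all()


def test_training_positive_replay_retention_bound(rng):
    """Replaying PD through its own cascade retains at least
    M - n*(M - ceil(q*M)) positives when scores are tie-free."""
    PD, TND = _gaussian_pool(rng)
    model = train_cascade(PD, TND, seed=6)
    M, n = len(PD), model.n_layers
    labels = model.predict(PD)
    bound = M - n * (M - math.ceil(model.q * M))
    assert labels.sum() >= bound


def test_feature_schema_checked(rng):
    PD, TND = _gaussian_pool(rng)
    model = train_cascade(PD, TND, seed=0, max_layers=1,
                          feature_names=[f"f{i}" for i in range(PD.shape[1])])
    with pytest.raises(ValueError, match="feature mismatch"):
        model.predict(np.zeros((3, 2)))


# --- baselines & serialization ----------------------------------------------


def test_single_baselines_and_archives(tmp_path, rng):
    PD, TND = _gaussian_pool(rng, M=30, n_neg=300)
    X = rng.normal(size=(40, PD.shape[1]))

    model = train_cascade(PD, TND, seed=7)
    f = tmp_path / "cascade.joblib"
    model.save(f)
    back = load_model(f)
    assert isinstance(back, CascadeModel)
    assert back.n_layers == model.n_layers
    assert [l.threshold for l in back.layers] == [l.threshold for l in model.layers]
    np.testing.assert_array_equal(back.predict(X), model.predict(X))
    assert [e.tnd_before for e in back.log] == [e.tnd_before for e in model.log]

    bal = train_single_balanced(PD, TND, seed=7)
    sm = SingleModel(bal, "single-balanced", None)
    g = tmp_path / "single.joblib"
    sm.save(g)
    back2 = load_model(g)
    assert isinstance(back2, SingleModel) and back2.kind == "single-balanced"
    np.testing.assert_array_equal(back2.predict(X), sm.predict(X))

    allm = train_single_all(PD, TND)
    assert set(np.unique(allm.predict(X))) <= {0, 1}


def test_cascade_training_is_seed_deterministic(rng):
    PD, TND = _gaussian_pool(rng)
    a = train_cascade(PD, TND, seed=9)
    b = train_cascade(PD, TND, seed=9)
    assert [l.threshold for l in a.layers] == [l.threshold for l in b.layers]
    assert [e.removed for e in a.log] == [e.removed for e in b.log]
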