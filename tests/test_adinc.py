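import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emgadapt.adinc import (ADINCConfig, AdaptiveBuffer, AdincKNN,
                            LabeledInstance, distance, neighbor_weight)

import oracles


# -- distance and weighting -------------------------------------------------

def test_distance_examples():
    assert distance([0, 0], [3, 4], "l1") == pytest.approx(7.0)
    assert distance([0, 0], [3, 4], "l2") == pytest.approx(5.0)
    assert distance([1.5, -2], [1.5, -2], "l1") == 0.0
    with pytest.raises(ValueError):
        distance([1], [1, 2], "l1")
    with pytest.raises(ValueError):
        distance([1], [1], "chebyshev")


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.floats(-100, 100, allow_nan=False, width=32), min_size=1, max_size=8),
       st.lists(st.floats(-100, 100, allow_nan=False, width=32), min_size=1, max_size=8),
       st.lists(st.floats(-100, 100, allow_nan=False, width=32), min_size=1, max_size=8))
def test_metric_axioms(a, b, c):
    n = min(len(a), len(b), len(c))
    a, b, c = a[:n], b[:n], c[:n]
    for m in ("l1", "l2"):
        dab, dba = distance(a, b, m), distance(b, a, m)
        assert dab == pytest.approx(dba)
        assert dab >= 0
        assert distance(a, a, m) == pytest.approx(0.0, abs=1e-9)
        assert distance(a, c, m) <= distance(a, b, m) + distance(b, c, m) + 1e-9
    assert distance(a, b, "l1") >= distance(a, b, "l2") - 1e-9


def test_neighbor_weight():
    assert neighbor_weight(0.0, 1e-8) == pytest.approx(1e8)
    assert neighbor_weight(1.0, 1e-8) == pytest.approx(1.0, rel=1e-6)
    assert neighbor_weight(0.1, 1e-8) > neighbor_weight(0.2, 1e-8)
    with pytest.raises(ValueError):
        neighbor_weight(-0.1, 1e-8)
    with pytest.raises(ValueError):
        neighbor_weight(1.0, 0.0)


# -- buffer contract --------------------------------------------------------

@settings(derandomize=True, max_examples=150)
@given(st.integers(0, 10), st.lists(st.integers(0, 4), max_size=60))
def test_buffer_capacity_and_fifo(capacity, labels):
    buf = AdaptiveBuffer(capacity)
    for i, lab in enumerate(labels):
        buf.append(LabeledInstance(np.array([float(i)]), lab, arrival_index=i))
        assert len(buf) <= capacity
        arrivals = [e.arrival_index for e in buf.entries]
        assert arrivals == sorted(arrivals)  # arrival order preserved
        # FIFO eviction: the survivors are exactly the most recent appends
        assert arrivals == list(range(max(0, i + 1 - capacity), i + 1))


def test_buffer_rejects_negative_capacity():
    with pytest.raises(ValueError):
        AdaptiveBuffer(-1)


# -- fitting and prediction -------------------------------------------------

def _random_problem(rng, n=40, d=4, n_classes=3):
    X = rng.normal(size=(n, d))
    y = rng.integers(0, n_classes, size=n)
    return X, y


def test_fit_validation():
    model = AdincKNN(ADINCConfig(k=3))
    with pytest.raises(ValueError):
        model.fit(np.empty((0, 2)), np.empty(0))
    with pytest.raises(ValueError):
        model.fit(np.ones((2, 2)), [0, 1])  # fewer instances than k
    with pytest.raises(ValueError):
        model.predict_one([0.0, 0.0])  # not fitted


def test_k1_training_point_predicts_own_label():
    rng = np.random.default_rng(0)
    X, y = _random_problem(rng)
    model = AdincKNN(ADINCConfig(k=1)).fit(X, y)
    for i in (0, 7, 21):
        assert model.predict_one(X[i]).label == y[i]


def test_fit_is_idempotent():
    rng = np.random.default_rng(1)
    X, y = _random_problem(rng)
    queries = rng.normal(size=(20, 4))
    model = AdincKNN().fit(X, y)
    first = [model.predict_one(q).label for q in queries]
    model.fit(X, y)
    assert [model.predict_one(q).label for q in queries] == first


def test_single_instance_pool_confidence():
    model = AdincKNN(ADINCConfig(k=1)).fit(np.array([[1.0, 2.0]]), [4])
    p = model.predict_one([0.0, 0.0])
    assert p.label == 4 and p.confidence == pytest.approx(1.0)


def test_weighted_vote_beats_majority():
    """Nearest single-class neighbor outweighs two farther same-class ones."""
    X = np.array([[0.1], [0.2], [0.3]])
    y = np.array([0, 1, 1])
    model = AdincKNN(ADINCConfig(k=3)).fit(X, y)
    weighted = model.predict_one([0.0])
    assert weighted.label == 0  # mass A ~ 10 vs B ~ 8.33
    assert weighted.class_weight_mass[0] == pytest.approx(1 / 0.1, rel=1e-6)
    unweighted = model.static_predict([0.0], weighted=False)
    assert unweighted.label == 1  # simple majority flips the decision


def test_majority_vote_ignores_distances():
    X = np.array([[0.01], [5.0], [5.1]])
    y = np.array([1, 0, 0])
    model = AdincKNN(ADINCConfig(k=3)).fit(X, y)
    assert model.static_predict([0.0]).label == 0


def test_predict_one_matches_full_scan_reference():
    rng = np.random.default_rng(123)
    for trial in range(60):
        n = int(rng.integers(5, 60))
        d = int(rng.integers(1, 6))
        k = int(rng.integers(1, min(n, 7)))
        metric = ["l1", "l2"][int(rng.integers(2))]
        X, y = rng.normal(size=(n, d)), rng.integers(0, 4, size=n)
        cfg = ADINCConfig(k=k, metric=metric, window_size=10)
        model = AdincKNN(cfg).fit(X, y)
        # put a few entries into the buffer too
        for j in range(int(rng.integers(0, 8))):
            model.update(rng.normal(size=d), label=int(rng.integers(0, 4)))
        bX, by, _ = model.buffer.arrays()
        pool_x = list(X) + (list(bX) if len(by) else [])
        pool_y = list(y) + list(by)
        for _ in range(5):
            q = rng.normal(size=d)
            expected = oracles.knn_reference(pool_x, pool_y, q, k, metric,
                                             cfg.epsilon, weighted=True)
            assert model.predict_one(q).label == expected


def test_buffer_only_mode_falls_back_to_base_until_filled():
    cfg = ADINCConfig(k=2, window_size=5, include_base_set=False)
    model = AdincKNN(cfg).fit(np.array([[0.0], [1.0], [2.0]]), [0, 1, 2])
    # buffer below k: neighbors still come from the base set
    assert all(src == "base" for src, _ in model.predict_one([0.0]).neighbor_ids)
    model.update(np.array([10.0]), label=1)
    model.update(np.array([10.1]), label=1)
    # buffer now holds k entries: pool is buffer-only
    p = model.predict_one([0.0])
    assert p.label == 1
    assert all(src == "buffer" for src, _ in p.neighbor_ids)


# -- update / streaming -----------------------------------------------------

def test_update_fifo_window():
    model = AdincKNN(ADINCConfig(window_size=2)).fit(np.zeros((3, 1)), [0, 1, 2])
    for i in range(3):
        model.update(np.array([float(i)]), label=i)
    labels = [e.label for e in model.buffer.entries]
    assert labels == [1, 2]
    assert [e.arrival_index for e in model.buffer.entries] == [1, 2]


def test_update_window_zero_keeps_buffer_empty():
    model = AdincKNN(ADINCConfig(window_size=0)).fit(np.zeros((3, 1)), [0, 1, 2])
    for i in range(5):
        model.update(np.array([float(i)]), label=i)
    assert len(model.buffer) == 0


def test_oracle_mode_requires_label():
    model = AdincKNN(ADINCConfig()).fit(np.zeros((3, 1)), [0, 1, 2])
    with pytest.raises(ValueError):
        model.update(np.array([1.0]))


def test_self_training_confidence_gate():
    cfg = ADINCConfig(label_mode="self_training", confidence_gate=1.0, k=3)
    X = np.array([[0.0], [0.1], [10.0]])
    model = AdincKNN(cfg).fit(X, [0, 0, 1])
    appended = model.update(np.array([0.05]))  # mixed neighborhood => conf < 1
    assert not appended and len(model.buffer) == 0
    cfg2 = ADINCConfig(label_mode="self_training", confidence_gate=0.0, k=1)
    model2 = AdincKNN(cfg2).fit(X, [0, 0, 1])
    assert model2.update(np.array([0.05]))
    assert model2.buffer.entries[0].label_source == "predicted"


def test_empty_stream():
    model = AdincKNN().fit(np.zeros((3, 2)), [0, 1, 2])
    preds = model.predict_stream(np.empty((0, 2)), labels=[])
    assert preds == [] and len(model.buffer) == 0


def test_window_zero_equals_static_weighted_knn():
    """W=0 makes the adaptive model a static weighted kNN, for any order."""
    rng = np.random.default_rng(5)
    X, y = _random_problem(rng, n=60)
    stream = rng.normal(size=(80, 4))
    stream_y = rng.integers(0, 3, size=80)
    model = AdincKNN(ADINCConfig(window_size=0)).fit(X, y)
    static = AdincKNN(ADINCConfig(window_size=0)).fit(X, y)
    preds = [p.label for p in model.predict_stream(stream, labels=stream_y)]
    expected = [static.static_predict(q, weighted=True).label for q in stream]
    assert preds == expected
    # and order invariance
    order = rng.permutation(80)
    model2 = AdincKNN(ADINCConfig(window_size=0)).fit(X, y)
    preds2 = [p.label for p in model2.predict_stream(stream[order], labels=stream_y[order])]
    assert preds2 == [expected[i] for i in order]


def test_epsilon_robustness():
    rng = np.random.default_rng(9)
    X, y = _random_problem(rng, n=50)
    queries = rng.normal(size=(40, 4))
    labels = {}
    for eps in (1e-12, 1e-8, 1e-6):
        model = AdincKNN(ADINCConfig(epsilon=eps)).fit(X, y)
        labels[eps] = [model.predict_one(q).label for q in queries]
    assert labels[1e-12] == labels[1e-8] == labels[1e-6]


def test_iid_stream_adaptation_does_not_hurt():
    """On an i.i.d. stream the adaptive model stays within 2 points of
    the static baseline (buffered neighbors come from the same
    distribution, so adaptation is neutral)."""
    gaps = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        centers = rng.normal(scale=3.0, size=(4, 4))
        y_tr = rng.integers(0, 4, size=200)
        X_tr = centers[y_tr] + rng.normal(size=(200, 4))
        y_st = rng.integers(0, 4, size=100)
        X_st = centers[y_st] + rng.normal(size=(100, 4))
        model = AdincKNN(ADINCConfig(window_size=50)).fit(X_tr, y_tr)
        adapt = np.mean([p.label for p in model.predict_stream(X_st, labels=y_st)] == y_st)
        static = AdincKNN(ADINCConfig()).fit(X_tr, y_tr)
        stat = np.mean([static.static_predict(q).label for q in X_st] == y_st)
        gaps.append(adapt - stat)
    assert np.mean(gaps) >= -0.02


def test_static_knn_matches_sklearn():
    """Unweighted majority vote agrees with an independent kNN library."""
    from sklearn.neighbors import KNeighborsClassifier
    rng = np.random.default_rng(11)
    X, y = _random_problem(rng, n=80)
    queries = rng.normal(size=(60, 4))
    model = AdincKNN(ADINCConfig(k=3, metric="l1")).fit(X, y)
    ours = [model.static_predict(q).label for q in queries]
    ref = KNeighborsClassifier(n_neighbors=3, metric="manhattan").fit(X, y)
    assert np.mean(np.array(ours) == ref.predict(queries)) >= 0.95


def test_serialization_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    X, y = _random_problem(rng)
    model = AdincKNN(ADINCConfig(window_size=5)).fit(X, y)
    for i in range(8):
        model.update(rng.normal(size=4), label=int(rng.integers(0, 3)))
    path = tmp_path / "model.json"
    model.save(path)
    back = AdincKNN.load(path)
    queries = rng.normal(size=(20, 4))
    assert [model.predict_one(q).label for q in queries] == \
           [back.predict_one(q).label for q in queries]
    assert [e.arrival_index for e in back.buffer.entries] == \
           [e.arrival_index for e in model.buffer.entries]


def test_config_validation():
    with pytest.raises(ValueError):
        ADINCConfig(k=0)
    with pytest.raises(ValueError):
        ADINCConfig(metric="cosine")
    with pytest.raises(ValueError):
        ADINCConfig(epsilon=0.0)
    with pytest.raises(ValueError):
        ADINCConfig(window_size=-1)
    with pytest.raises(ValueError):
        ADINCConfig(label_mode="semi")
    with pytest.raises(ValueError):
        ADINCConfig(confidence_gate=1.5)
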