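"""Point (weighted KNN) and sequence (bi-LSTM) classifiers."""

import numpy as np
import pytest

from icgfa.bilstm import (
    LAYER_SPEC,
    BiLSTMNet,
    predict_bilstm,
    load_model,
    save_model,
    train_bilstm,
)
from icgfa.config import ConfigError, KNNConfig, LSTMConfig
from icgfa.containers import CLASSES, ContractError, Dataset, LineSample
from icgfa.knn import PointModel, TrainingError, predict_knn, train_knn


def make_sample(features, labels, video="v", expert=0, line=0):
    features = np.asarray(features, dtype=float)
    coords = np.stack([np.full(len(features), 5),
                       np.arange(len(features))], axis=1)
    return LineSample(coords=coords, features=features,
                      labels=None if labels is None
                      else np.asarray(labels, dtype=np.int64),
                      video_id=video, expert_id=expert, line_id=line)


def synthetic_sequences(n, rng, length=40, band=12, noisy=0.02):
    """Well-separated three-zone sequences mimicking condensed lines."""
    samples = []
    for i in range(n):
        start = rng.integers(8, length - band - 8)
        labels = np.full(length, 2)
        labels[:start] = 0
        labels[start:start + band] = 1
        centers = np.array([[0.9, 0.8, 0.3, 0.25],
                            [0.5, 0.45, 0.6, 0.5],
                            [0.1, 0.05, 0.95, 0.9]])
        feats = centers[labels] + rng.normal(0, noisy, (length, 4))
        samples.append(make_sample(feats, labels, video=f"v{i:03d}"))
    return samples


def knn_oracle(X_train, y_train, query, k):
    """Brute-force inverse-distance weighted vote with the documented
    tie rules, written independently in plain python."""
    d = np.sqrt(((X_train - query) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")[:k]
    nd, nl = d[order], y_train[order]
    if (nd == 0).any():
        weights = (nd == 0).astype(float)
    else:
        weights = 1.0 / nd
    best = (-1.0, np.inf, -1)
    for c in range(len(CLASSES)):
        members = nl == c
        if not members.any():
            continue
        votes = weights[members].sum()
        mean_d = nd[members].mean()
        cand = (votes, mean_d, c)
        if cand[0] > best[0] + 1e-12 or (
                abs(cand[0] - best[0]) <= 1e-12 * max(1.0, cand[0])
                and cand[1] < best[1] - 1e-12):
            best = cand
    return best[2]


@pytest.fixture(scope="module")
def toy_dataset():
    rng = np.random.default_rng(0)
    samples = synthetic_sequences(14, rng)
    split = {s.video_id: ("validation" if i >= 12 else "train")
             for i, s in enumerate(samples)}
    return Dataset(samples=samples, split=split)


class TestKNN:
    def test_weighted_vote_on_1d_toy_set(self):
        model = PointModel(X=np.array([[0.0], [0.5], [1.0]]),
                           y=np.array([0, 1, 2]), k=3)
        pred = predict_knn(model, make_sample([[0.45]], None))
        assert pred[0] == 1  # expert: nearest neighbour dominates the vote

    def test_exact_match_wins_with_k1(self):
        model = PointModel(X=np.array([[0.1, 0.2, 0.3, 0.4],
                                       [0.9, 0.8, 0.7, 0.6]]),
                           y=np.array([2, 0]), k=1)
        pred = predict_knn(model, make_sample([[0.9, 0.8, 0.7, 0.6]], None))
        assert pred[0] == 0

    def test_equidistant_tie_breaks_by_class_order(self):
        # two neighbours at identical distance, one good one poor:
        # identical votes and mean distances, class order picks good
        model = PointModel(X=np.array([[0.0, 0.0, 0.0, 0.0],
                                       [2.0, 0.0, 0.0, 0.0]]),
                           y=np.array([2, 0]), k=2)
        pred = predict_knn(model, make_sample([[1.0, 0.0, 0.0, 0.0]], None))
        assert pred[0] == 0

    def test_matches_bruteforce_oracle_on_200_random_queries(self,
                                                             toy_dataset):
        model = train_knn(toy_dataset, KNNConfig(k=10), seed=0)
        rng = np.random.default_rng(42)
        queries = rng.uniform(-0.2, 1.2, size=(200, 4))
        pred = predict_knn(model, make_sample(queries, None))
        for q, p in zip(queries, pred):
            assert p == knn_oracle(model.X, model.y, q, model.k)

    def test_agrees_with_sklearn_off_ties(self, toy_dataset):
        from sklearn.neighbors import KNeighborsClassifier

        model = train_knn(toy_dataset, KNNConfig(k=10), seed=0)
        clf = KNeighborsClassifier(n_neighbors=10, weights="distance")
        clf.fit(model.X, model.y)
        rng = np.random.default_rng(3)
        queries = rng.uniform(0, 1, size=(100, 4))
        mine = predict_knn(model, make_sample(queries, None))
        theirs = clf.predict(queries)
        assert (mine == theirs).mean() >= 0.99

    def test_cv_report_has_10_seeded_reproducible_folds(self, toy_dataset):
        m1 = train_knn(toy_dataset, seed=5)
        m2 = train_knn(toy_dataset, seed=5)
        assert len(m1.cv_report["fold_accuracy"]) == 10
        assert m1.cv_report == m2.cv_report
        assert 0.0 <= m1.cv_report["mean_accuracy"] <= 1.0

    def test_k_larger_than_training_set_rejected(self, toy_dataset):
        with pytest.raises(TrainingError):
            train_knn(toy_dataset, KNNConfig(k=10 ** 6))

    def test_missing_class_rejected(self):
        samples = [make_sample(np.random.rand(30, 4), np.zeros(30),
                               video=f"v{i}") for i in range(12)]
        with pytest.raises(TrainingError):
            train_knn(Dataset(samples=samples))

    def test_nan_features_rejected_at_predict(self, toy_dataset):
        model = train_knn(toy_dataset, seed=0)
        bad = make_sample(np.full((3, 4), np.nan), None)
        with pytest.raises(ContractError):
            predict_knn(model, bad)


class TestBiLSTMNet:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        net = BiLSTMNet(n_features=2, hidden=3, n_classes=3, seed=1)
        T, B = 5, 2
        x = rng.standard_normal((T, B, 2))
        mask = np.ones((T, B))
        mask[3:, 1] = 0
        y = rng.integers(0, 3, size=(T, B))
        w = np.array([1.0, 2.0, 0.7])
        _, grads = net.loss_and_grads(x, mask, y, w)
        for name, p in net.params.items():
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps = 1e-6
            old = p[idx]
            p[idx] = old + eps
            lp = net.loss(x, mask, y, w)
            p[idx] = old - eps
            lm = net.loss(x, mask, y, w)
            p[idx] = old
            num = (lp - lm) / (2 * eps)
            assert grads[name][idx] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_architecture_contract(self):
        net = BiLSTMNet(n_features=4, hidden=200, n_classes=3, seed=0)
        assert net.params["Wx_f"].shape == (4, 800)
        assert net.params["Wh_b"].shape == (200, 800)
        assert net.params["Wo"].shape == (400, 3)
        assert LAYER_SPEC == ("sequence_input", "bilstm", "fully_connected",
                              "softmax", "classification_output")


@pytest.fixture(scope="module")
def trained_sequence_model(toy_dataset):
    config = LSTMConfig(hidden_units=200, max_epochs=30, patience=4, seed=11)
    return train_bilstm(toy_dataset, config)


class TestTrainBiLSTM:
    def test_separable_data_reaches_high_heldout_accuracy(
            self, trained_sequence_model):
        rng = np.random.default_rng(99)
        held_out = synthetic_sequences(6, rng)
        correct = total = 0
        for s in held_out:
            labels, _ = predict_bilstm(trained_sequence_model, s)
            correct += (labels == s.labels).sum()
            total += len(s)
        assert correct / total >= 0.95

    def test_early_stop_contract(self, trained_sequence_model):
        log = trained_sequence_model.training_log
        assert trained_sequence_model.stop_epoch <= 30
        assert trained_sequence_model.stop_epoch == len(log)
        vals = [e["val_loss"] for e in log]
        # kept weights correspond to the best validation epoch, which lies
        # within the patience window of the stop epoch
        assert np.argmin(vals) >= len(vals) - 1 - 4

    def test_default_capacity_is_five_layers_200_units(
            self, trained_sequence_model):
        assert trained_sequence_model.hidden_units == 200
        assert len(trained_sequence_model.layer_spec) == 5

    def test_empty_validation_split_rejected(self, toy_dataset):
        ds = Dataset(samples=toy_dataset.subset("train"),
                     split={s.video_id: "train"
                            for s in toy_dataset.subset("train")})
        with pytest.raises(ConfigError):
            train_bilstm(ds, LSTMConfig(max_epochs=2))

    def test_reproducible_given_seed(self, toy_dataset):
        cfg = LSTMConfig(hidden_units=16, max_epochs=4, patience=2, seed=3)
        m1 = train_bilstm(toy_dataset, cfg)
        m2 = train_bilstm(toy_dataset, cfg)
        assert m1.stop_epoch == m2.stop_epoch
        for k in m1.net.params:
            assert np.array_equal(m1.net.params[k], m2.net.params[k])

    def test_checkpoint_round_trip(self, tmp_path, trained_sequence_model,
                                   toy_dataset):
        save_model(trained_sequence_model, tmp_path / "ckpt")
        back = load_model(tmp_path / "ckpt")
        s = toy_dataset.samples[0]
        l1, p1 = predict_bilstm(trained_sequence_model, s)
        l2, p2 = predict_bilstm(back, s)
        assert np.array_equal(l1, l2)
        assert np.allclose(p1, p2)


class TestPredictBiLSTM:
    def test_posteriors_sum_to_one(self, trained_sequence_model,
                                   toy_dataset):
        _, post = predict_bilstm(trained_sequence_model,
                                 toy_dataset.samples[0])
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-6)
        assert post.shape[1] == 3

    def test_canonical_orientation_matters(self, trained_sequence_model,
                                           toy_dataset):
        # the model is trained on proximal->distal sequences; feeding a
        # reversed line and flipping the output back is not equivalent
        s = toy_dataset.samples[0]
        _, direct = predict_bilstm(trained_sequence_model, s)
        rev = make_sample(s.features[::-1].copy(), None)
        _, flipped = predict_bilstm(trained_sequence_model, rev)
        assert np.abs(direct - flipped[::-1]).max() > 1e-6

    def test_zone_overlaps_truth_on_separable_scene(
            self, trained_sequence_model):
        from icgfa.evaluation import extract_expert_zone, object_hit

        rng = np.random.default_rng(123)
        s = synthetic_sequences(1, rng)[0]
        labels, _ = predict_bilstm(trained_sequence_model, s)
        zone = extract_expert_zone(labels)
        truth = np.flatnonzero(s.labels == 1)
        band = (truth[0], truth[-1] + 1)
        assert not zone.no_prediction
        assert object_hit(zone, band)

    def test_wrong_feature_dimension_rejected(self, trained_sequence_model):
        with pytest.raises(ContractError):
            predict_bilstm(trained_sequence_model,
                           make_sample(np.zeros((5, 3)), None))
        with pytest.raises(ContractError):
            predict_bilstm(trained_sequence_model,
                           make_sample(np.zeros((1, 4)), None))
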