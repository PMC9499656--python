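import numpy as np
import pytest

from exprgat import (
    ClassifierHead,
    GATConfig,
    LabelVector,
    SplitSpec,
    TrainConfig,
    classify_forward,
    evaluate_auroc,
    nll_loss,
    split_samples,
    train_classifier,
)


def _labels(n, frac_pos=0.3, seed=0):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < frac_pos).astype(int)
    y[:2] = [0, 1]  # both classes present
    return LabelVector(labels=y, classes=[0, 1])


class TestSplitSamples:
    def test_protocol_sizes_n100(self):
        tr, va, te = split_samples(100, _labels(100), SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (64, 16, 20)

    def test_deterministic(self):
        a = split_samples(50, _labels(50), SplitSpec(seed=3))
        b = split_samples(50, _labels(50), SplitSpec(seed=3))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_partition(self):
        for n in (23, 57, 100):
            tr, va, te = split_samples(n, _labels(n), SplitSpec(seed=1))
            allidx = np.concatenate([tr, va, te])
            assert len(allidx) == n
            np.testing.assert_array_equal(np.sort(allidx), np.arange(n))

    def test_stratification_preserves_ratio(self):
        labels = _labels(200, frac_pos=0.25, seed=5)
        tr, va, te = split_samples(200, labels, SplitSpec(seed=2, stratified=True))
        y = labels.indices()
        overall = y.mean()
        for subset in (tr, te):
            assert abs(y[subset].mean() - overall) < 0.08

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            split_samples(4, _labels(4), SplitSpec())


class TestClassifyForward:
    def test_zero_weights_uniform(self, rng):
        head = ClassifierHead(W_cls=np.zeros((3, 4)), b_cls=np.zeros(3))
        P = classify_forward(rng.normal(size=(5, 4)), head)
        np.testing.assert_allclose(P, np.full((5, 3), 1 / 3))

    def test_closed_form_binary(self):
        # logits (ln 3, 0) -> probabilities (0.75, 0.25)
        head = ClassifierHead(W_cls=np.array([[np.log(3.0)], [0.0]]), b_cls=np.zeros(2))
        P = classify_forward(np.array([[1.0]]), head)
        np.testing.assert_allclose(P[0], [0.75, 0.25], atol=1e-12)

    def test_rows_normalized(self, rng):
        head = ClassifierHead(W_cls=rng.normal(size=(4, 6)), b_cls=rng.normal(size=4))
        P = classify_forward(rng.normal(size=(10, 6)) * 20, head)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(P >= 0)

    def test_dim_mismatch(self, rng):
        head = ClassifierHead(W_cls=np.zeros((2, 3)), b_cls=np.zeros(2))
        with pytest.raises(ValueError):
            classify_forward(rng.normal(size=(4, 5)), head)


class TestNLLLoss:
    def test_perfect_one_hot(self):
        probs = np.eye(3)[[0, 1, 2, 1]]
        labels = LabelVector(labels=np.array([0, 1, 2, 1]), classes=[0, 1, 2])
        assert nll_loss(probs, labels) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_binary_closed_form(self):
        probs = np.full((10, 2), 0.5)
        labels = LabelVector(labels=np.zeros(10, dtype=int), classes=[0, 1])
        assert nll_loss(probs, labels, np.arange(10)) == pytest.approx(10 * np.log(2), abs=1e-9)

    def test_hand_sum(self):
        probs = np.array([[0.7, 0.3], [0.2, 0.8], [0.5, 0.5]])
        labels = LabelVector(labels=np.array([0, 1, 1]), classes=[0, 1])
        expected = -(np.log(0.7) + np.log(0.8) + np.log(0.5))
        assert nll_loss(probs, labels) == pytest.approx(expected, abs=1e-9)

    def test_label_outside_classes(self):
        probs = np.full((3, 2), 0.5)
        labels = LabelVector(labels=np.array([0, 1, 2]), classes=[0, 1, 2])
        with pytest.raises(ValueError):
            nll_loss(probs, labels)


class TestEvaluateAUROC:
    def test_perfect_ranking(self):
        assert evaluate_auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_inverted_ranking(self):
        assert evaluate_auroc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1]) == 0.0

    def test_pair_counting_example(self):
        assert evaluate_auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_auroc([0.1, 0.2], [1, 1])


@pytest.fixture(scope="module")
def trained():
    from exprgat import FeatureMatrix, SynthConfig, build_adjacency, generate_binary_task, pairwise_correlation

    cfg = SynthConfig(n_samples=80, n_features=40, k_groups=2, separation=5.0, seed=11)
    expr, labels = generate_binary_task(cfg)
    X = FeatureMatrix.from_expression(expr)
    A = build_adjacency(pairwise_correlation(X), 0.15)
    gat = GATConfig(embed_size=4, heads=4)
    tc = TrainConfig(max_epochs=120, patience=30, seed=0)
    model = train_classifier(X, A, labels, split=SplitSpec(seed=0), gat=gat, train=tc)
    return X, A, labels, gat, tc, model


class TestTraining:
    def test_loss_decreases(self, trained):
        _, _, _, _, _, model = trained
        hist = model.history["train_loss"]
        assert hist[-1] < hist[0]

    def test_separable_task_auroc(self, trained):
        X, A, labels, _, _, model = trained
        _, _, te = model.history["split"]
        y = labels.indices()
        scores = model.decision_scores(X, A)
        assert evaluate_auroc(scores[te], (y[te] == 1).astype(int)) >= 0.95

    def test_training_deterministic(self, trained):
        X, A, labels, gat, tc, model = trained
        again = train_classifier(X, A, labels, split=SplitSpec(seed=0), gat=gat, train=tc)
        np.testing.assert_allclose(
            model.history["train_loss"], again.history["train_loss"], atol=1e-6
        )

    def test_forward_permutation_equivariance(self, trained, rng):
        X, A, labels, _, _, model = trained
        perm = rng.permutation(X.n_samples)
        P = model.predict_proba(X, A)
        Pp = model.predict_proba(X.values[perm], A.values[np.ix_(perm, perm)])
        np.testing.assert_allclose(Pp, P[perm], atol=1e-6)
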