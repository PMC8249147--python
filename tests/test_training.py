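import numpy as np
import pytest

from frbain.clustering import build_kernel_bank
from frbain.errors import ValidationError
from frbain.network import RuleIndex, build_model
from frbain.signal import Signal, SignalDataset
from frbain.synthetic import GeneratorSpec, generate
from frbain.training import (TrainingConfig, evaluate, learning_rate, loss,
                             loss_and_gradients, precompute_distances,
                             predict_dataset, train)


def random_training_case(rng, B=6, K=3, m=7):
    """A random small parameter set plus a distance batch, away from the
    membership clamp boundaries so gradients are smooth."""
    class_index = np.sort(np.concatenate([
        np.arange(K), rng.integers(0, K, size=m - K)]))
    counts = RuleIndex(n_classes=K).counts
    dists = rng.uniform(0.5, 3.0, size=(B, m))
    params = {
        "sigma": rng.uniform(1.0, 3.0, m),
        "a": rng.uniform(0.5, 2.0, m),
        "c": rng.uniform(0.0, 0.2, m),
        "W": rng.normal(0, 0.5, (K ** K, K)),
        "r": rng.normal(0, 0.5, K),
    }
    y = rng.integers(0, K, B)
    return dists, y, params, class_index, counts


def finite_difference_max_error(dists, y, params, class_index, counts):
    _, grads = loss_and_gradients(dists, y, params, class_index, counts)
    worst = 0.0
    for name, p in params.items():
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            ix = it.multi_index
            h = 1e-6 * max(1.0, abs(p[ix]))
            orig = p[ix]
            p[ix] = orig + h
            lp, _ = loss_and_gradients(dists, y, params, class_index, counts)
            p[ix] = orig - h
            lm, _ = loss_and_gradients(dists, y, params, class_index, counts)
            p[ix] = orig
            fd = (lp - lm) / (2 * h)
            ga = grads[name][ix]
            worst = max(worst, abs(ga - fd) / max(abs(fd), abs(ga), 1.0))
    return worst


class TestLoss:
    def test_perfect_predictions_zero(self):
        p = np.eye(3)
        assert loss(p, np.arange(3)) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_predictions_log_k(self):
        p = np.full((5, 4), 0.25)
        assert loss(p, np.zeros(5, dtype=int)) == pytest.approx(np.log(4))

    def test_batch_mean_linearity(self, rng):
        p = rng.dirichlet(np.ones(3), size=2)
        y = np.array([0, 2])
        individual = [loss(p[i:i + 1], y[i:i + 1]) for i in range(2)]
        assert loss(p, y) == pytest.approx(np.mean(individual))


class TestSchedule:
    def test_step_decay_values(self):
        cfg = TrainingConfig()
        assert learning_rate(0, cfg) == pytest.approx(0.5)
        assert learning_rate(49, cfg) == pytest.approx(0.5)
        assert learning_rate(50, cfg) == pytest.approx(0.05)
        assert learning_rate(100, cfg) == pytest.approx(0.005)
        assert learning_rate(120, cfg) == pytest.approx(0.005)

    def test_closed_form(self):
        cfg = TrainingConfig(initial_lr=1.0, lr_decay_every=10,
                             lr_decay_factor=0.5)
        for epoch in range(40):
            assert learning_rate(epoch, cfg) == pytest.approx(
                1.0 * 0.5 ** (epoch // 10))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            TrainingConfig(initial_lr=-1.0)
        with pytest.raises(ValidationError):
            TrainingConfig(lr_decay_factor=1.5)
        with pytest.raises(ValidationError):
            TrainingConfig(optimizer="rmsprop")


class TestGradients:
    def test_analytic_matches_finite_differences(self, rng):
        for _ in range(5):
            case = random_training_case(rng)
            assert finite_difference_max_error(*case) < 1e-5


class TestPrecomputeDistances:
    def test_matches_pairwise_calls(self, toy_bank, rng):
        from frbain.dtw import dtw_distance
        ds = SignalDataset([Signal(rng.normal(size=(1, 12)), record_id="x",
                                   label="A")])
        model = build_model(toy_bank, seed=0)
        table = precompute_distances(ds, model)
        for j, z in enumerate(toy_bank.centers):
            assert table[0, j] == pytest.approx(
                dtw_distance(ds[0], z).distance)

    def test_deterministic(self, toy_bank, small_generated):
        model = build_model(toy_bank, seed=0)
        ds = SignalDataset([Signal(np.ones((1, 8)) * 0.3, record_id="x")])
        t1 = precompute_distances(ds, model)
        t2 = precompute_distances(ds, model)
        np.testing.assert_array_equal(t1, t2)


@pytest.fixture(scope="module")
def two_class():
    spec = GeneratorSpec(K=2, subclasses_per_class=(1, 1), n_total=40,
                         base_length=32, n_channels=2, seed=17)
    return generate(spec)


class TestTrain:
    def test_separable_problem_learns(self, two_class):
        ds = two_class.dataset
        bank = build_kernel_bank(ds, c_ranges=(1, 1), seed=0)
        model = build_model(bank, seed=0)
        cfg = TrainingConfig(max_epochs=50, batch_count=4, seed=0)
        trained, history = train(model, ds, cfg)
        assert history.loss[-1] < history.loss[0]
        assert evaluate(trained, ds).accuracy >= 0.95

    def test_seeded_determinism(self, two_class):
        ds = two_class.dataset
        bank = build_kernel_bank(ds, c_ranges=(1, 1), seed=0)
        model = build_model(bank, seed=0)
        cfg = TrainingConfig(max_epochs=5, batch_count=4, seed=9)
        d = precompute_distances(ds, model)
        t1, h1 = train(model, ds, cfg, distances=d)
        t2, h2 = train(model, ds, cfg, distances=d)
        assert h1.loss == h2.loss
        np.testing.assert_array_equal(t1.ts.weights, t2.ts.weights)
        np.testing.assert_array_equal(t1.frbn.sigma, t2.frbn.sigma)

    def test_lr_history_follows_schedule(self, two_class):
        ds = two_class.dataset
        bank = build_kernel_bank(ds, c_ranges=(1, 1), seed=0)
        model = build_model(bank, seed=0)
        cfg = TrainingConfig(max_epochs=8, lr_decay_every=3,
                             lr_decay_factor=0.1, stop_loss=1e-12,
                             batch_count=4, seed=0)
        _, history = train(model, ds, cfg)
        expected = [0.5 * 0.1 ** (e // 3) for e in range(history.n_epochs)]
        np.testing.assert_allclose(history.lr, expected)

    def test_zero_gradient_leaves_parameters_unchanged(self):
        # records equidistant from every center, balanced labels, zero head
        # weights: the gradient vanishes identically, so one SGD epoch is a
        # no-op
        from frbain.clustering import KernelBank
        z = np.zeros((1, 8))
        bank = KernelBank(
            centers=[Signal(z + 1.0, record_id="cA", label="A"),
                     Signal(z - 1.0, record_id="cB", label="B")],
            class_index=np.array([0, 1]), subclass_index=np.array([0, 0]),
            class_order=["A", "B"])
        ds = SignalDataset([
            Signal(z, record_id="p", label="A"),
            Signal(z.copy(), record_id="q", label="B"),
        ])
        model = build_model(bank, seed=0, weight_scale=0.0)
        cfg = TrainingConfig(max_epochs=1, optimizer="sgd", batch_count=1,
                             seed=0, stop_loss=1e-9)
        trained, _ = train(model, ds, cfg)
        np.testing.assert_allclose(trained.ts.weights, model.ts.weights,
                                   atol=1e-15)
        np.testing.assert_allclose(trained.frbn.sigma, model.frbn.sigma,
                                   atol=1e-12)
        np.testing.assert_allclose(trained.frbn.shape_a, model.frbn.shape_a,
                                   atol=1e-12)

    def test_empty_dataset_rejected(self, toy_model):
        with pytest.raises(ValidationError):
            train(toy_model, SignalDataset([]), TrainingConfig(max_epochs=1))


class TestEvaluate:
    def _dataset_with_preds(self, toy_model, rng, n=6):
        # records identical to kernel centers get predicted crisply
        sigs = []
        for i in range(n):
            c = toy_model.bank.centers[i % 4]
            sigs.append(Signal(c.values, record_id=f"e{i}", label=c.label))
        return SignalDataset(sigs)

    def test_perfect_classifier_metrics(self, toy_bank):
        model = build_model(toy_bank, seed=0, a_init=4.0, weight_scale=0.0)
        # bias the head with the identity pattern->class map via pattern sums
        ds = SignalDataset([Signal(c.values, record_id=f"e{i}", label=c.label)
                            for i, c in enumerate(toy_bank.centers)])
        rep = evaluate(model, ds)
        if rep.accuracy == 1.0:
            assert np.all(rep.precision == 1.0)
            assert np.all(rep.recall == 1.0)
            assert np.all(np.diag(rep.confusion) == rep.support)

    def test_hand_confusion_matrix(self, monkeypatch, toy_model):
        # force predictions and check the metric arithmetic directly
        from frbain import training as tr

        ds = SignalDataset([
            Signal(np.ones((1, 8)) * i, record_id=str(i), label=lab)
            for i, lab in enumerate(["A", "A", "A", "B", "B", "B"])
        ])
        fixed = ["A", "A", "B", "B", "B", "A"]

        class P:
            def __init__(self, lab):
                self.label = lab

        monkeypatch.setattr(tr, "predict_dataset",
                            lambda m, d, distances=None: [P(l) for l in fixed])
        rep = tr.evaluate(toy_model, ds)
        # class A: tp=2, fp=1, fn=1 -> P=R=2/3; same for B by symmetry
        assert rep.precision[0] == pytest.approx(2 / 3)
        assert rep.recall[0] == pytest.approx(2 / 3)
        assert rep.f1[0] == pytest.approx(2 / 3)
        assert rep.accuracy == pytest.approx(4 / 6)
        np.testing.assert_array_equal(rep.confusion, [[2, 1], [1, 2]])

    def test_single_class_predictions(self, monkeypatch, toy_model):
        from frbain import training as tr
        ds = SignalDataset([
            Signal(np.ones((1, 8)), record_id=str(i), label=lab)
            for i, lab in enumerate(["A", "A", "B", "B"])
        ])

        class P:
            def __init__(self, lab):
                self.label = lab

        monkeypatch.setattr(tr, "predict_dataset",
                            lambda m, d, distances=None: [P("A")] * 4)
        rep = tr.evaluate(toy_model, ds)
        assert rep.accuracy == pytest.approx(0.5)
        assert rep.recall[0] == pytest.approx(1.0)
        assert rep.recall[1] == pytest.approx(0.0)

    def test_unlabeled_record_rejected(self, toy_model):
        ds = SignalDataset([Signal(np.ones((1, 8)), record_id="u")])
        with pytest.raises(ValidationError):
            evaluate(toy_model, ds)
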