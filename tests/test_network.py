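import numpy as np
import pytest

from frbain.clustering import KernelBank
from frbain.dtw import dtw_distance
from frbain.errors import (DegenerateMembershipError, StructureError,
                           ValidationError)
from frbain.network import (EFRBAINModel, RuleIndex, TSParams, build_model,
                            forward, frbn_membership, fuzzify, load_model,
                            pattern_layer, regularize, rule_layer, save_model,
                            ts_classify)
from frbain.signal import Signal


class TestFRBNMembership:
    def test_sigmoid_at_origin(self):
        assert frbn_membership(0.0, 1.0, 0.0, 0.0) == pytest.approx(0.5)

    def test_sigmoid_midpoint(self):
        # d = sigma*sqrt(a) gives exponent zero
        assert frbn_membership(np.sqrt(2.0) * 1.5, 1.5, 2.0, 0.0) == \
            pytest.approx(0.5)

    def test_saturation_at_large_distance(self):
        assert frbn_membership(1e4, 1.0, 1.0, 0.0) == pytest.approx(0.0)
        assert frbn_membership(1e4, 1.0, 1.0, 0.3) == pytest.approx(0.0)

    def test_monotone_nonincreasing_in_distance(self, rng):
        for _ in range(20):
            sigma = rng.uniform(0.1, 5.0)
            a = rng.uniform(-2.0, 4.0)
            c = rng.uniform(0.0, 0.9)
            d = np.sort(rng.uniform(0, 10, size=50))
            mu = frbn_membership(d, sigma, a, c)
            assert np.all(np.diff(mu) <= 1e-12)
            assert np.all((mu >= 0) & (mu <= 1))

    def test_invalid_sigma(self):
        with pytest.raises(ValidationError):
            frbn_membership(1.0, 0.0, 1.0, 0.0)


class TestRegularize:
    def test_normalises_to_simplex(self):
        np.testing.assert_allclose(regularize(np.array([2.0, 2.0, 6.0])),
                                   [0.2, 0.2, 0.6])

    def test_idempotent_on_simplex(self):
        v = np.array([0.3, 0.7])
        np.testing.assert_allclose(regularize(v), v)

    def test_single_positive_element(self):
        np.testing.assert_allclose(regularize(np.array([0.42])), [1.0])

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateMembershipError):
            regularize(np.zeros(3))


class TestPatternAndRuleLayers:
    def test_sum_and_max_pooling(self, toy_bank):
        h = np.array([0.5, 0.3, 0.15, 0.05])
        np.testing.assert_allclose(pattern_layer(h, toy_bank, "sum"),
                                   [0.8, 0.2])
        np.testing.assert_allclose(pattern_layer(h, toy_bank, "max"),
                                   [0.5, 0.15])

    def test_sum_pooling_conserves_total(self, toy_bank, rng):
        h = rng.uniform(size=4)
        assert pattern_layer(h, toy_bank, "sum").sum() == pytest.approx(h.sum())

    def test_rule_count_and_lexicographic_order(self):
        rules = RuleIndex(n_classes=2)
        assert rules.L == 4
        assert rules.tuples.tolist() == [[0, 0], [0, 1], [1, 0], [1, 1]]

    def test_one_hot_pattern_fires_single_rule(self):
        rules = RuleIndex(n_classes=3)
        z = rule_layer(np.array([1.0, 0.0, 0.0]), rules)
        assert z.sum() == pytest.approx(1.0)
        assert z[0] == pytest.approx(1.0)  # the all-class-0 tuple is first

    def test_simplex_input_gives_simplex_output(self, rng):
        rules = RuleIndex(n_classes=3)
        q = rng.dirichlet(np.ones(3))
        z = rule_layer(q, rules)
        # multinomial identity: sum over all K-tuples of products = (sum q)^K
        assert z.sum() == pytest.approx(1.0)


class TestTSClassifier:
    def test_zero_params_uniform(self):
        ts = TSParams(weights=np.zeros((16, 4)), bias=np.zeros(4))
        np.testing.assert_allclose(ts_classify(np.full(16, 1 / 16), ts),
                                   np.full(4, 0.25))

    def test_bias_dominance(self):
        ts = TSParams(weights=np.zeros((16, 4)),
                      bias=np.array([10.0, 0, 0, 0]))
        p = ts_classify(np.full(16, 1 / 16), ts)
        assert p[0] > 0.999

    def test_matches_direct_affine_softmax(self, rng):
        L, K = 9, 3
        ts = TSParams(weights=rng.normal(size=(L, K)), bias=rng.normal(size=K))
        qn = rng.dirichlet(np.ones(L))
        scores = qn @ ts.weights + ts.bias
        expected = np.exp(scores) / np.exp(scores).sum()
        np.testing.assert_allclose(ts_classify(qn, ts), expected, atol=1e-12)


class TestForward:
    def test_kernel_center_classified_to_its_class(self, toy_bank):
        # align the head with the rule structure: weight each rule by the
        # multiplicity of each class in its tuple, so scores ~ K * q_k
        model = build_model(toy_bank, seed=0, a_init=4.0, weight_scale=0.0)
        model.ts.weights = model.rules.counts.astype(float)
        for center, k in zip(toy_bank.centers, toy_bank.class_index):
            pred = forward(center, model)
            assert pred.label == toy_bank.class_order[k]
            assert np.argmax(pred.pattern_memberships) == k

    def test_conservation_chain(self, toy_model, rng):
        x = Signal(rng.normal(size=(1, 16)))
        pred = forward(x, toy_model)
        assert pred.class_scores.sum() == pytest.approx(1.0, abs=1e-9)
        assert pred.rule_activations.sum() == pytest.approx(1.0, abs=1e-9)
        assert pred.pattern_memberships.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all((pred.frbn_memberships >= 0)
                      & (pred.frbn_memberships <= 1))

    def test_symmetric_banks_give_uniform_scores(self):
        t = np.linspace(0, 1, 12)
        z = np.sin(2 * np.pi * t)[None, :]
        bank = KernelBank(
            centers=[Signal(z, record_id="a", label="A"),
                     Signal(z, record_id="b", label="B")],
            class_index=np.array([0, 1]), subclass_index=np.array([0, 0]),
            class_order=["A", "B"])
        model = build_model(bank, seed=0, weight_scale=0.0)
        pred = forward(Signal(np.cos(2 * np.pi * t)[None, :]), model)
        np.testing.assert_allclose(pred.class_scores, [0.5, 0.5], atol=1e-12)

    def test_within_class_bank_permutation_invariance(self, toy_bank, rng):
        model = build_model(toy_bank, seed=0)
        permuted = KernelBank(
            centers=[toy_bank.centers[i] for i in (1, 0, 3, 2)],
            class_index=toy_bank.class_index,
            subclass_index=toy_bank.subclass_index,
            class_order=toy_bank.class_order)
        model_p = EFRBAINModel(
            bank=permuted,
            frbn=type(model.frbn)(sigma=model.frbn.sigma[[1, 0, 3, 2]],
                                  shape_a=model.frbn.shape_a[[1, 0, 3, 2]],
                                  offset_c=model.frbn.offset_c[[1, 0, 3, 2]]),
            rules=model.rules, ts=model.ts, class_order=model.class_order)
        x = Signal(rng.normal(size=(1, 16)))
        np.testing.assert_allclose(forward(x, model).class_scores,
                                   forward(x, model_p).class_scores,
                                   atol=1e-12)


class TestBuildModel:
    def test_structure_counts(self, toy_bank):
        model = build_model(toy_bank, seed=0)
        assert model.m == 4
        assert model.L == 2 ** 2
        assert model.ts.weights.shape == (4, 2)

    def test_sigma_initialised_to_median_center_distance(self, toy_bank):
        model = build_model(toy_bank, seed=0)
        dists = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i != j:
                    dists[i, j] = dtw_distance(
                        toy_bank.centers[i], toy_bank.centers[j]).distance
        for j in range(4):
            expected = np.median(np.delete(dists[j], j))
            assert model.frbn.sigma[j] == pytest.approx(expected)

    def test_seeded_determinism(self, toy_bank):
        m1 = build_model(toy_bank, seed=7)
        m2 = build_model(toy_bank, seed=7)
        np.testing.assert_array_equal(m1.ts.weights, m2.ts.weights)

    def test_rule_cap(self, toy_bank):
        with pytest.raises(StructureError):
            build_model(toy_bank, seed=0, rule_cap=3)


class TestModelArchive:
    def test_round_trip_forward_bitwise(self, toy_model, tmp_path, rng):
        x = Signal(rng.normal(size=(1, 16)))
        before = forward(x, toy_model).class_scores
        save_model(toy_model, str(tmp_path / "m"))
        loaded = load_model(str(tmp_path / "m"))
        after = forward(x, loaded).class_scores
        np.testing.assert_array_equal(before, after)

    def test_unequal_length_centers_preserved(self, tmp_path):
        centers = [Signal(np.ones((1, 10)), record_id="a", label="A"),
                   Signal(np.ones((1, 14)) * 2, record_id="b", label="B")]
        bank = KernelBank(centers=centers, class_index=np.array([0, 1]),
                          subclass_index=np.array([0, 0]),
                          class_order=["A", "B"])
        model = build_model(bank, seed=0)
        save_model(model, str(tmp_path / "m"))
        loaded = load_model(str(tmp_path / "m"))
        assert [c.n_timepoints for c in loaded.bank.centers] == [10, 14]

    def test_truncated_archive_rejected(self, toy_model, tmp_path):
        save_model(toy_model, str(tmp_path / "m"))
        (tmp_path / "m" / "params.json").write_text("{\"version\": 1")
        with pytest.raises(Exception):
            load_model(str(tmp_path / "m"))
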