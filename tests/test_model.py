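import numpy as np
import pandas as pd
import pytest

from coroscreen.model import (POSITIVE_CLASS, SEResNetClassifier, TensorCase, TrainConfig,
                              PredictionSet, predict_case, split_patientwise, task_label,
                              train_task)
from coroscreen.nn import NetworkConfig, build_network


def _micro_net():
    return NetworkConfig(n_stages=1, blocks_per_stage=(1,), block_type="basic",
                         base_channels=2, se_reduction=2, input_dims=(6, 6, 4))


def _toy_cases(n=20, seed=0, dims=(6, 6, 4)):
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        y = i % 2
        x = rng.random(dims).astype(np.float32)
        if y:
            x = np.clip(x + 0.4, 0, 1)
        cases.append(TensorCase(f"p{i:03d}", [x], y))
    return cases


class TestSplit:
    def test_ninety_ten_split_of_100_patients(self):
        ids = [f"p{i}" for i in range(100)]
        train, val = split_patientwise(ids, 0.9, seed=0)
        assert len(train) == 90 and len(val) == 10
        assert set(train) | set(val) == set(ids)
        assert not set(train) & set(val)

    def test_same_seed_same_split(self):
        ids = [f"p{i}" for i in range(37)]
        assert split_patientwise(ids, seed=5) == split_patientwise(ids, seed=5)
        assert split_patientwise(ids, seed=5) != split_patientwise(ids, seed=6)

    def test_duplicate_ids_stay_together(self):
        # phases appear as repeated case ids; the split sees unique patients
        ids = ["a", "a", "b", "c", "c", "c", "d", "e", "f", "g"]
        train, val = split_patientwise(ids, 0.9, seed=1)
        assert sorted(train + val) == sorted(set(ids))

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            split_patientwise(["only"], 0.9, 0)


class TestTaskLabels:
    def test_origin_and_risk_only_for_anomalous(self):
        normal = TensorCase("n", [np.zeros((2, 2, 2))], 0)
        assert task_label(normal, "anomaly") == 0
        assert task_label(normal, "origin") is None
        assert task_label(normal, "risk") is None
        anom = TensorCase("a", [np.zeros((2, 2, 2))], 1, y_origin="right", y_risk="low")
        assert task_label(anom, "origin") == 1
        assert task_label(anom, "risk") == 0
        assert POSITIVE_CLASS == {"anomaly": 1, "origin": "right", "risk": "high"}


class TestPredictionAggregation:
    def test_ensemble_is_arithmetic_mean(self):
        models = [build_network(_micro_net(), seed=s) for s in range(3)]
        case = TensorCase("c", [np.random.default_rng(0).random((6, 6, 4)).astype(np.float32)], 1,
                          y_origin="right", y_risk="high")
        ps = predict_case(models, case)
        assert np.isclose(ps.ensemble_prob, ps.member_probs.mean())
        # permutation invariance and min/max bounds
        ps_rev = predict_case(models[::-1], case)
        assert np.isclose(ps.ensemble_prob, ps_rev.ensemble_prob)
        assert ps.member_probs.min() <= ps.ensemble_prob <= ps.member_probs.max()

    def test_single_member_equals_itself(self):
        model = build_network(_micro_net(), seed=0)
        case = TensorCase("c", [np.zeros((6, 6, 4), dtype=np.float32)], 0)
        ps = predict_case([model], case)
        assert ps.ensemble_prob == ps.member_probs[0]

    def test_phases_average(self):
        model = build_network(_micro_net(), seed=0)
        rng = np.random.default_rng(1)
        t1, t2 = rng.random((6, 6, 4)).astype(np.float32), rng.random((6, 6, 4)).astype(np.float32)
        p1 = predict_case([model], TensorCase("a", [t1], 0)).ensemble_prob
        p2 = predict_case([model], TensorCase("b", [t2], 0)).ensemble_prob
        both = predict_case([model], TensorCase("ab", [t1, t2], 0)).ensemble_prob
        assert np.isclose(both, (p1 + p2) / 2)

    def test_prediction_set_validates_ensemble_mean(self):
        with pytest.raises(ValueError):
            PredictionSet("x", "anomaly", [0.2, 0.4], 0.5)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            predict_case([], TensorCase("c", [np.zeros((2, 2, 2))], 0))
        model = build_network(_micro_net(), seed=0)
        with pytest.raises(ValueError):
            predict_case([model], TensorCase("c", [], 0))


class TestTraining:
    def test_history_and_execution_contract(self):
        cases = _toy_cases(20)
        cfg = TrainConfig(total_epochs=5, n_members=2, seed=0, patience=10)
        trained = train_task(cases, "anomaly", _micro_net(), cfg)
        assert len(trained.members) == 2
        for hist in trained.histories:
            assert len(hist) <= 5
            assert np.isfinite(hist.val_loss.iloc[-1])
        assert not set(trained.train_ids) & set(trained.val_ids)

    def test_early_stopping_with_scripted_validation_loss(self):
        """Patience 2 with validation loss rising monotonically after epoch 2
        halts training by epoch 4 (0-based)."""
        cases = _toy_cases(10)
        cfg = TrainConfig(total_epochs=50, n_members=1, seed=0, patience=2)
        script = [1.0, 0.8, 0.5, 0.9, 1.1, 1.3, 1.5]

        def eval_fn(model, epoch):
            return script[min(epoch, len(script) - 1)], 0.5

        trained = train_task(cases, "anomaly", _micro_net(), cfg, eval_fn=eval_fn)
        hist = trained.histories[0]
        assert hist.epoch.iloc[-1] == 4          # best at 2, patience 2 -> stop at 4
        assert len(hist) == 5

    def test_zero_epoch_fine_tune_is_backbone_plus_fresh_head(self):
        """Fine-tuning for 0 epochs leaves the transferred backbone and the
        freshly initialized head untouched."""
        from coroscreen.model import fine_tune, fine_tune_init
        from coroscreen.nn import build_network
        pretrained = build_network(_micro_net(), seed=3)
        cases = _toy_cases(10)
        cfg = TrainConfig(total_epochs=0, n_members=1, seed=4)
        trained = fine_tune(pretrained, cases, "anomaly", _micro_net(), cfg,
                            eval_fn=lambda model, epoch: (0.0, 1.0))
        reference = fine_tune_init(pretrained, _micro_net(), seed=cfg.seeds()[0])
        x = np.stack([c.tensors[0] for c in cases])
        assert np.allclose(trained.members[0].predict_proba(x), reference.predict_proba(x))

    def test_single_class_partition_raises(self):
        cases = [TensorCase(f"p{i}", [np.zeros((6, 6, 4), dtype=np.float32)], 1,
                            y_origin="right", y_risk="high") for i in range(10)]
        cfg = TrainConfig(total_epochs=2, n_members=1)
        with pytest.raises(ValueError, match="single class"):
            train_task(cases, "anomaly", _micro_net(), cfg)

    def test_member_seeds_length_checked(self):
        with pytest.raises(ValueError):
            TrainConfig(n_members=3, member_seeds=(1, 2)).seeds()


class TestSEResNetClassifier:
    def test_sklearn_protocol_and_learning(self):
        from sklearn.base import clone
        rng = np.random.default_rng(0)
        X = rng.random((24, 6, 6, 4)).astype(np.float32)
        y = np.repeat([0, 1], 12)
        X[y == 1] = np.clip(X[y == 1] + 0.5, 0, 1)
        clf = SEResNetClassifier(net_config=_micro_net(),
                                 train_config=TrainConfig(total_epochs=15, n_members=1, seed=0,
                                                          lr0=0.01, patience=30))
        clone(clf)                                 # get_params/set_params round-trip
        clf.fit(X, y)
        probs = clf.predict_proba(X)
        assert probs.shape == (24, 2)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert clf.score(X, y) >= 0.75
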