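"""Training/evaluation tests: model variants, schedule arithmetic, early
stopping, metrics against an independent reference, efficiency statistics,
gate analysis and activation maps."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import precision_recall_fscore_support

from freshfusion.image_branch import BackboneConfig
from freshfusion.nn import Tensor
from freshfusion.training import (ModelResultRow, ModelSizeConfig, TrainConfig,
                                  activation_map, build_model,
                                  classification_metrics, efficiency_metrics,
                                  evaluate, gate_analysis,
                                  prepare_training_data, stage_from_time,
                                  train)
from freshfusion.preprocess import split_dataset

TINY_SIZE = ModelSizeConfig(
    backbone=BackboneConfig(width=0.125, single_repeats=True))


@pytest.fixture(scope="module")
def tiny_data(tiny_dataset):
    ds = split_dataset(tiny_dataset, 0.8, seed=0)
    return prepare_training_data(ds)


class TestBuildModel:
    @pytest.mark.parametrize("variant", ["full", "image_only", "chem_only",
                                         "concat"])
    def test_variants_build_and_forward(self, variant, rng):
        model = build_model(variant, TINY_SIZE, seed=0)
        imgs = Tensor(rng.random((2, 3, 64, 64)).astype(np.float32))
        chem = Tensor(rng.random((2, 3, 6)).astype(np.float32))
        out = model(imgs if variant != "chem_only" else None,
                    chem if variant != "image_only" else None)
        assert out.shape == (2, 3)
        assert model.num_parameters() > 0

    def test_head_hidden_width_is_128(self):
        model = build_model("full", TINY_SIZE, seed=0)
        assert model.head.fc1.weight.shape[1] == 128
        assert model.head.fc2.weight.shape == (128, 3)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_model("ensemble", TINY_SIZE)


class TestSchedule:
    def test_lr_decays_10pct_every_20_epochs(self):
        cfg = TrainConfig()
        assert cfg.lr_at_epoch(1) == pytest.approx(1e-4)
        assert cfg.lr_at_epoch(20) == pytest.approx(1e-4)
        assert cfg.lr_at_epoch(21) == pytest.approx(9e-5)
        assert cfg.lr_at_epoch(41) == pytest.approx(8.1e-5)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr0=0.0)


class TestTrainLoop:
    def test_history_structure_and_determinism(self, tiny_data):
        cfg = TrainConfig.slim(max_epochs=2, seed=3)
        histories = []
        for _ in range(2):
            model = build_model("chem_only", TINY_SIZE, seed=3)
            histories.append(train(model, tiny_data, cfg))
        assert histories[0]["val_accuracy"] == histories[1]["val_accuracy"]
        assert histories[0]["train_loss"] == histories[1]["train_loss"]
        assert len(histories[0]["epoch"]) == 2

    def test_early_stopping_on_flat_validation_accuracy(self, tiny_data):
        # a vanishing learning rate freezes the model, so validation accuracy
        # never improves and training stops after the patience window
        cfg = TrainConfig(lr0=1e-12, max_epochs=10, patience=2, seed=0)
        model = build_model("chem_only", TINY_SIZE, seed=0)
        history = train(model, tiny_data, cfg)
        # training halts exactly `patience` epochs after the best one
        assert len(history["epoch"]) < cfg.max_epochs
        assert history["epoch"][-1] == history["best_epoch"] + cfg.patience

    def test_empty_split_rejected(self, tiny_data):
        import dataclasses as dc
        broken = dc.replace(tiny_data,
                            split=np.array(["train"] * len(tiny_data.split)))
        model = build_model("chem_only", TINY_SIZE, seed=0)
        with pytest.raises(ValueError):
            train(model, broken, TrainConfig())


class TestMetrics:
    def test_toy_confusion_matrix(self):
        y_true = [0] * 4 + [1] * 4
        y_pred = [0, 0, 0, 1, 1, 1, 1, 0]
        m = classification_metrics(y_true, y_pred, n_classes=2,
                                   class_names=("a", "b"))
        assert np.array_equal(m.confusion, [[3, 1], [1, 3]])
        assert m.accuracy == pytest.approx(0.75)

    def test_perfect_predictions(self):
        m = classification_metrics([0, 1, 2], [0, 1, 2])
        assert m.accuracy == 1.0
        assert m.precision_macro == m.recall_macro == 1.0

    def test_confusion_row_sums_equal_support(self, rng):
        y_true = rng.integers(0, 3, size=200)
        y_pred = rng.integers(0, 3, size=200)
        m = classification_metrics(y_true, y_pred)
        assert np.array_equal(m.confusion.sum(axis=1),
                              m.per_class["support"])

    def test_agreement_with_reference_implementation(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            y_true = rng.integers(0, 3, size=n)
            y_pred = rng.integers(0, 3, size=n)
            m = classification_metrics(y_true, y_pred)
            p, r, f1, _ = precision_recall_fscore_support(
                y_true, y_pred, labels=[0, 1, 2], average="macro",
                zero_division=0)
            assert m.accuracy == pytest.approx((y_true == y_pred).mean())
            assert m.precision_macro == pytest.approx(p, abs=1e-9)
            assert m.recall_macro == pytest.approx(r, abs=1e-9)
            assert m.f1_macro == pytest.approx(f1, abs=1e-9)


class TestEfficiency:
    def test_accuracy_per_million_parameters(self):
        row = ModelResultRow("ours", acc=99.61, recall=99.19, f1=99.25,
                             params_m=39.32, precision=99.48)
        assert efficiency_metrics(row).acc_per_mparam == 2.53

    def test_f1_per_million_parameters(self):
        row = ModelResultRow("FoodNet", acc=73.37, recall=72.54, f1=73.03,
                             params_m=25.46)
        assert efficiency_metrics(row).f1_per_mparam == 2.87

    def test_precision_recall_gap(self):
        row = ModelResultRow("gated", acc=97.44, recall=97.20, f1=97.29,
                             params_m=26.83, precision=97.55)
        assert efficiency_metrics(row).precision_recall_gap == 0.35

    def test_deltas_versus_reference(self):
        ours = ModelResultRow("ours", acc=99.61, recall=99.19, f1=99.25,
                              params_m=39.32)
        concat = ModelResultRow("concat", acc=94.35, recall=93.80, f1=94.14,
                                params_m=26.12)
        rep = efficiency_metrics(ours, reference=concat)
        assert rep.delta_acc_pp == 5.26
        assert rep.delta_params_pct == pytest.approx(50.5)

    def test_zero_params_rejected(self):
        with pytest.raises(ValueError):
            efficiency_metrics(ModelResultRow("x", 1, 1, 1, params_m=0.0))


class TestGateAnalysis:
    def test_perfect_inverse_linear_correlation(self):
        ph = np.linspace(6.0, 7.8, 30)
        records = pd.DataFrame({
            "g": 1.0 - (ph - 6.0) / 1.8, "ph": ph,
            "stage": ["early"] * 15 + ["late"] * 15})
        out = gate_analysis(records)
        assert out["pearson_r"] == pytest.approx(-1.0)
        assert not out["undefined_correlation"]

    def test_constant_gate_flags_undefined_correlation(self):
        records = pd.DataFrame({"g": [0.5] * 10,
                                "ph": np.linspace(6, 8, 10),
                                "stage": ["early"] * 10})
        out = gate_analysis(records)
        assert out["undefined_correlation"]
        assert np.isnan(out["pearson_r"])
        assert out["mean_g_by_stage"]["early"] == pytest.approx(0.5)

    def test_stage_bucket_means(self):
        records = pd.DataFrame({
            "g": [0.8] * 5 + [0.2] * 5,
            "ph": [6.1] * 5 + [7.6] * 5,
            "stage": ["early"] * 5 + ["late"] * 5})
        out = gate_analysis(records)
        assert out["mean_g_by_stage"] == {"early": 0.8, "late": 0.2}
        assert out["mean_g_low_ph"] == pytest.approx(0.8)
        assert out["mean_g_high_ph"] == pytest.approx(0.2)

    def test_stage_from_time_buckets(self):
        assert stage_from_time(0) == "early"
        assert stage_from_time(10) == "early"
        assert stage_from_time(15) == "mid"
        assert stage_from_time(25) == "late"

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            gate_analysis(pd.DataFrame({"g": [0.5], "ph": [6.5],
                                        "stage": ["early"]}))


class TestActivationMap:
    def test_bounds_and_size(self, rng):
        model = build_model("image_only", TINY_SIZE, seed=1)
        img = rng.random((32, 32, 3)).astype(np.float32)
        cam = activation_map(model, img, class_index=0)
        assert cam.shape == (32, 32)
        assert cam.min() >= 0.0 and cam.max() <= 1.0

    def test_zero_gradients_give_zero_map(self, rng):
        model = build_model("image_only", TINY_SIZE, seed=1)
        model.head.fc2.weight.data[:] = 0.0
        model.head.fc2.bias.data[:] = 0.0
        cam = activation_map(model, rng.random((32, 32, 3)), class_index=1)
        assert np.all(cam == 0.0)

    def test_class_index_out_of_range(self, rng):
        model = build_model("image_only", TINY_SIZE, seed=1)
        with pytest.raises(ValueError):
            activation_map(model, rng.random((32, 32, 3)), class_index=5)

    def test_chem_only_model_rejected(self, rng):
        model = build_model("chem_only", TINY_SIZE, seed=1)
        with pytest.raises(ValueError):
            activation_map(model, rng.random((32, 32, 3)), class_index=0)


class TestEvaluate:
    def test_metrics_and_gate_records(self, tiny_data):
        model = build_model("full", TINY_SIZE, seed=2)
        metrics, records = evaluate(model, tiny_data, split="val")
        assert metrics.confusion.sum() == len(records)
        assert set(records.columns) >= {"sample_id", "s", "g", "ph", "stage",
                                        "predicted", "true"}
        assert records["g"].between(0, 1).all()
        assert records["s"].between(-1, 1).all()

    def test_unknown_split_rejected(self, tiny_data):
        model = build_model("chem_only", TINY_SIZE, seed=2)
        with pytest.raises(ValueError):
            evaluate(model, tiny_data, split="test")
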