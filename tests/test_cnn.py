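import copy

import numpy as np
import pytest

from facequant import cnn, synthgen
from facequant.cnn import (
    BatchNorm2D,
    Conv2D,
    ExperimentConfig,
    Linear,
    Model,
    apply_freezing,
    build_model,
    evaluate,
    run_experiment_grid,
    softmax_xent,
    train,
)


@pytest.fixture(params=cnn.BACKBONES)
def backbone(request):
    return request.param


class TestBuild:
    def test_no_normalization_layers_when_bn_off(self, backbone):
        m = build_model(ExperimentConfig(backbone=backbone, batch_norm=False,
                                         input_size=32))
        assert not any(isinstance(l, BatchNorm2D) for l in m.param_layers())

    def test_bn_layers_present_when_on(self, backbone):
        m = build_model(ExperimentConfig(backbone=backbone, batch_norm=True,
                                         input_size=32))
        assert any(isinstance(l, BatchNorm2D) for l in m.param_layers())

    def test_same_config_same_seed_identical_weights(self, backbone):
        cfg = ExperimentConfig(backbone=backbone, seed=5, input_size=32)
        a, b = build_model(cfg), build_model(cfg)
        for la, lb in zip(a.param_layers(), b.param_layers()):
            for k in la.params:
                assert np.array_equal(la.params[k], lb.params[k])

    def test_pretrained_stub_loads_exact_weights(self, tmp_path):
        cfg = ExperimentConfig(backbone="small-vgg-like", seed=2, input_size=32)
        src = build_model(cfg)
        ckpt = tmp_path / "stub.npz"
        src.save(ckpt)
        cfg2 = ExperimentConfig(backbone="small-vgg-like", seed=99, input_size=32,
                                pretrained=True, checkpoint=str(ckpt))
        dst = build_model(cfg2)
        for la, lb in zip(src.param_layers(), dst.param_layers()):
            for k in la.params:
                assert np.array_equal(la.params[k], lb.params[k])

    def test_missing_stub_checkpoint_raises(self, tmp_path):
        cfg = ExperimentConfig(pretrained=True, checkpoint=str(tmp_path / "no.npz"),
                               input_size=32)
        with pytest.raises(FileNotFoundError):
            build_model(cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="learning_rate"):
            ExperimentConfig(learning_rate=0.0)
        with pytest.raises(ValueError, match="freezing"):
            ExperimentConfig(freezing="last-fc-only", pretrained=False)
        with pytest.raises(ValueError, match="checkpoint"):
            ExperimentConfig(pretrained=True, checkpoint=None)

    def test_weight_init_flag_changes_scheme(self):
        a = build_model(ExperimentConfig(seed=1, weight_init=False, input_size=32))
        b = build_model(ExperimentConfig(seed=1, weight_init=True, input_size=32))
        assert not np.array_equal(a.param_layers()[0].params["W"],
                                  b.param_layers()[0].params["W"])


class TestFreezing:
    def test_last_fc_only_trains_only_the_head(self):
        m = build_model(ExperimentConfig(input_size=32))
        apply_freezing(m, "last-fc-only")
        trainable = [l for l in m.param_layers() if l.trainable]
        assert len(trainable) == 1 and isinstance(trainable[0], Linear)

    def test_from_scratch_trains_everything(self):
        m = build_model(ExperimentConfig(input_size=32))
        apply_freezing(m, "from-scratch")
        assert all(l.trainable for l in m.param_layers())

    def test_last_five_layers_count(self):
        m = build_model(ExperimentConfig(input_size=32, batch_norm=True))
        apply_freezing(m, "last-five-layers")
        plist = m.param_layers()
        assert [l.trainable for l in plist] == \
            [i >= len(plist) - 5 for i in range(len(plist))]

    def test_frozen_tensors_unchanged_by_a_training_step(self, small_dataset):
        cfg = ExperimentConfig(input_size=64, epochs_max=1, batch_size=16, seed=0)
        m = build_model(cfg)
        apply_freezing(m, "last-fc-only")
        frozen_before = {
            l.name: {k: v.copy() for k, v in l.params.items()}
            for l in m.param_layers() if not l.trainable
        }
        head = m.param_layers()[-1]
        head_before = {k: v.copy() for k, v in head.params.items()}
        train(m, small_dataset.subset(range(32)), cfg)
        for l in m.param_layers():
            if l.trainable:
                continue
            for k in l.params:
                assert np.array_equal(l.params[k], frozen_before[l.name][k]), l.name
        assert any(not np.array_equal(head.params[k], head_before[k])
                   for k in head.params)


class TestTraining:
    def test_single_class_training_set_rejected(self, small_dataset):
        controls = [i for i, l in enumerate(small_dataset.labels) if l == "control"]
        cfg = ExperimentConfig(input_size=64, epochs_max=1)
        m = build_model(cfg)
        with pytest.raises(ValueError, match="both classes"):
            train(m, small_dataset.subset(controls), cfg)

    def test_loss_history_finite_across_grid_smoke(self, small_dataset):
        smoke = small_dataset.subset(range(0, 90, 2))
        for backbone in cnn.BACKBONES:
            for opt in ("SGD", "Adam"):
                cfg = ExperimentConfig(backbone=backbone, optimizer=opt,
                                       learning_rate=0.01, input_size=64,
                                       epochs_max=2, seed=3)
                m = build_model(cfg)
                hist = train(m, smoke, cfg)
                assert np.isfinite(hist["loss"]).all(), (backbone, opt)

    def test_planted_effect_learnable(self, trained_model):
        model, _, test_set, _ = trained_model
        cm = evaluate(model, test_set)
        assert (cm.TP + cm.TN) / cm.total >= 0.9

    def test_training_reproducible(self, small_dataset):
        tr = small_dataset.subset(range(0, 90, 3))
        cfg = ExperimentConfig(input_size=64, epochs_max=2, seed=8)
        models = []
        for _ in range(2):
            m = build_model(cfg)
            train(m, tr, cfg)
            models.append(m)
        for la, lb in zip(models[0].param_layers(), models[1].param_layers()):
            for k in la.params:
                assert np.array_equal(la.params[k], lb.params[k])


class TestEvaluate:
    def test_confusion_marginals_conserved(self, trained_model):
        model, _, test_set, _ = trained_model
        cm = evaluate(model, test_set)
        labels = test_set.label_array()
        assert cm.TP + cm.FN == int((labels == 1).sum())
        assert cm.FP + cm.TN == int((labels == 0).sum())
        assert cm.total == len(test_set)

    def test_constant_control_predictor_has_no_positives(self, small_dataset):
        cfg = ExperimentConfig(input_size=64)
        m = build_model(cfg)
        head = m.param_layers()[-1]
        head.params["W"][:] = 0.0
        head.params["b"][:] = (1.0, 0.0)  # logit for control always wins
        cm = evaluate(m, small_dataset)
        assert cm.TP == 0 and cm.FP == 0


class TestGrid:
    def test_single_config_single_row(self, small_dataset):
        tr, te = synthgen.split_dataset(small_dataset, 0.7, seed=0)
        cfg = ExperimentConfig(input_size=64, epochs_max=2, seed=1, name="only")
        report = run_experiment_grid([cfg], tr, te)
        assert len(report) == 1 and bool(report["best"].iloc[0])

    def test_duplicate_configs_give_identical_rows(self, small_dataset):
        tr, te = synthgen.split_dataset(small_dataset, 0.7, seed=0)
        cfg = ExperimentConfig(input_size=64, epochs_max=2, seed=1)
        report = run_experiment_grid([cfg, cfg], tr, te)
        a, b = report.drop(columns=["experiment", "best"]).iloc[0], \
            report.drop(columns=["experiment", "best"]).iloc[1]
        assert a.equals(b)
        assert list(report["best"]) == [True, False]  # tie goes to the first

    def test_bn_on_off_rows_have_valid_accuracies(self, small_dataset):
        tr, te = synthgen.split_dataset(small_dataset, 0.7, seed=0)
        grid = [ExperimentConfig(input_size=64, epochs_max=2, seed=1, batch_norm=bn)
                for bn in (True, False)]
        report = run_experiment_grid(grid, tr, te)
        assert list(report["batch_norm"]) == [True, False]
        assert ((report["ACC"] >= 0) & (report["ACC"] <= 100)).all()


def test_softmax_xent_gradient_matches_finite_differences():
    rng = np.random.default_rng(0)
    logits = rng.normal(size=(4, 2))
    y = np.array([0, 1, 1, 0])
    loss, grad = softmax_xent(logits, y)
    eps = 1e-6
    for i in range(4):
        for j in range(2):
            lp = logits.copy()
            lp[i, j] += eps
            num = (softmax_xent(lp, y)[0] - loss) / eps
            assert num == pytest.approx(grad[i, j], abs=1e-4)
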