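"""Model construction, training recipe contracts, metrics, ablation runner."""

import numpy as np
import pytest

from lungsurv.fixtures import separable_stack_dataset
from lungsurv.losses import LossParams, pen_bce
from lungsurv.train_eval import (
    TrainConfig,
    accuracy,
    augment_batch,
    build_model,
    evaluate,
    imbalanced_logistic_fp_experiment,
    roc_auc,
    run_ablation,
    stratified_split,
    train,
    train_single,
)


class TestBuildModel:
    def test_sigmoid_head_output_in_unit_interval(self):
        model = build_model("tiny3d", (16, 16, 5), seed=0)
        x = np.random.default_rng(0).uniform(0, 1, (4, 1, 5, 16, 16))
        p = model.forward(x, train=True)
        assert p.shape == (4,)
        assert ((p > 0) & (p < 1)).all()

    def test_same_seed_identical_initial_weights(self):
        m1 = build_model("tiny3d", (16, 16, 5), seed=3)
        m2 = build_model("tiny3d", (16, 16, 5), seed=3)
        for a, b in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(a.value, b.value)
        m3 = build_model("tiny3d", (16, 16, 5), seed=4)
        assert any(not np.array_equal(a.value, b.value)
                   for a, b in zip(m1.parameters(), m3.parameters()))

    def test_resnet34_3d_constructs_and_forwards(self):
        model = build_model("resnet34_3d", (64, 64, 5), seed=0)
        # 34-layer basic-block budget: (3+4+6+3) blocks of 2 convs + stem + fc
        assert model.n_parameters() > 30_000_000
        x = np.random.default_rng(1).uniform(0, 1, (2, 1, 5, 64, 64))
        p = model.forward(x, train=True)
        assert p.shape == (2,)
        assert ((p >= 0) & (p <= 1)).all()

    def test_incompatible_input_size_guidance(self):
        with pytest.raises(ValueError, match="divisible"):
            build_model("resnet34_3d", (50, 50, 5), seed=0)

    def test_unknown_arch(self):
        with pytest.raises(ValueError):
            build_model("vgg", (16, 16, 5))


class TestStratifiedSplit:
    def test_proportions_within_one_patient(self):
        rng = np.random.default_rng(0)
        y = (rng.uniform(size=373) < 0.327).astype(int)
        tr, te = stratified_split(y, test_frac=0.15, seed=0)
        overall = y.mean()
        train_frac = y[tr].mean()
        assert abs(train_frac - overall) <= 1.0 / len(tr) + 1e-12

    def test_deterministic_and_partition(self):
        y = np.array([0] * 30 + [1] * 15)
        tr1, te1 = stratified_split(y, seed=7)
        tr2, te2 = stratified_split(y, seed=7)
        np.testing.assert_array_equal(tr1, tr2)
        np.testing.assert_array_equal(te1, te2)
        assert set(tr1) | set(te1) == set(range(45))
        assert set(tr1) & set(te1) == set()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.ones(20))


class TestMetrics:
    def test_perfect_separation(self):
        assert accuracy([0.1, 0.9], [0, 1]) == 1.0
        assert roc_auc([0.1, 0.9], [0, 1]) == 1.0

    def test_constant_scores_auc_half(self):
        assert roc_auc([0.5] * 10, [0, 1] * 5) == 0.5

    def test_single_class_auc_missing(self):
        assert roc_auc([0.2, 0.8], [1, 1]) is None

    def test_auc_equals_brute_force_pairwise(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(10, 200))
            p = np.round(rng.uniform(size=n), 2)  # rounding forces ties
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            pos, neg = p[y == 1], p[y == 0]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            brute = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert roc_auc(p, y) == pytest.approx(brute, abs=1e-12)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(0)
        aucs = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            p = r.uniform(size=1000)
            y = r.integers(0, 2, 1000)
            aucs.append(roc_auc(p, y))
        assert abs(np.mean(aucs) - 0.5) < 0.05


@pytest.fixture(scope="module")
def separable():
    x, y = separable_stack_dataset(n=80, size=32, seed=0)
    tr, te = stratified_split(y, test_frac=0.25, seed=0)
    return x, y, tr, te


class TestTraining:
    def test_separable_task_learns(self, separable):
        x, y, tr, te = separable
        cfg = TrainConfig(lr=0.05, epochs=20, folds=1, seed=0)
        model = build_model("tiny3d", x.shape[1:], seed=0)
        fitted, hist = train(model, x[tr], y[tr], cfg)
        assert hist["train_loss"][-1] <= 0.5 * hist["train_loss"][0]
        res = evaluate(fitted, x[te], y[te], cfg)
        assert res.auc > 0.9

    def test_pen_bce_zero_alpha_beta_matches_bce_bitwise(self):
        x, y = separable_stack_dataset(n=24, size=16, seed=1)
        histories, weights = [], []
        for loss, params in (("bce", None), ("pen_bce", LossParams(0, 0, 0.5, 0.2))):
            kw = dict(lr=0.05, epochs=4, folds=1, seed=5, loss=loss)
            if params is not None:
                kw["loss_params"] = params
            model = build_model("tiny3d", x.shape[1:], seed=5)
            _, hist = train(model, x, y, TrainConfig(**kw))
            histories.append(hist)
            weights.append([p.value.copy() for p in model.parameters()])
        assert histories[0]["train_loss"] == histories[1]["train_loss"]
        assert histories[0]["val_loss"] == histories[1]["val_loss"]
        for a, b in zip(*weights):
            np.testing.assert_array_equal(a, b)

    def test_lr_reduced_after_forced_plateau(self):
        x, y = separable_stack_dataset(n=20, size=8, seed=2)
        cfg = TrainConfig(lr=1e-12, epochs=28, folds=1, seed=0,
                          plateau_patience=25, early_stopping_patience=100)
        model = build_model("tiny3d", x.shape[1:], seed=0)
        _, hist = train(model, x, y, cfg)
        # a vanishing lr cannot improve validation loss: plateau at 25 epochs
        assert hist["lr"][25] == pytest.approx(1e-12)
        assert hist["lr"][26] == pytest.approx(0.9e-12)

    def test_early_stopping_restores_best_weights(self):
        x, y = separable_stack_dataset(n=24, size=8, seed=3)
        cfg = TrainConfig(lr=0.5, epochs=60, folds=1, seed=1,
                          early_stopping_patience=5, plateau_patience=3)
        model = build_model("tiny3d", x.shape[1:], seed=1)
        fitted, hist = train(model, x, y, cfg)
        assert len(hist["val_loss"]) <= 60

    def test_criterion_in_training_equals_pure_function(self):
        x, y = separable_stack_dataset(n=16, size=8, seed=4)
        params = LossParams(1, 5, 0.5, 0.2)
        captured = []
        cfg = TrainConfig(lr=0.05, epochs=1, folds=1, seed=0, loss="pen_bce",
                          loss_params=params)
        model = build_model("tiny3d", x.shape[1:], seed=0)
        train(model, x, y, cfg,
              batch_hook=lambda p, yy, lo: captured.append((p, yy, lo)))
        assert captured
        for p, yy, lo in captured:
            assert lo == pen_bce(p, yy, params)

    def test_five_fold_cv_returns_per_fold_metrics(self):
        x, y = separable_stack_dataset(n=50, size=8, seed=5)
        cfg = TrainConfig(lr=0.05, epochs=3, folds=5, seed=0)
        model = build_model("tiny3d", x.shape[1:], seed=0)
        fitted, hist = train(model, x, y, cfg)
        assert len(hist["folds"]) == 5
        res = evaluate(fitted, x, y, cfg)
        assert len(res.per_fold) == 5
        assert res.acc == pytest.approx(np.mean([f["acc"] for f in res.per_fold]))

    def test_nan_loss_aborts_with_diagnostics(self, monkeypatch):
        x, y = separable_stack_dataset(n=16, size=8, seed=6)
        cfg = TrainConfig(lr=0.05, epochs=10, folds=1, seed=0)
        model = build_model("tiny3d", x.shape[1:], seed=0)
        monkeypatch.setattr(
            model, "forward",
            lambda xb, train=False: np.full(len(xb), np.nan))
        with pytest.raises(RuntimeError, match="non-finite"):
            train(model, x, y, cfg)


class TestAugmentation:
    def test_augmented_copies_differ_but_stay_valid(self):
        x, _ = separable_stack_dataset(n=6, size=16, seed=0)
        xb = x.transpose(0, 3, 1, 2)[:, None]
        rng = np.random.default_rng(0)
        aug = augment_batch(xb, rng)
        assert aug.shape == xb.shape
        assert aug.min() >= 0 and aug.max() <= 1
        assert not np.allclose(aug, xb)

    def test_augmentation_changes_training_stream(self):
        x, y = separable_stack_dataset(n=16, size=8, seed=7)
        seen = {True: [], False: []}
        for flag in (False, True):
            cfg = TrainConfig(lr=0.05, epochs=1, folds=1, seed=0, augmentation=flag)
            model = build_model("tiny3d", x.shape[1:], seed=0)
            train(model, x, y, cfg,
                  batch_hook=lambda p, yy, lo: seen[flag].append(lo))
        assert seen[True] != seen[False]


class TestAblation:
    def test_bce_and_zeroed_pen_bce_rows_identical(self):
        x, y = separable_stack_dataset(n=30, size=8, seed=8)
        half = 20

        def provider(cell):
            return x[:half], y[:half], x[half:], y[half:]

        cells = [
            {"name": "bce", "loss": "bce"},
            {"name": "pen0", "loss": "pen_bce", "loss_params": LossParams(0, 0, 0.5, 0.2)},
        ]
        base = TrainConfig(lr=0.05, epochs=3, folds=1, seed=0)
        report = run_ablation(cells, provider, base)
        assert len(report) == 2
        assert report.loc[0, "test_loss"] == report.loc[1, "test_loss"]
        assert report.loc[0, "acc"] == report.loc[1, "acc"]
        assert report.loc[0, "auc"] == report.loc[1, "auc"]


class TestBehavioralLossProperty:
    def test_pen_bce_reduces_false_positives_on_imbalanced_task(self):
        result = imbalanced_logistic_fp_experiment(range(10))
        assert result["mean_fp_pen_bce"] < result["mean_fp_bce"]
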