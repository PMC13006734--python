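"""Tests for the CNN-Transformer decoder, folds, distillation, and LoRA."""

import numpy as np
import pytest
from sklearn.base import clone

from strainspeech import decoder, synthfab
from strainspeech.decoder import (
    ArrayDataset,
    ClassifierConfig,
    DistillConfig,
    LoRAConfig,
    SequenceClassifier,
    TrainConfig,
    build_classifier,
    evaluate,
    load_model,
    make_folds,
    export_model,
)


TINY = ClassifierConfig(
    in_channels=3, n_classes=4, seq_len=200,
    conv_blocks=((8, 5, 4), (16, 5, 4)), n_layers=1, n_heads=2, d_ff=16,
    n_residual_features=8, fusion_width=8, head_hidden=16, dropout=0.0,
)


def _tiny_data(n_per_class=6, seed=0, n_classes=4, C=3):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, 200)
    X, R, y = [], [], []
    for k in range(n_classes):
        base = np.stack([np.sin(2 * np.pi * (k + 1) * t + c) for c in range(C)], axis=1)
        for _ in range(n_per_class):
            X.append(base + rng.normal(0, 0.05, base.shape))
            R.append(rng.uniform(0, 1, 8))
            y.append(k)
    X, R, y = np.stack(X), np.stack(R), np.array(y)
    return ArrayDataset(X, R, y, np.zeros(len(y), dtype=int))


class TestForward:
    def test_probability_simplex(self):
        model = build_classifier(ClassifierConfig(in_channels=8), seed=0)
        proba = model.predict_proba(np.zeros((2, 200, 8)), np.zeros((2, 16)))
        assert proba.shape == (2, 26)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(proba >= 0)

    def test_head_permutation_permutes_probabilities(self):
        model = build_classifier(TINY, seed=1)
        rng = np.random.default_rng(0)
        X, R = rng.normal(size=(3, 200, 3)), rng.normal(size=(3, 8)) ** 2
        p0 = model.predict_proba(X, R)
        perm = np.array([2, 0, 3, 1])
        model.fc2.W.data = model.fc2.W.data[:, perm]
        model.fc2.b.data = model.fc2.b.data[perm]
        p1 = model.predict_proba(X, R)
        assert np.allclose(p1, p0[:, perm], atol=1e-12)

    def test_parameter_count_matches_analytic_formula(self):
        cfg = ClassifierConfig(in_channels=8)
        model = build_classifier(cfg, seed=0)
        expected = 0
        c_in, T = cfg.in_channels, cfg.seq_len
        for f, k, s in cfg.conv_blocks:
            expected += (k * c_in) * f + f
            T = (T - k) // s + 1
            c_in = f
        d = cfg.d_model
        expected += T * d  # positional embedding
        per_layer = 4 * (d * d + d)  # q, k, v, o
        per_layer += 2 * (2 * d)  # two layer norms
        per_layer += d * cfg.d_ff + cfg.d_ff + cfg.d_ff * d + d  # feed-forward
        expected += cfg.n_layers * per_layer
        expected += cfg.n_residual_features * cfg.fusion_width + cfg.fusion_width
        head_in = d + cfg.fusion_width
        expected += head_in * cfg.head_hidden + cfg.head_hidden
        expected += cfg.head_hidden * cfg.n_classes + cfg.n_classes
        assert model.n_parameters() == expected

    def test_channel_mismatch_raises(self):
        model = build_classifier(TINY, seed=0)
        with pytest.raises(ValueError, match="channel mismatch"):
            model.logits(np.zeros((1, 200, 5)), np.zeros((1, 8)))

    def test_indivisible_heads_raise(self):
        with pytest.raises(ValueError, match="divisible"):
            ClassifierConfig(conv_blocks=((30, 5, 2),), n_heads=4)


class TestFolds:
    def test_balanced_design_exact_shares(self):
        # 26 classes x 50 samples over 5 subjects -> 10 per class per fold
        n_classes, per_class, n_subj = 26, 50, 5
        labels = np.repeat(np.arange(n_classes), per_class)
        subjects = np.tile(np.arange(n_subj).repeat(per_class // n_subj), n_classes)
        plan = make_folds(labels, subjects, k=5, seed=0)
        for f in range(5):
            test_labels = labels[plan.test_indices(f)]
            assert np.all(np.bincount(test_labels, minlength=n_classes) == 10)

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 6, size=200)
        subjects = rng.integers(0, 8, size=200)
        plan = make_folds(labels, subjects, k=5, seed=3)
        all_test = np.concatenate([plan.test_indices(f) for f in range(5)])
        assert sorted(all_test) == list(range(200))

    def test_subject_disjointness(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 4, size=300)
        subjects = rng.integers(0, 9, size=300)
        plan = make_folds(labels, subjects, k=5, seed=1)
        for f in range(5):
            tr = set(subjects[plan.train_indices(f)])
            te = set(subjects[plan.test_indices(f)])
            assert not (tr & te)

    def test_too_few_subjects_raises(self):
        with pytest.raises(ValueError, match="subject"):
            make_folds(np.zeros(30, dtype=int), np.repeat([0, 1, 2], 10), k=5)


class TestTraining:
    def test_single_sample_memorization(self):
        data = _tiny_data(n_per_class=1, n_classes=4)
        model = build_classifier(TINY, seed=0)
        cfg = TrainConfig(max_epochs=60, patience=60, batch_train=4, lr=5e-3, seed=0)
        decoder.train(model, data, data, cfg)
        acc, _ = evaluate(model, data)
        assert acc == 1.0

    def test_early_stop_history_contract(self):
        data = _tiny_data(n_per_class=4)
        model = build_classifier(TINY, seed=0)
        cfg = TrainConfig(max_epochs=200, patience=3, batch_train=16, lr=5e-3, seed=0)
        hist = decoder.train(model, data, _tiny_data(n_per_class=2, seed=5), cfg)
        n_epochs = len(hist["val_loss"])
        assert n_epochs <= hist["best_epoch"] + cfg.patience + 1

    def test_training_is_seeded_and_reproducible(self):
        data = _tiny_data(n_per_class=3)
        val = _tiny_data(n_per_class=2, seed=9)
        runs = []
        for _ in range(2):
            model = build_classifier(TINY, seed=4)
            decoder.train(model, data, val, TrainConfig(max_epochs=3, patience=3, batch_train=8, seed=4))
            runs.append(model.state_dict())
        for key in runs[0]:
            assert np.array_equal(runs[0][key], runs[1][key])

    def test_nan_loss_aborts(self):
        data = _tiny_data(n_per_class=2)
        model = build_classifier(TINY, seed=0)
        model.fc2.W.data[:] = 1e308  # force divergent logits
        model.fc2.W.data[:, 0] = -1e308
        with pytest.raises(RuntimeError, match="NaN"):
            decoder.train(model, data, data, TrainConfig(max_epochs=2, seed=0))


class TestEvaluate:
    def test_constant_predictor_on_balanced_data(self):
        model = build_classifier(TINY, seed=0)
        # zero head -> uniform logits -> argmax = class 0 always
        model.fc2.W.data[:] = 0.0
        model.fc2.b.data[:] = 0.0
        data = _tiny_data(n_per_class=8)
        acc, cm = evaluate(model, data)
        assert np.isclose(acc, 1.0 / 4)
        assert cm.sum() == len(data)
        assert np.all(cm[:, 0] == 8)

    def test_confusion_matrix_conserves_counts(self, trained_teacher, word_splits):
        acc, cm = evaluate(trained_teacher["model"], word_splits["test"])
        assert cm.sum() == len(word_splits["test"])
        assert np.isclose(np.trace(cm) / cm.sum(), acc)

    def test_label_outside_model_space_raises(self):
        model = build_classifier(TINY, seed=0)
        data = _tiny_data(n_per_class=1)
        data.y[0] = 99
        with pytest.raises(ValueError, match="class space"):
            evaluate(model, data)


class TestDistillation:
    def test_lambda_zero_equals_plain_training(self):
        data = _tiny_data(n_per_class=3)
        val = _tiny_data(n_per_class=2, seed=8)
        teacher = build_classifier(TINY, seed=0)
        decoder.train(teacher, data, val, TrainConfig(max_epochs=2, batch_train=8, seed=0))
        scfg = ClassifierConfig(
            in_channels=3, n_classes=4, conv_blocks=((4, 5, 4), (8, 5, 4)),
            n_layers=1, n_heads=2, d_ff=8, n_residual_features=8, fusion_width=4,
            head_hidden=8, dropout=0.0,
        )
        tcfg = TrainConfig(max_epochs=3, batch_train=8, seed=2)
        student_a, _ = decoder.distill(
            teacher, DistillConfig(soft_weight=0.0, student=scfg), data, val, tcfg
        )
        student_b = decoder.StrainWordNet(student_a.cfg, seed=tcfg.seed)
        decoder._fit(student_b, data, val, tcfg)
        sa, sb = student_a.state_dict(), student_b.state_dict()
        for key in sa:
            assert np.array_equal(sa[key], sb[key])

    def test_student_smaller_than_teacher(self, trained_teacher, distilled_student):
        assert distilled_student["model"].n_parameters() < trained_teacher["model"].n_parameters()

    def test_student_tracks_teacher_accuracy(self, trained_teacher, distilled_student):
        assert distilled_student["accuracy"] >= trained_teacher["accuracy"] - 0.05

    def test_invalid_soft_weight_raises(self):
        with pytest.raises(ValueError):
            DistillConfig(soft_weight=1.5)


class TestLoRA:
    def test_identity_at_initialization(self):
        model = build_classifier(TINY, seed=3)
        rng = np.random.default_rng(0)
        X, R = rng.normal(size=(4, 200, 3)), rng.uniform(0, 1, (4, 8))
        before = model.predict_proba(X, R)
        model.attach_lora(LoRAConfig(rank=4), seed=1)
        after = model.predict_proba(X, R)
        assert np.array_equal(before, after)

    def test_trainable_fraction_formula(self):
        model = build_classifier(TINY, seed=0)
        base = model.n_parameters()
        cfg = LoRAConfig(rank=4)
        data = _tiny_data(n_per_class=4)
        model, report = decoder.lora_adapt(
            model, data, cfg, TrainConfig(max_epochs=1, batch_train=8, seed=0)
        )
        d = model.cfg.d_model
        n_proj = 2 * model.cfg.n_layers  # q and v per layer
        lora_params = cfg.rank * (d + d) * n_proj
        assert report["trainable_parameters"] == lora_params
        assert np.isclose(report["trainable_fraction"], lora_params / (base + lora_params))

    def test_base_weights_bit_identical(self):
        model = build_classifier(TINY, seed=5)
        snapshot = {n: p.data.copy() for n, p in model.named_parameters()}
        data = _tiny_data(n_per_class=5)
        model, report = decoder.lora_adapt(
            model, data, LoRAConfig(rank=2), TrainConfig(max_epochs=3, batch_train=8, seed=0)
        )
        for name, p in model.named_parameters():
            if ".lora_" in name:
                continue
            assert np.array_equal(p.data, snapshot[name]), name

    def test_adapts_fraction_below_ten_percent(self, trained_teacher, word_splits):
        import copy

        model = copy.deepcopy(trained_teacher["model"])
        user = word_splits["all"].subset(word_splits["all"].subjects == 2)
        model, report = decoder.lora_adapt(
            model, user, LoRAConfig(), TrainConfig(max_epochs=5, patience=2, batch_train=64, seed=0)
        )
        assert report["trainable_fraction"] < 0.10
        assert report["accuracy_after"] >= 0.0  # report well-formed

    def test_no_transformer_layer_raises(self):
        cfg = ClassifierConfig(
            in_channels=3, n_classes=4, conv_blocks=((8, 5, 4), (16, 5, 4)),
            n_layers=0, n_heads=2, d_ff=8, n_residual_features=8, fusion_width=4, head_hidden=8,
        )
        model = build_classifier(cfg, seed=0)
        with pytest.raises(ValueError, match="adapt"):
            model.attach_lora(LoRAConfig())


class TestExport:
    def test_roundtrip_reproduces_outputs(self, tmp_path):
        model = build_classifier(TINY, seed=7)
        rng = np.random.default_rng(1)
        X, R = rng.normal(size=(3, 200, 3)), rng.uniform(0, 1, (3, 8))
        p0 = model.predict_proba(X, R)
        export_model(model, tmp_path / "m.npz")
        p1 = load_model(tmp_path / "m.npz").predict_proba(X, R)
        assert np.abs(p0 - p1).max() < 1e-5

    def test_student_export_smaller(self, tmp_path, trained_teacher, distilled_student):
        tp = export_model(trained_teacher["model"], tmp_path / "teacher.npz")
        sp = export_model(distilled_student["model"], tmp_path / "student.npz")
        assert sp.stat().st_size < tp.stat().st_size

    def test_structure_metadata_independent_of_training(self, tmp_path):
        import json
        import numpy as np

        a = build_classifier(TINY, seed=0)
        b = build_classifier(TINY, seed=9)  # different weights, same structure
        export_model(a, tmp_path / "a.npz")
        export_model(b, tmp_path / "b.npz")
        metas = []
        for name in ("a.npz", "b.npz"):
            with np.load(tmp_path / name) as z:
                metas.append(json.loads(bytes(z["__meta__"]).decode()))
        assert metas[0] == metas[1]

    def test_lora_checkpoint_roundtrip(self, tmp_path):
        model = build_classifier(TINY, seed=2)
        model.attach_lora(LoRAConfig(rank=2), seed=0)
        model.blocks[0].attn.lora_q.B.data[:] = 0.3  # make adaptation visible
        rng = np.random.default_rng(2)
        X, R = rng.normal(size=(2, 200, 3)), rng.uniform(0, 1, (2, 8))
        p0 = model.predict_proba(X, R)
        export_model(model, tmp_path / "l.npz")
        p1 = load_model(tmp_path / "l.npz").predict_proba(X, R)
        assert np.abs(p0 - p1).max() < 1e-12


class TestRobustnessProperties:
    def test_accuracy_degrades_with_noise(self, trained_teacher, word_arrays):
        """A model trained at low noise loses accuracy monotonically (on
        average) as the test-time channel noise grows."""
        _, stats = word_arrays
        accs = []
        for noise in (0.02, 0.6, 2.0):
            cfg = synthfab.SequenceGenConfig(
                n_classes=26, samples_per_class=4, n_subjects=5,
                template_noise_sd=0.02, channel_noise_sd=noise, seed=7,
            )
            ds = synthfab.generate_word_dataset(cfg)
            arr, _ = decoder.preprocess_dataset(ds, stats=stats)
            acc, _ = evaluate(trained_teacher["model"], arr)
            accs.append(acc)
        assert accs[0] >= accs[1] >= accs[2] - 0.02

    def test_residual_fusion_helps_on_held_out_state(self):
        """With class patterns shifted per attachment state, fusing the
        residual map should not hurt held-out-state accuracy."""
        cfg = synthfab.SequenceGenConfig(
            n_classes=6, samples_per_class=18, n_subjects=3, attachment_states=3,
            template_noise_sd=0.02, channel_noise_sd=0.05, state_offset_sd=0.8, seed=21,
        )
        ds = synthfab.generate_word_dataset(cfg)
        arr, _ = decoder.preprocess_dataset(ds)
        states = ds.states  # preprocessing preserves sample order here
        train_idx = np.flatnonzero(states != 2)
        hold_idx = np.flatnonzero(states == 2)
        tr, hold = arr.subset(train_idx), arr.subset(hold_idx)
        accs = {}
        for fusion in (True, False):
            mcfg = ClassifierConfig(
                in_channels=8, n_classes=6, conv_blocks=((16, 5, 2), (32, 5, 2)),
                n_layers=1, n_heads=2, d_ff=32, fusion_width=16, head_hidden=32,
                use_residual_fusion=fusion,
            )
            model = build_classifier(mcfg, seed=0)
            decoder.train(model, tr, hold, TrainConfig(max_epochs=15, patience=15, batch_train=64, lr=2e-3, seed=0))
            accs[fusion], _ = evaluate(model, hold)
        assert accs[True] >= accs[False] - 0.02


class TestSequenceClassifierEstimator:
    def test_sklearn_params_and_clone(self):
        est = SequenceClassifier(n_layers=1, max_epochs=2)
        params = est.get_params()
        assert params["n_layers"] == 1
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_fit_predict_on_tiny_problem(self):
        data = _tiny_data(n_per_class=8)
        est = SequenceClassifier(
            conv_blocks=((8, 5, 4), (16, 5, 4)), n_layers=1, n_heads=2, d_ff=16,
            fusion_width=8, head_hidden=16, dropout=0.0, lr=5e-3, batch_size=16,
            max_epochs=25, patience=25, random_state=0,
        )
        est.fit(data.X, data.y, residual=data.residual)
        assert est.score(data.X, data.y, residual=data.residual) >= 0.9
        proba = est.predict_proba(data.X[:3], residual=data.residual[:3])
        assert np.allclose(proba.sum(axis=1), 1.0)
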