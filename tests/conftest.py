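"""Shared fixtures: synthetic frames, datasets, and trained models.

Expensive artifacts (the trained teacher, the distilled student) are
session-scoped so the decoder unit tests and the acceptance suite share one
training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from strainspeech import decoder, synthfab


@pytest.fixture(scope="session")
def substrate() -> synthfab.SubstrateSpec:
    return synthfab.SubstrateSpec()


@pytest.fixture(scope="session")
def grid5x5() -> synthfab.SubstrateSpec:
    return synthfab.SubstrateSpec(rows=5, cols=5)


@pytest.fixture(scope="session")
def identity_frame(substrate):
    return synthfab.render_marker_image(substrate, synthfab.DeformationField.identity())


@pytest.fixture(scope="session")
def word_dataset():
    """Low-noise, well-separated 26-class dataset (the learnable benchmark)."""
    cfg = synthfab.SequenceGenConfig(
        n_classes=26,
        samples_per_class=10,
        n_subjects=5,
        template_noise_sd=0.02,
        channel_noise_sd=0.02,
        seed=7,
    )
    return synthfab.generate_word_dataset(cfg)


@pytest.fixture(scope="session")
def word_arrays(word_dataset):
    arr, stats = decoder.preprocess_dataset(word_dataset)
    return arr, stats


@pytest.fixture(scope="session")
def word_splits(word_arrays):
    arr, _ = word_arrays
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(arr))
    return {
        "test": arr.subset(perm[:52]),
        "val": arr.subset(perm[52:78]),
        "train": arr.subset(perm[78:]),
        "all": arr,
    }


@pytest.fixture(scope="session")
def teacher_config():
    return decoder.ClassifierConfig(in_channels=8)


@pytest.fixture(scope="session")
def trained_teacher(word_splits, teacher_config):
    model = decoder.build_classifier(teacher_config, seed=0)
    cfg = decoder.TrainConfig(max_epochs=30, patience=6, batch_train=64, lr=2e-3, seed=0)
    history = decoder.train(model, word_splits["train"], word_splits["val"], cfg)
    acc, cm = decoder.evaluate(model, word_splits["test"])
    return {"model": model, "history": history, "accuracy": acc, "confusion": cm}


@pytest.fixture(scope="session")
def distilled_student(trained_teacher, word_splits):
    cfg = decoder.DistillConfig()
    tcfg = decoder.TrainConfig(max_epochs=25, patience=6, batch_train=64, lr=2e-3, seed=0)
    student, history = decoder.distill(trained_teacher["model"], cfg, word_splits["train"], word_splits["val"], tcfg)
    acc, _ = decoder.evaluate(student, word_splits["test"])
    return {"model": student, "history": history, "accuracy": acc}
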