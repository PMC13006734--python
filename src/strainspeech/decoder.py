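"""The word decoder: a hybrid CNN-Transformer classifier with residual-map
fusion, subject-independent cross-validation, knowledge distillation, and
low-rank user adaptation.

The network maps a fixed-length (200-step) multichannel strain sequence plus
a fixed-length residual-deviation feature vector to a probability vector over
the 26 spelling-alphabet word classes.  Strided convolutions extract local
deformation cues and downsample time; transformer encoder layers reweight the
resulting tokens with self-attention; residual-map features join at the fully
connected stage.  Training minimizes cross-entropy with Adam, with early
stopping and best-validation checkpointing.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix as _sk_confusion

from . import signals
from .autodiff import Tensor, concat
from .nn import (
    Adam,
    Conv1d,
    Dropout,
    Linear,
    Module,
    Parameter,
    TransformerEncoderLayer,
)
from .synthfab import LabeledDataset

__all__ = [
    "ClassifierConfig",
    "TrainConfig",
    "DistillConfig",
    "LoRAConfig",
    "FoldPlan",
    "ArrayDataset",
    "StrainWordNet",
    "build_classifier",
    "preprocess_dataset",
    "make_folds",
    "train",
    "evaluate",
    "distill",
    "lora_adapt",
    "export_model",
    "load_model",
    "SequenceClassifier",
]


# ---------------------------------------------------------------------------
# Configs


@dataclass
class ClassifierConfig:
    """Architecture of the word classifier.

    ``conv_blocks`` lists (filters, kernel, stride) per block; the last
    block's filter count is the transformer model width and must be divisible
    by ``n_heads``.  ``fusion_width`` sizes the residual-map branch appended
    at the fully connected stage.
    """

    in_channels: int = 8
    n_classes: int = 26
    seq_len: int = 200
    conv_blocks: tuple[tuple[int, int, int], ...] = ((32, 5, 2), (64, 5, 2))
    n_layers: int = 2
    n_heads: int = 4
    d_ff: int = 128
    n_residual_features: int = 16
    fusion_width: int = 32
    head_hidden: int = 64
    dropout: float = 0.1
    use_residual_fusion: bool = True

    @property
    def d_model(self) -> int:
        return self.conv_blocks[-1][0]

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.d_model % self.n_heads != 0:
            raise ValueError("model width must be divisible by head count")


@dataclass
class TrainConfig:
    lr: float = 1e-3
    batch_train: int = 256
    batch_eval: int = 1
    max_epochs: int = 60
    patience: int = 8
    seed: int = 0
    checkpoint_path: str | None = None

    def __post_init__(self) -> None:
        if self.patience < 1 or self.batch_train < 1 or self.batch_eval < 1:
            raise ValueError("patience and batch sizes must be >= 1")


@dataclass
class DistillConfig:
    """Teacher-student knowledge distillation settings."""

    temperature: float = 4.0
    soft_weight: float = 0.5  # lambda: weight of the soft (teacher) loss
    student: ClassifierConfig = dc_field(
        default_factory=lambda: ClassifierConfig(
            conv_blocks=((16, 5, 2), (32, 5, 2)), n_layers=1, n_heads=2, d_ff=64,
            fusion_width=16, head_hidden=32,
        )
    )

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not 0.0 <= self.soft_weight <= 1.0:
            raise ValueError("soft-loss weight must lie in [0, 1]")


@dataclass
class LoRAConfig:
    rank: int = 8
    alpha: float = 16.0
    targets: tuple[str, ...] = ("q", "v")
    adapt_head: bool = False

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")


# ---------------------------------------------------------------------------
# Data containers


@dataclass
class ArrayDataset:
    """Fixed-length tensors ready for the network."""

    X: np.ndarray  # (N, seq_len, C)
    residual: np.ndarray  # (N, F)
    y: np.ndarray  # (N,)
    subjects: np.ndarray  # (N,)

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx) -> "ArrayDataset":
        return ArrayDataset(self.X[idx], self.residual[idx], self.y[idx], self.subjects[idx])


def _resample_sorted(values: np.ndarray, length: int) -> np.ndarray:
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        return np.zeros(length)
    if v.size == 1:
        return np.full(length, v[0])
    return np.interp(np.linspace(0, 1, length), np.linspace(0, 1, v.size), v)


def preprocess_dataset(
    ds: LabeledDataset,
    stats: signals.NormStats | None = None,
    augment: bool = False,
    rng: np.random.Generator | None = None,
    n_residual: int = 16,
) -> tuple[ArrayDataset, signals.NormStats]:
    """Condition a raw labeled dataset into fixed-length model inputs.

    Per sample: moving-average smoothing, center padding to 220 steps, then
    either the stochastic training augmentation chain (time warp -> random
    200-step crop -> amplitude scale) or, for evaluation, the deterministic
    center 200-step window.  Normalization statistics are fitted on the given
    corpus when ``stats`` is None (training corpus) and applied afterwards.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    padded = []
    for s in ds.samples:
        x = signals.smooth(s.values, window=5)
        if not signals.validate_length(x):
            continue
        padded.append((signals.center_pad(x, signals.PAD_TARGET), s))
    if stats is None:
        stats = signals.fit_norm([p for p, _ in padded])
    X, R, y, subj = [], [], [], []
    lead = (signals.PAD_TARGET - signals.CROP_LENGTH) // 2
    for p, s in padded:
        p = signals.apply_norm(p, stats)
        if augment:
            p = signals.augment_time_warp(p, rng=rng)
            p = signals.augment_crop(p, rng=rng)
            p = signals.augment_scale(p, rng=rng)
        else:
            p = p[lead : lead + signals.CROP_LENGTH]
        X.append(p)
        R.append(_resample_sorted(s.residual_map, n_residual))
        y.append(s.label)
        subj.append(s.subject)
    return (
        ArrayDataset(np.stack(X), np.stack(R), np.array(y, dtype=int), np.array(subj, dtype=int)),
        stats,
    )


# ---------------------------------------------------------------------------
# Model


class StrainWordNet(Module):
    """Hybrid CNN-Transformer word classifier with residual-map fusion."""

    def __init__(self, cfg: ClassifierConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.convs: list[Conv1d] = []
        c_in = cfg.in_channels
        T = cfg.seq_len
        for filters, kernel, stride in cfg.conv_blocks:
            conv = Conv1d(c_in, filters, kernel, stride, rng)
            self.convs.append(conv)
            T = conv.out_len(T)
            c_in = filters
        if T < 1:
            raise ValueError("conv stack consumes the whole sequence; config invalid")
        self.token_len = T
        self.pos_emb = Parameter(rng.normal(0.0, 0.02, size=(T, cfg.d_model)))
        self.blocks = [
            TransformerEncoderLayer(cfg.d_model, cfg.n_heads, cfg.d_ff, rng, cfg.dropout)
            for _ in range(cfg.n_layers)
        ]
        self.drop = Dropout(cfg.dropout, rng)
        if cfg.use_residual_fusion:
            self.res_fc = Linear(cfg.n_residual_features, cfg.fusion_width, rng)
            head_in = cfg.d_model + cfg.fusion_width
        else:
            self.res_fc = None
            head_in = cfg.d_model
        self.fc1 = Linear(head_in, cfg.head_hidden, rng)
        self.fc2 = Linear(cfg.head_hidden, cfg.n_classes, rng)

    def logits(self, x: np.ndarray | Tensor, residual: np.ndarray | Tensor | None = None) -> Tensor:
        h = x if isinstance(x, Tensor) else Tensor(x)
        if h.ndim != 3:
            raise ValueError("expected input of shape (batch, time, channels)")
        if h.shape[2] != self.cfg.in_channels:
            raise ValueError(
                f"channel mismatch: got {h.shape[2]}, model expects {self.cfg.in_channels}"
            )
        for conv in self.convs:
            h = conv(h).relu()
        h = h + self.pos_emb
        h = self.drop(h)
        for block in self.blocks:
            h = block(h)
        pooled = h.mean(axis=1)  # (B, d_model)
        if self.res_fc is not None:
            if residual is None:
                raise ValueError("model was built with residual fusion; residual features required")
            r = residual if isinstance(residual, Tensor) else Tensor(residual)
            pooled = concat([pooled, self.res_fc(r).relu()], axis=-1)
        return self.fc2(self.fc1(pooled).relu())

    def predict_proba(self, x: np.ndarray, residual: np.ndarray | None = None) -> np.ndarray:
        was_training = self.training
        self.eval()
        out = self.logits(x, residual).softmax(axis=-1).data
        if was_training:
            self.train()
        return out

    def attach_lora(self, cfg: LoRAConfig, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        if not self.blocks:
            raise ValueError("no transformer sublayers present to adapt")
        for block in self.blocks:
            block.attn.attach_lora(cfg.rank, cfg.alpha, rng, targets=cfg.targets)
        self.lora_cfg_ = cfg

    def lora_parameters(self) -> list[tuple[str, Parameter]]:
        return [(n, p) for n, p in self.named_parameters() if ".lora_" in n]


def build_classifier(cfg: ClassifierConfig, seed: int = 0) -> StrainWordNet:
    """Construct the classifier; forward yields a probability simplex."""
    return StrainWordNet(cfg, seed=seed)


# ---------------------------------------------------------------------------
# Cross-validation folds


@dataclass
class FoldPlan:
    """A subject-disjoint, class-stratified k-fold assignment."""

    k: int
    fold_of_sample: np.ndarray  # (N,) fold index per sample
    subjects_per_fold: list[set]

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample != fold)


def make_folds(labels, subjects, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified, subject-independent k-fold plan.

    Subjects are assigned whole to folds (no subject straddles a train/test
    boundary); assignment greedily balances per-fold sample counts after a
    seeded shuffle, which yields exact 1/k per-class test shares when classes
    are spread evenly over subjects.
    """
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    if len(uniq) < k:
        raise ValueError(
            f"need at least k={k} subjects for a subject-independent plan, got {len(uniq)}; "
            "reduce k or collect data from more subjects"
        )
    rng = np.random.default_rng(seed)
    counts = {s: int((subjects == s).sum()) for s in uniq}
    order = list(uniq[rng.permutation(len(uniq))])
    order.sort(key=lambda s: -counts[s])  # stable: big subjects first, seeded ties
    fold_sizes = np.zeros(k)
    fold_subjects: list[set] = [set() for _ in range(k)]
    for s in order:
        f = int(np.argmin(fold_sizes))
        fold_subjects[f].add(s)
        fold_sizes[f] += counts[s]
    subj_to_fold = {s: f for f, ss in enumerate(fold_subjects) for s in ss}
    fold_of_sample = np.array([subj_to_fold[s] for s in subjects], dtype=int)
    return FoldPlan(k=k, fold_of_sample=fold_of_sample, subjects_per_fold=fold_subjects)


# ---------------------------------------------------------------------------
# Losses and the shared fit loop


def _cross_entropy(logits: Tensor, y: np.ndarray) -> Tensor:
    B, K = logits.shape
    onehot = np.zeros((B, K))
    onehot[np.arange(B), y] = 1.0
    logp = logits.log_softmax(axis=-1)
    return -(logp * onehot).sum() * (1.0 / B)


def _soft_loss(student_logits: Tensor, teacher_logits: np.ndarray, temperature: float) -> Tensor:
    """KL(teacher_T || student_T) scaled by T^2 (batch mean)."""
    t = temperature
    tl = teacher_logits / t
    tl = tl - tl.max(axis=-1, keepdims=True)
    pt = np.exp(tl)
    pt /= pt.sum(axis=-1, keepdims=True)
    log_ps = (student_logits * (1.0 / t)).log_softmax(axis=-1)
    B = student_logits.shape[0]
    const = float((pt * np.log(pt + 1e-32)).sum() / B)
    return (const - (log_ps * pt).sum() * (1.0 / B)) * (t * t)


def _dataset_loss(model: StrainWordNet, ds: ArrayDataset, batch: int = 256) -> float:
    model.eval()
    total = 0.0
    for i in range(0, len(ds), batch):
        sl = slice(i, i + batch)
        logits = model.logits(ds.X[sl], ds.residual[sl])
        total += float(_cross_entropy(logits, ds.y[sl]).data) * (len(ds.y[sl]))
    model.train()
    return total / len(ds)


def _fit(
    model: StrainWordNet,
    train_set: ArrayDataset,
    val_set: ArrayDataset,
    cfg: TrainConfig,
    params: list[Parameter] | None = None,
    teacher: StrainWordNet | None = None,
    temperature: float = 4.0,
    soft_weight: float = 0.0,
) -> dict:
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    if train_set.y.max() >= model.cfg.n_classes:
        raise ValueError("label outside the model's class space")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(params if params is not None else model.parameters(), lr=cfg.lr)
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = -1
    model.train()
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(len(train_set))
        epoch_loss = 0.0
        for i in range(0, len(perm), cfg.batch_train):
            idx = perm[i : i + cfg.batch_train]
            logits = model.logits(train_set.X[idx], train_set.residual[idx])
            loss = _cross_entropy(logits, train_set.y[idx])
            if teacher is not None and soft_weight > 0.0:
                with_teacher = teacher.logits(train_set.X[idx], train_set.residual[idx]).data
                loss = loss * (1.0 - soft_weight) + _soft_loss(logits, with_teacher, temperature) * soft_weight
            if not np.isfinite(loss.data):
                raise RuntimeError(f"NaN/inf loss at epoch {epoch}; aborting training")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        history["train_loss"].append(epoch_loss / len(train_set))
        val_loss = _dataset_loss(model, val_set, batch=max(cfg.batch_train, 32))
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_epoch = epoch
            best_state = model.state_dict()
        elif epoch - best_epoch >= cfg.patience:
            break
    model.load_state_dict(best_state)
    model.eval()
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = best_val
    if cfg.checkpoint_path:
        export_model(model, cfg.checkpoint_path)
    return history


def train(model: StrainWordNet, train_set: ArrayDataset, val_set: ArrayDataset, cfg: TrainConfig) -> dict:
    """Train with Adam + cross-entropy, early stopping, best-val checkpoint.

    Returns the per-epoch history; the model is left at the checkpointed
    best-validation weights.
    """
    return _fit(model, train_set, val_set, cfg)


def evaluate(model: StrainWordNet, test_set: ArrayDataset) -> tuple[float, np.ndarray]:
    """Top-1 accuracy at batch size 1 and the confusion matrix (rows = truth)."""
    if len(test_set) == 0:
        raise ValueError("test set must be non-empty")
    if test_set.y.max() >= model.cfg.n_classes:
        raise ValueError("label outside the model's class space")
    preds = np.empty(len(test_set), dtype=int)
    for i in range(len(test_set)):
        proba = model.predict_proba(test_set.X[i : i + 1], test_set.residual[i : i + 1])
        preds[i] = int(np.argmax(proba[0]))
    acc = float(np.mean(preds == test_set.y))
    cm = _sk_confusion(test_set.y, preds, labels=np.arange(model.cfg.n_classes))
    return acc, cm


def distill(
    teacher: StrainWordNet,
    cfg: DistillConfig,
    train_set: ArrayDataset,
    val_set: ArrayDataset,
    train_cfg: TrainConfig | None = None,
) -> tuple[StrainWordNet, dict]:
    """Train a smaller student against hard labels and the teacher's softened
    probabilities: (1 - lambda) * CE + lambda * T^2 * KL."""
    train_cfg = train_cfg or TrainConfig()
    scfg = copy.deepcopy(cfg.student)
    scfg.in_channels = teacher.cfg.in_channels
    scfg.n_classes = teacher.cfg.n_classes
    scfg.seq_len = teacher.cfg.seq_len
    scfg.n_residual_features = teacher.cfg.n_residual_features
    scfg.use_residual_fusion = teacher.cfg.use_residual_fusion
    student = StrainWordNet(scfg, seed=train_cfg.seed)
    if student.n_parameters() >= teacher.n_parameters():
        raise ValueError("student must be smaller than the teacher")
    teacher.eval()
    history = _fit(
        student,
        train_set,
        val_set,
        train_cfg,
        teacher=teacher if cfg.soft_weight > 0 else None,
        temperature=cfg.temperature,
        soft_weight=cfg.soft_weight,
    )
    return student, history


def lora_adapt(
    model: StrainWordNet,
    new_user_set: ArrayDataset,
    cfg: LoRAConfig,
    train_cfg: TrainConfig | None = None,
    holdout_fraction: float = 0.3,
) -> tuple[StrainWordNet, dict]:
    """User adaptation with low-rank factors on the attention projections.

    Rank-r additive factors are attached to the configured projections of
    every transformer block; only those factors (and optionally the head)
    receive gradients — base weights stay bit-identical.  The report gives
    the trainable-parameter fraction and before/after accuracy on a held-out
    split of the new user's data.
    """
    train_cfg = train_cfg or TrainConfig(max_epochs=30, patience=5)
    rng = np.random.default_rng(train_cfg.seed)
    n = len(new_user_set)
    perm = rng.permutation(n)
    n_hold = max(int(round(holdout_fraction * n)), 1)
    hold = new_user_set.subset(perm[:n_hold])
    adapt = new_user_set.subset(perm[n_hold:])

    base_total = model.n_parameters()
    acc_before, _ = evaluate(model, hold)

    model.attach_lora(cfg, seed=train_cfg.seed)
    lora_params = [p for _, p in model.lora_parameters()]
    trainable = list(lora_params)
    if cfg.adapt_head:
        trainable += [model.fc1.W, model.fc1.b, model.fc2.W, model.fc2.b]
    trainable_ids = {id(p) for p in trainable}
    frozen_snapshot = {
        n_: p.data.copy() for n_, p in model.named_parameters() if id(p) not in trainable_ids
    }
    for _, p in model.named_parameters():
        if id(p) not in trainable_ids:
            p.requires_grad = False
    history = _fit(model, adapt, hold, train_cfg, params=trainable)
    for _, p in model.named_parameters():
        p.requires_grad = True

    acc_after, _ = evaluate(model, hold)
    for n_, p in model.named_parameters():
        if id(p) not in trainable_ids:
            assert np.array_equal(p.data, frozen_snapshot[n_]), "frozen weight drifted"
    n_trainable = sum(p.data.size for p in trainable)
    report = {
        "trainable_parameters": n_trainable,
        "total_parameters": base_total + sum(p.data.size for p in lora_params),
        "trainable_fraction": n_trainable / (base_total + sum(p.data.size for p in lora_params)),
        "accuracy_before": acc_before,
        "accuracy_after": acc_after,
        "history": history,
    }
    return model, report


# ---------------------------------------------------------------------------
# Portable serialization


def export_model(model: StrainWordNet, path: str | Path, stats: signals.NormStats | None = None) -> Path:
    """Serialize architecture + weights to a portable NPZ checkpoint.

    The archive holds every named parameter array plus a JSON description of
    the architecture; a reloaded model reproduces outputs exactly.  Optional
    normalization statistics ride along so inference can precondition inputs
    the way training did.
    """
    path = Path(path)
    cfg = model.cfg
    meta = {
        "format": "strainspeech-checkpoint-v1",
        "config": {
            "in_channels": cfg.in_channels,
            "n_classes": cfg.n_classes,
            "seq_len": cfg.seq_len,
            "conv_blocks": [list(b) for b in cfg.conv_blocks],
            "n_layers": cfg.n_layers,
            "n_heads": cfg.n_heads,
            "d_ff": cfg.d_ff,
            "n_residual_features": cfg.n_residual_features,
            "fusion_width": cfg.fusion_width,
            "head_hidden": cfg.head_hidden,
            "dropout": cfg.dropout,
            "use_residual_fusion": cfg.use_residual_fusion,
        },
    }
    lcfg = getattr(model, "lora_cfg_", None)
    if lcfg is not None:
        meta["lora"] = {"rank": lcfg.rank, "alpha": lcfg.alpha, "targets": list(lcfg.targets)}
    arrays = {f"param/{name}": p.data for name, p in model.named_parameters()}
    if stats is None:
        stats = getattr(model, "norm_stats_", None)
    if stats is not None:
        arrays["norm/mu"] = np.atleast_1d(np.asarray(stats.mu, dtype=float))
        arrays["norm/sigma"] = np.atleast_1d(np.asarray(stats.sigma, dtype=float))
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_model(path: str | Path) -> StrainWordNet:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        if meta.get("format") != "strainspeech-checkpoint-v1":
            raise ValueError("unrecognized checkpoint format")
        c = meta["config"]
        cfg = ClassifierConfig(
            in_channels=c["in_channels"],
            n_classes=c["n_classes"],
            seq_len=c["seq_len"],
            conv_blocks=tuple(tuple(b) for b in c["conv_blocks"]),
            n_layers=c["n_layers"],
            n_heads=c["n_heads"],
            d_ff=c["d_ff"],
            n_residual_features=c["n_residual_features"],
            fusion_width=c["fusion_width"],
            head_hidden=c["head_hidden"],
            dropout=c["dropout"],
            use_residual_fusion=c["use_residual_fusion"],
        )
        model = StrainWordNet(cfg, seed=0)
        if "lora" in meta:
            lora = meta["lora"]
            model.attach_lora(LoRAConfig(rank=lora["rank"], alpha=lora["alpha"], targets=tuple(lora["targets"])))
        state = {name[len("param/") :]: archive[name] for name in archive.files if name.startswith("param/")}
        if "norm/mu" in archive.files:
            mu, sigma = archive["norm/mu"], archive["norm/sigma"]
            model.norm_stats_ = signals.NormStats(
                mu=float(mu[0]) if mu.size == 1 else mu,
                sigma=float(sigma[0]) if sigma.size == 1 else sigma,
            )
    model.load_state_dict(state)
    model.eval()
    return model


# ---------------------------------------------------------------------------
# scikit-learn estimator facade


class SequenceClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn interface to the CNN-Transformer word decoder.

    ``fit(X, y)`` expects ``X`` of shape (n_samples, seq_len, n_channels);
    residual-map features may be passed via ``residual=``.  A stratified
    fraction of the training data is held out internally for early stopping.
    """

    def __init__(
        self,
        conv_blocks=((32, 5, 2), (64, 5, 2)),
        n_layers: int = 2,
        n_heads: int = 4,
        d_ff: int = 128,
        fusion_width: int = 32,
        head_hidden: int = 64,
        dropout: float = 0.1,
        lr: float = 1e-3,
        batch_size: int = 256,
        max_epochs: int = 60,
        patience: int = 8,
        val_fraction: float = 0.15,
        n_residual_features: int = 16,
        random_state: int = 0,
    ):
        self.conv_blocks = conv_blocks
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.d_ff = d_ff
        self.fusion_width = fusion_width
        self.head_hidden = head_hidden
        self.dropout = dropout
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.n_residual_features = n_residual_features
        self.random_state = random_state

    def _validate(self, X, residual):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_samples, seq_len, n_channels)")
        if residual is None:
            residual = np.zeros((len(X), self.n_residual_features))
        residual = np.asarray(residual, dtype=float)
        return X, residual

    def fit(self, X, y, residual=None):
        X, residual = self._validate(X, residual)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        cfg = ClassifierConfig(
            in_channels=X.shape[2],
            n_classes=len(self.classes_),
            seq_len=X.shape[1],
            conv_blocks=tuple(tuple(b) for b in self.conv_blocks),
            n_layers=self.n_layers,
            n_heads=self.n_heads,
            d_ff=self.d_ff,
            n_residual_features=residual.shape[1],
            fusion_width=self.fusion_width,
            head_hidden=self.head_hidden,
            dropout=self.dropout,
        )
        rng = np.random.default_rng(self.random_state)
        n_val = max(int(round(self.val_fraction * len(y))), 1)
        perm = rng.permutation(len(y))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        subjects = np.zeros(len(y), dtype=int)
        ds = ArrayDataset(X, residual, y_enc, subjects)
        self.model_ = StrainWordNet(cfg, seed=self.random_state)
        tcfg = TrainConfig(
            lr=self.lr,
            batch_train=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            seed=self.random_state,
        )
        self.history_ = _fit(self.model_, ds.subset(tr_idx), ds.subset(val_idx), tcfg)
        return self

    def predict_proba(self, X, residual=None):
        X, residual = self._validate(X, residual)
        out = []
        for i in range(0, len(X), 256):
            out.append(self.model_.predict_proba(X[i : i + 256], residual[i : i + 256]))
        return np.concatenate(out, axis=0)

    def predict(self, X, residual=None):
        proba = self.predict_proba(X, residual)
        return self.classes_[np.argmax(proba, axis=1)]

    def score(self, X, y, residual=None):
        return float(np.mean(self.predict(X, residual) == np.asarray(y)))
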