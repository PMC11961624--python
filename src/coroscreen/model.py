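"""Task training, the three-task cascade, and 5-member ensembling.

Three binary tasks are trained on cropped+preprocessed volumes:

* ``anomaly`` — normal vs AAOCA (all cases, trained from scratch);
* ``origin``  — right vs left anomalous vessel (AAOCA cases only);
* ``risk``    — low vs high anatomical risk (AAOCA cases only).

Origin and risk networks are fine-tuned from the anomaly checkpoint.
Training uses binary cross entropy, a cosine-annealed learning rate
(lr0 = 0.001 over the configured epochs), early stopping on validation
loss, and a patient-wise 90:10 train/validation split shared by all
ensemble members; members differ only in their weight-initialization seed
and the ensemble probability is the arithmetic mean of member
probabilities.  Multi-phase cases are averaged over phases at inference.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import AugmentationConfig, augment
from .localize import crop_case
from .nn import NetworkConfig, RMSprop, Adam, SEResNet3D, bce_with_logits, build_network, cosine_lr
from .preprocess import PreprocessConfig, preprocess_pipeline

__all__ = [
    "TrainConfig",
    "TensorCase",
    "PredictionSet",
    "TrainedTask",
    "POSITIVE_CLASS",
    "task_label",
    "cases_to_tensors",
    "split_patientwise",
    "train_task",
    "fine_tune",
    "predict_case",
    "predict_cases",
    "SEResNetClassifier",
]

#: Positive-class encoding for each binary task.
POSITIVE_CLASS = {"anomaly": 1, "origin": "right", "risk": "high"}


@dataclass
class TrainConfig:
    lr0: float = 0.001
    total_epochs: int = 300
    batch_size: int = 8
    patience: int = 20
    split_ratio: float = 0.9
    n_members: int = 5
    member_seeds: tuple | None = None
    optimizer: str = "rmsprop"          # momentum-free adaptive default
    weight_decay: float = 0.0
    augment_config: AugmentationConfig | None = None
    seed: int = 0

    def seeds(self) -> list[int]:
        if self.member_seeds is not None:
            if len(self.member_seeds) != self.n_members:
                raise ValueError("member_seeds must have n_members entries")
            return list(self.member_seeds)
        return [self.seed * 1000 + m for m in range(self.n_members)]


@dataclass
class TensorCase:
    """Preprocessed network inputs for one patient (one tensor per phase)."""

    case_id: str
    tensors: list
    y_anomaly: int
    y_origin: str | None = None
    y_risk: str | None = None
    group: dict = field(default_factory=dict)


@dataclass
class PredictionSet:
    """Per-case member and ensemble probabilities for one task."""

    case_id: str
    task: str
    member_probs: np.ndarray
    ensemble_prob: float
    y_true: int | None = None

    def __post_init__(self):
        self.member_probs = np.asarray(self.member_probs, dtype=float)
        expected = float(self.member_probs.mean())
        if not np.isclose(self.ensemble_prob, expected):
            raise ValueError("ensemble_prob must be the mean of member_probs")


@dataclass
class TrainedTask:
    task: str
    members: list
    histories: list
    train_ids: list
    val_ids: list
    net_config: NetworkConfig
    train_config: TrainConfig


def task_label(case, task: str) -> int | None:
    """Binary label of a case for a task; None when undefined (normals on
    origin/risk)."""
    if task == "anomaly":
        return int(case.y_anomaly)
    if case.y_anomaly == 0:
        return None
    if task == "origin":
        return int(case.y_origin == POSITIVE_CLASS["origin"])
    if task == "risk":
        return int(case.y_risk == POSITIVE_CLASS["risk"])
    raise ValueError(f"unknown task {task!r}")


def cases_to_tensors(records, preprocess_config: PreprocessConfig | None = None,
                     extent_mm=(80.0, 80.0, 60.0), offset_mm=(10.0, 0.0, 10.0),
                     segmenter=None) -> list[TensorCase]:
    """Crop each phantom case around its aortic root and preprocess all phases.

    ``segmenter`` maps an ImageVolume to a LabelMap; by default the case's
    ground-truth label map drives the crop (segmentation bypassed).
    """
    cfg = preprocess_config or PreprocessConfig()
    out = []
    for rec in records:
        labels = segmenter(rec.volumes[0]) if segmenter is not None else rec.label_map
        tensors = []
        for vol in rec.volumes:
            crop = crop_case(vol, labels, extent_mm=extent_mm, offset_mm=offset_mm)
            tensors.append(preprocess_pipeline(crop, cfg))
        out.append(TensorCase(rec.case_id, tensors, rec.y_anomaly, rec.y_origin,
                              rec.y_risk, dict(rec.group)))
    return out


def split_patientwise(case_ids, ratio: float = 0.9, seed: int = 0):
    """Disjoint train/validation patient-id sets; all phases follow their patient.

    |validation| = round((1 - ratio) * n_patients), at least 1.
    """
    ids = list(dict.fromkeys(case_ids))      # unique, order-preserving
    if len(ids) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_val = max(int(round((1.0 - ratio) * len(ids))), 1)
    val_ids = [ids[i] for i in perm[:n_val]]
    train_ids = [ids[i] for i in perm[n_val:]]
    return train_ids, val_ids


def _flatten_samples(cases, task):
    xs, ys = [], []
    for c in cases:
        y = task_label(c, task)
        if y is None:
            continue
        for t in c.tensors:
            xs.append(t)
            ys.append(y)
    return np.asarray(xs, dtype=np.float32), np.asarray(ys, dtype=np.float64)


def _evaluate(model: SEResNet3D, x, y, batch_size=16):
    probs = model.predict_proba(x, batch_size=batch_size)
    eps = 1e-7
    loss = float(-np.mean(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)))
    acc = float(np.mean((probs >= 0.5) == (y == 1)))
    return loss, acc


def _train_member(model, x_tr, y_tr, x_val, y_val, cfg: TrainConfig, member_seed: int,
                  eval_fn=None):
    """One member's training loop: BCE + cosine schedule + early stopping.

    Checkpoint selection: lowest validation loss, ties broken by higher
    validation accuracy.  ``eval_fn(model, epoch) -> (val_loss, val_acc)``
    substitutes the internal validation pass (used to script trajectories
    in tests).
    """
    rng = np.random.default_rng(member_seed)
    opt = Adam(model, weight_decay=cfg.weight_decay) if cfg.optimizer == "adam" \
        else RMSprop(model, weight_decay=cfg.weight_decay)
    best = (np.inf, -np.inf, None)           # (val_loss, -val_acc ordering via tuple)
    history = []
    since_best = 0
    for epoch in range(cfg.total_epochs):
        lr = cosine_lr(epoch, cfg.total_epochs, cfg.lr0)
        order = rng.permutation(len(x_tr))
        epoch_loss = 0.0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb = x_tr[idx]
            if cfg.augment_config is not None:
                xb = np.stack([augment(t, cfg.augment_config, rng) for t in xb])
            model.zero_grad()
            logits = model.forward(xb, train=True)
            loss, dlog = bce_with_logits(logits, y_tr[idx])
            model.backward(dlog)
            opt.step(lr)
            epoch_loss += loss * len(idx)
        epoch_loss /= max(len(order), 1)
        if eval_fn is not None:
            val_loss, val_acc = eval_fn(model, epoch)
        else:
            val_loss, val_acc = _evaluate(model, x_val, y_val)
        history.append({"epoch": epoch, "lr": lr, "train_loss": epoch_loss,
                        "val_loss": val_loss, "val_acc": val_acc})
        if (val_loss < best[0]) or (val_loss == best[0] and val_acc > best[1]):
            best = (val_loss, val_acc, model.state_dict())
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if best[2] is not None:
        model.load_state_dict(best[2])
    return model, pd.DataFrame(history)


def train_task(cases, task: str, net_config: NetworkConfig, train_config: TrainConfig,
               pretrained: SEResNet3D | None = None, eval_fn=None) -> TrainedTask:
    """Train the n-member ensemble for one task on TensorCase records."""
    eligible = [c for c in cases if task_label(c, task) is not None]
    if not eligible:
        raise ValueError(f"no cases carry a label for task {task!r}")
    train_ids, val_ids = split_patientwise([c.case_id for c in eligible],
                                           train_config.split_ratio, train_config.seed)
    by_id = {c.case_id: c for c in eligible}
    tr_cases = [by_id[i] for i in train_ids]
    val_cases = [by_id[i] for i in val_ids]
    x_tr, y_tr = _flatten_samples(tr_cases, task)
    x_val, y_val = _flatten_samples(val_cases, task)
    for name, y in (("training", y_tr), ("validation", y_val)):
        if eval_fn is None and len(np.unique(y)) < 2:
            raise ValueError(f"{name} partition holds a single class for task {task!r}")

    members, histories = [], []
    for seed in train_config.seeds():
        if pretrained is not None:
            model = fine_tune_init(pretrained, net_config, seed)
        else:
            model = build_network(net_config, seed=seed)
        model, hist = _train_member(model, x_tr, y_tr, x_val, y_val, train_config, seed,
                                    eval_fn=eval_fn)
        members.append(model)
        histories.append(hist)
    return TrainedTask(task, members, histories, train_ids, val_ids, net_config, train_config)


def fine_tune_init(pretrained: SEResNet3D, net_config: NetworkConfig, seed: int) -> SEResNet3D:
    """Fresh network carrying the pretrained backbone; head re-initialized."""
    if pretrained.config != net_config:
        raise ValueError("architecture mismatch between pretrained network and net_config")
    model = build_network(net_config, seed=seed)    # fresh (seeded) head
    model.load_state_dict(pretrained.state_dict(), skip_head=True)
    return model


def fine_tune(pretrained: SEResNet3D, cases, task: str, net_config: NetworkConfig,
              train_config: TrainConfig, eval_fn=None) -> TrainedTask:
    """Task-cascade transfer: initialize members from the anomaly backbone."""
    return train_task(cases, task, net_config, train_config, pretrained=pretrained,
                      eval_fn=eval_fn)


def predict_case(models, case: TensorCase, task: str = "anomaly",
                 phase_aggregate: str = "mean") -> PredictionSet:
    """Member probability = aggregate over phases; ensemble = mean over members."""
    models = list(models)
    if not models:
        raise ValueError("need at least one model")
    if not case.tensors:
        raise ValueError(f"case {case.case_id} has no phase volumes")
    x = np.asarray(case.tensors, dtype=np.float32)
    member_probs = []
    for m in models:
        phase_probs = m.predict_proba(x)
        member_probs.append(float(np.max(phase_probs) if phase_aggregate == "max"
                                  else np.mean(phase_probs)))
    member_probs = np.asarray(member_probs)
    return PredictionSet(case.case_id, task, member_probs, float(member_probs.mean()),
                         y_true=task_label(case, task))


def predict_cases(trained: TrainedTask, cases, phase_aggregate: str = "mean") -> pd.DataFrame:
    rows = []
    for c in cases:
        ps = predict_case(trained.members, c, trained.task, phase_aggregate)
        row = {"case_id": ps.case_id, "task": ps.task, "ensemble_prob": ps.ensemble_prob,
               "y_true": ps.y_true}
        row.update({f"member_{i}": p for i, p in enumerate(ps.member_probs)})
        row.update({f"group_{k}": v for k, v in c.group.items()})
        rows.append(row)
    return pd.DataFrame(rows)


class SEResNetClassifier:
    """scikit-learn style binary classifier over [0,1] volume tensors.

    ``fit(X, y)`` trains an ensemble of ``n_members`` networks sharing one
    patient-wise split; ``predict_proba`` returns the ensemble average.
    X is (n, D, H, W); an optional ``case_ids`` keeps multi-phase samples of
    one patient on one side of the split.
    """

    _param_names = ("net_config", "train_config")

    def __init__(self, net_config: NetworkConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.net_config = net_config
        self.train_config = train_config

    def fit(self, X, y, case_ids=None):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary classification requires exactly two classes")
        net_cfg = self.net_config or NetworkConfig.tiny(X.shape[1:])
        train_cfg = self.train_config or TrainConfig(total_epochs=25)
        if case_ids is None:
            case_ids = [f"s{i}" for i in range(len(X))]
        cases = [TensorCase(str(cid), [x], int(yy == self.classes_[1]))
                 for cid, x, yy in zip(case_ids, X, y)]
        trained = train_task(cases, "anomaly", net_cfg, train_cfg)
        self.members_ = trained.members
        self.histories_ = trained.histories
        self.train_ids_, self.val_ids_ = trained.train_ids, trained.val_ids
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float32)
        probs = np.mean([m.predict_proba(X) for m in self.members_], axis=0)
        return np.column_stack([1.0 - probs, probs])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self
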