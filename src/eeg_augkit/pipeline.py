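"""Unified training: online augmentation inside training folds, early stopping,
stratified cross-validation and per-condition reporting.

The protocol, per fold: build a freshly initialised model, train it with
mini-batch Adam on the training fold — each drawn sample is perturbed online
with the condition's augmentation policy — monitor validation loss, restore the
best-epoch weights, and report validation accuracy. Validation samples are
never augmented; an instrumented log of every augmented segment id backs the
leakage guard. Fold accuracies are aggregated into mean, sample std and a
Student-t confidence interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import nn
from .augment import AugmentationPolicy, apply_augmentation, sample_augmentation
from .crossval import CVSummary, aggregate_metrics, fold_split, stratified_folds
from .models import ModelSpec, build_model
from .segment import EEGSegment
from .synthetic import ID_TO_STAGE, make_shifted_eval_set


class LeakageError(RuntimeError):
    """Train and validation sets share segments — the run is invalid."""


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """In-memory labelled dataset: X (n, channels, time), y (n,), unique ids."""

    X: np.ndarray
    y: np.ndarray
    ids: list[str]
    fs: float

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=nn.DTYPE)
        self.y = np.asarray(self.y, dtype=int)
        if not (len(self.X) == len(self.y) == len(self.ids)):
            raise ValueError("X, y and ids must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("segment ids must be unique")

    @classmethod
    def from_segments(cls, segments: list[EEGSegment]) -> "Dataset":
        if not segments:
            raise ValueError("no segments")
        ids = []
        seen = set()
        for i, seg in enumerate(segments):
            sid = seg.source_id or f"seg-{i:06d}"
            if sid in seen:
                sid = f"{sid}#{i}"
            seen.add(sid)
            ids.append(sid)
        X = np.stack([seg.data for seg in segments])
        y = np.array([seg.label for seg in segments])
        return cls(X=X, y=y, ids=ids, fs=segments[0].fs)

    def to_segments(self) -> list[EEGSegment]:
        return [EEGSegment(data=self.X[i].copy(), fs=self.fs, label=int(self.y[i]),
                           source_id=self.ids[i]) for i in range(len(self))]

    def subset(self, indices) -> "Dataset":
        indices = np.asarray(indices, dtype=int)
        return Dataset(X=self.X[indices], y=self.y[indices],
                       ids=[self.ids[i] for i in indices], fs=self.fs)

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    @property
    def n_samples(self) -> int:
        return self.X.shape[2]


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training hyperparameters; defaults follow the study protocol where it
    states them (batch 512, up to 200 epochs, early stopping on validation
    loss) and community defaults where it does not (Adam, 1e-3,
    cross-entropy)."""

    batch_size: int = 512
    max_epochs: int = 200
    early_stop_patience: int = 20
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    loss: str = "cross_entropy"
    seed: int = 0
    device: str = "cpu"
    #: "replace": each draw is stochastically augmented in place (default);
    #: "append": every epoch streams raw plus one augmented copy per sample
    augment_mode: str = "replace"

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_epochs < 1 or self.early_stop_patience < 1:
            raise ValueError("batch_size, max_epochs and patience must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if self.augment_mode not in ("replace", "append"):
            raise ValueError(f"augment_mode must be 'replace' or 'append'")


CONDITION_TAGS = ("raw", "raw+ts", "raw+as", "raw+na", "raw+ts+as+na")

_TAG_METHODS = {
    "raw": (),
    "raw+ts": ("TS",),
    "raw+as": ("AS",),
    "raw+na": ("NA",),
    "raw+ts+as+na": ("TS", "AS", "NA"),
}


@dataclass
class ExperimentCondition:
    """An augmentation condition: a tag plus the policy it induces."""

    tag: str
    policy: AugmentationPolicy

    @classmethod
    def from_tag(cls, tag: str, apply_prob: float = 0.5,
                 **policy_kwargs) -> "ExperimentCondition":
        if tag not in CONDITION_TAGS:
            raise ValueError(f"unknown condition {tag!r}; known: {CONDITION_TAGS}")
        methods = _TAG_METHODS[tag]
        if not methods:
            return cls(tag=tag, policy=AugmentationPolicy.disabled())
        return cls(tag=tag, policy=AugmentationPolicy(
            enabled=methods, apply_prob=apply_prob, **policy_kwargs))


@dataclass
class LabelScheme:
    """Mapping from the five sleep stages to a coarser class granularity."""

    granularity: str
    mapping: dict[str, int]
    class_names: list[str]


LABEL_SCHEMES = {
    "binary-N3": LabelScheme(
        "binary-N3",
        {"Wake": 0, "N1": 0, "N2": 0, "REM": 0, "N3": 1},
        ["non-N3", "N3"]),
    "3-class": LabelScheme(
        "3-class",
        {"Wake": 0, "N1": 1, "N2": 1, "N3": 1, "REM": 2},
        ["Wake", "NREM", "REM"]),
    "4-class": LabelScheme(
        "4-class",
        {"Wake": 0, "N1": 1, "N2": 1, "N3": 2, "REM": 3},
        ["Wake", "LightSleep", "DeepSlowWave", "REM"]),
    "5-class": LabelScheme(
        "5-class",
        {"Wake": 0, "N1": 1, "N2": 2, "N3": 3, "REM": 4},
        ["Wake", "N1", "N2", "N3", "REM"]),
}


def apply_label_scheme(dataset: Dataset, scheme: LabelScheme | str) -> Dataset:
    """Relabel a dataset carrying five-stage labels under a coarser scheme."""
    if isinstance(scheme, str):
        scheme = LABEL_SCHEMES[scheme]
    new_y = np.empty_like(dataset.y)
    for i, lab in enumerate(dataset.y):
        stage = ID_TO_STAGE.get(int(lab))
        if stage is None or stage not in scheme.mapping:
            raise ValueError(f"unknown stage label {lab} at index {i}")
        new_y[i] = scheme.mapping[stage]
    return replace(dataset, y=new_y, ids=list(dataset.ids))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _forward_batches(net: nn.Sequential, ds: Dataset, batch_size: int
                     ) -> tuple[float, float]:
    """(mean loss, accuracy) in evaluation mode."""
    losses, n_correct = [], 0
    for start in range(0, len(ds), batch_size):
        Xb = ds.X[start:start + batch_size]
        yb = ds.y[start:start + batch_size]
        logits = net.forward(Xb, train=False)
        loss, _ = nn.cross_entropy(logits, yb)
        losses.append(loss * len(yb))
        n_correct += int((logits.argmax(axis=1) == yb).sum())
    return sum(losses) / len(ds), n_correct / len(ds)


def evaluate_accuracy(net: nn.Sequential, ds: Dataset, batch_size: int = 256) -> float:
    """Fraction of segments whose argmax prediction matches the label."""
    if len(ds) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    return _forward_batches(net, ds, batch_size)[1]


def _maybe_augment(x: np.ndarray, fs: float, policy: AugmentationPolicy,
                   rng: np.random.Generator, force: bool,
                   log: set | None, sid: str) -> np.ndarray:
    active = policy.enabled and (force or policy.apply_prob > 0)
    if not active:
        return x
    if not force and not (rng.uniform() < policy.apply_prob):
        return x
    seg = EEGSegment(data=x, fs=fs, label=0)
    method, param = sample_augmentation(policy, seg, rng)
    seg = apply_augmentation(seg, method, param, rng)
    if log is not None:
        log.add(sid)
    return seg.data


def train_one_fold(net: nn.Sequential, train_ds: Dataset, val_ds: Dataset,
                   config: TrainConfig, policy: AugmentationPolicy,
                   rng: np.random.Generator,
                   augment_log: set | None = None) -> tuple[nn.Sequential, float]:
    """Train with online augmentation, early-stop on validation loss, and
    return (model restored to its best epoch, its validation accuracy)."""
    overlap = set(train_ds.ids) & set(val_ds.ids)
    if overlap:
        raise LeakageError(
            f"{len(overlap)} segment(s) present in both train and validation "
            f"sets, e.g. {sorted(overlap)[:3]}")
    shuffle_rng, aug_rng, drop_rng = rng.spawn(3)
    net.set_rng(drop_rng)
    opt = nn.Adam(net, lr=config.learning_rate)

    best_loss, best_state, best_acc = np.inf, net.get_state(), np.nan
    stall = 0
    n = len(train_ds)
    augmenting = bool(policy.enabled) and policy.apply_prob > 0
    for _epoch in range(config.max_epochs):
        order = shuffle_rng.permutation(n)
        entries = [(int(i), False) for i in order]
        if augmenting and config.augment_mode == "append":
            extra = [(int(i), True) for i in shuffle_rng.permutation(n)]
            entries += extra
        for start in range(0, len(entries), config.batch_size):
            chunk = entries[start:start + config.batch_size]
            Xb = np.empty((len(chunk),) + train_ds.X.shape[1:], dtype=nn.DTYPE)
            yb = np.empty(len(chunk), dtype=int)
            for row, (i, force) in enumerate(chunk):
                Xb[row] = _maybe_augment(train_ds.X[i], train_ds.fs, policy,
                                         aug_rng, force, augment_log,
                                         train_ds.ids[i])
                yb[row] = train_ds.y[i]
            logits = net.forward(Xb, train=True)
            _loss, grad = nn.cross_entropy(logits, yb)
            net.backward(grad)
            opt.step()
        val_loss, val_acc = _forward_batches(net, val_ds, config.batch_size)
        if val_loss < best_loss:
            best_loss, best_state, best_acc = val_loss, net.get_state(), val_acc
            stall = 0
        else:
            stall += 1
            if stall >= config.early_stop_patience:
                break
    net.set_state(best_state)
    return net, float(best_acc)


def shifted_eval_transform(shift_frac: float, gain_jitter: float):
    """An eval-set perturbation for robustness experiments: random circular
    shift plus gain jitter applied to validation folds only."""

    def transform(val_ds: Dataset, rng: np.random.Generator) -> Dataset:
        return Dataset.from_segments(
            make_shifted_eval_set(val_ds.to_segments(), shift_frac, gain_jitter, rng))

    return transform


def run_cross_validation(dataset: Dataset, model_spec: ModelSpec,
                         condition: ExperimentCondition, config: TrainConfig,
                         k: int = 10, confidence: float = 0.95,
                         eval_transform=None,
                         augment_log: set | None = None) -> CVSummary:
    """Stratified k-fold CV of one architecture under one augmentation condition.

    Every fold trains a freshly initialised model; augmentation only ever sees
    training folds. ``eval_transform(val_ds, rng) -> Dataset`` optionally
    perturbs each validation fold (distribution-shift experiments). The
    returned summary carries a per-fold machine-readable report.
    """
    plan = stratified_folds(dataset.y, k, seed=config.seed)
    fold_seeds = np.random.SeedSequence(config.seed).spawn(k)
    per_fold, reports = [], []
    for i in range(k):
        train_idx, val_idx = fold_split(plan, i)
        train_ds = dataset.subset(train_idx)
        val_ds = dataset.subset(val_idx)
        fold_rng = np.random.default_rng(fold_seeds[i])
        if eval_transform is not None:
            val_ds = eval_transform(val_ds, fold_rng.spawn(1)[0])
        model_seed = int(fold_seeds[i].generate_state(1)[0] % (1 << 31))
        net = build_model(model_spec, seed=model_seed)
        fold_log: set = set()
        net, acc = train_one_fold(net, train_ds, val_ds, config,
                                  condition.policy, fold_rng, fold_log)
        if fold_log & set(val_ds.ids):
            raise LeakageError("augmentation touched validation segments")
        if augment_log is not None:
            augment_log |= fold_log
        per_fold.append(acc)
        reports.append({
            "fold": i,
            "accuracy": acc,
            "n_train": len(train_ds),
            "n_val": len(val_ds),
            "n_augmented": len(fold_log),
        })
    summary = aggregate_metrics(per_fold, confidence)
    summary.per_fold_reports = reports
    return summary


def cv_report(summary: CVSummary, model_spec: ModelSpec,
              condition: ExperimentCondition, config: TrainConfig,
              k: int) -> dict:
    """Machine-readable record of one condition x architecture CV run."""
    return {
        "architecture": model_spec.architecture,
        "condition": condition.tag,
        "k": k,
        "seed": config.seed,
        **summary.as_dict(),
        "per_fold_reports": summary.per_fold_reports,
    }


def save_report(path: str | Path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
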