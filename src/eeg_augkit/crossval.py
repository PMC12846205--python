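"""Stratified k-fold partitioning and fold-metric aggregation.

The dataset is split into k mutually exclusive, approximately equal-sized folds
with stratified sampling so every fold preserves the class distribution; each
fold serves once as validation and k-1 times as training material. Per-fold
metrics M_i are summarised by their mean, the sample (k-1 denominator) standard
deviation s, and a Student-t confidence interval

    mean ± t_{(1+c)/2, k-1} * s / sqrt(k).

For k = 10 and c = 0.95 the critical value is t_{0.975,9} = 2.262.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats


@dataclass
class FoldPlan:
    """Stratified assignment of segment indices to folds.

    ``assignment[i]`` is the fold id (0-based) of segment ``i``. Folds are
    disjoint, cover all indices, differ in size by at most one, and per-class
    counts across folds differ by at most one.
    """

    k: int
    assignment: np.ndarray
    class_labels: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return len(self.assignment)

    def fold_indices(self, i: int) -> np.ndarray:
        self._check_fold(i)
        return np.flatnonzero(self.assignment == i)

    def _check_fold(self, i: int) -> None:
        if not 0 <= i < self.k:
            raise IndexError(f"fold id {i} out of range [0, {self.k})")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "seed": self.seed,
            "assignment": self.assignment.tolist(),
            "class_labels": np.asarray(self.class_labels).tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldPlan":
        payload = json.loads(Path(path).read_text())
        return cls(
            k=payload["k"],
            assignment=np.asarray(payload["assignment"], dtype=int),
            class_labels=np.asarray(payload["class_labels"]),
            seed=payload["seed"],
        )


def stratified_folds(labels, k: int, seed: int) -> FoldPlan:
    """Deal each class's (shuffled) indices round-robin across k folds.

    The starting fold rotates from class to class so remainders do not pile up
    in the first folds. Deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n == 0:
        raise ValueError("no labels to partition")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of segments n={n}")

    rng = np.random.default_rng(seed)
    assignment = np.full(n, -1, dtype=int)
    start = 0
    classes = np.unique(labels)
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            import warnings

            warnings.warn(
                f"class {cls!r} has only {len(idx)} members for k={k} folds; "
                "stratification is best-effort for this class",
                stacklevel=2,
            )
        rng.shuffle(idx)
        folds = (start + np.arange(len(idx))) % k
        assignment[idx] = folds
        start = (start + len(idx)) % k
    return FoldPlan(k=k, assignment=assignment, class_labels=labels, seed=seed)


def fold_split(plan: FoldPlan, i: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (train indices, validation indices) for fold ``i`` (0-based).

    Validation is fold i; training is the union of the other folds. The two
    sets are disjoint and together cover every index.
    """
    plan._check_fold(i)
    val = np.flatnonzero(plan.assignment == i)
    train = np.flatnonzero(plan.assignment != i)
    return train, val


def t_quantile(confidence: float, df: int) -> float:
    """Two-sided Student-t critical value t_{(1+confidence)/2, df}."""
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    return float(stats.t.ppf((1 + confidence) / 2, df))


@dataclass
class CVSummary:
    """Per-fold metrics with mean, sample std and a Student-t CI of the mean."""

    per_fold: np.ndarray
    mean: float
    std: float
    ci_low: float
    ci_high: float
    confidence: float
    k: int
    per_fold_reports: list = field(default_factory=list, repr=False)

    def as_dict(self) -> dict:
        return {
            "per_fold": np.asarray(self.per_fold).tolist(),
            "mean": self.mean,
            "std": self.std,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "confidence": self.confidence,
            "k": self.k,
        }


def aggregate_metrics(per_fold, confidence: float = 0.95) -> CVSummary:
    """Summarise per-fold metric values into mean, std and CI of the mean."""
    per_fold = np.asarray(per_fold, dtype=float)
    k = len(per_fold)
    if k < 2:
        raise ValueError(f"need at least 2 folds to aggregate, got {k}")
    mean = float(per_fold.mean())
    std = float(per_fold.std(ddof=1))
    half = t_quantile(confidence, k - 1) * std / np.sqrt(k)
    return CVSummary(
        per_fold=per_fold,
        mean=mean,
        std=std,
        ci_low=mean - half,
        ci_high=mean + half,
        confidence=confidence,
        k=k,
    )
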