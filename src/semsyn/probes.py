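"""Decoding probes: do the embeddings carry the intended information?

A multinomial logistic classifier is trained to predict a per-token label
(syntactic triplet id, or a semantic category) from the token's embedding,
under run-wise cross-validation: each fold holds out one acquisition run
and trains on the rest.  A majority-class dummy fitted per fold estimates
the chance level, which varies with the task and the eligible-token set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.dummy import DummyClassifier
from sklearn.linear_model import LogisticRegression

from .embeddings import EmbeddingMatrix

__all__ = ["ProbeTask", "ProbeResult", "eligibility_filter", "probe_decoding"]


@dataclass
class ProbeTask:
    """Per-token labels, run assignment and an eligible-token mask."""

    labels: np.ndarray
    runs: np.ndarray
    eligible: np.ndarray = None  # type: ignore[assignment]
    is_content: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.runs = np.asarray(self.runs)
        if self.eligible is None:
            self.eligible = np.ones(self.labels.shape[0], dtype=bool)
        else:
            self.eligible = np.asarray(self.eligible, dtype=bool)
        if self.is_content is not None:
            self.is_content = np.asarray(self.is_content, dtype=bool)
        n = self.labels.shape[0]
        if self.runs.shape[0] != n or self.eligible.shape[0] != n:
            raise ValueError("labels, runs and eligible mask must align")


@dataclass
class ProbeResult:
    accuracy: float
    per_fold: list[float]
    dummy_accuracy: float
    dummy_per_fold: list[float]
    n_classes: int

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "per_fold": self.per_fold,
                "dummy": self.dummy_accuracy, "n_classes": self.n_classes}


def eligibility_filter(task: ProbeTask, mode: str) -> ProbeTask:
    """Restrict the eligible-token mask (``all-tokens`` or ``content-only``).

    Masks compose idempotently: applying the same mode twice is a no-op.
    """
    if mode not in ("all-tokens", "content-only"):
        raise ValueError(f"unknown eligibility mode {mode!r}")
    eligible = task.eligible.copy()
    if mode == "content-only":
        if task.is_content is None:
            raise ValueError("task has no content-word annotation to filter on")
        eligible &= task.is_content
    meta = dict(task.metadata)
    meta["eligibility"] = mode
    return replace(task, eligible=eligible, metadata=meta)


def probe_decoding(X: EmbeddingMatrix | np.ndarray, task: ProbeTask, *,
                   C: float = 1.0, max_iter: int = 1000,
                   seed: int = 0) -> ProbeResult:
    """Run-wise cross-validated logistic decoding with a dummy baseline.

    One fold per run: train on the other runs' eligible tokens, score
    accuracy on the held-out run's eligible tokens.  Labels absent from a
    fold's training data simply contribute errors (with a warning).
    """
    feats = X.X if isinstance(X, EmbeddingMatrix) else np.asarray(X, dtype=float)
    if feats.shape[0] != task.labels.shape[0]:
        raise ValueError("embedding rows must align with task tokens")
    el = task.eligible
    if not el.any():
        raise ValueError("no eligible tokens to decode")
    run_ids = np.unique(task.runs[el])
    if run_ids.size < 2:
        raise ValueError("need at least 2 runs for run-wise cross-validation")

    per_fold, dummy_per_fold = [], []
    for held in run_ids:
        test = el & (task.runs == held)
        train = el & (task.runs != held)
        y_tr, y_te = task.labels[train], task.labels[test]
        if np.unique(y_tr).size < 2:
            raise ValueError("need at least 2 classes in training folds")
        missing = set(np.unique(y_te)) - set(np.unique(y_tr))
        if missing:
            warnings.warn(f"{len(missing)} class(es) absent from training fold "
                          f"(run {held}); they will contribute errors")
        clf = LogisticRegression(C=C, max_iter=max_iter, random_state=seed)
        clf.fit(feats[train], y_tr)
        per_fold.append(float(np.mean(clf.predict(feats[test]) == y_te)))
        dummy = DummyClassifier(strategy="most_frequent")
        dummy.fit(feats[train], y_tr)
        dummy_per_fold.append(float(np.mean(dummy.predict(feats[test]) == y_te)))

    return ProbeResult(
        accuracy=float(np.mean(per_fold)), per_fold=per_fold,
        dummy_accuracy=float(np.mean(dummy_per_fold)),
        dummy_per_fold=dummy_per_fold,
        n_classes=int(np.unique(task.labels[el]).size),
    )
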