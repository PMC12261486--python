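"""Drug-likeness classification on frozen ADME-informed embeddings (Step 2).

A small MLP is trained with binary cross-entropy to separate approved
drugs (label 1) from non-drug library compounds (label 0), reading only
the embeddings ``z`` of a *frozen* encoder — the encoder's parameters
are never touched here.  Evaluation uses the class-imbalance-aware
battery: Matthews correlation coefficient (MCC) and F1 at the fixed 0.5
threshold, and area under the precision-recall curve (AUPRC) computed as
average precision over the score ranking, reported per cross-validation
fold with mean and standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, f1_score, matthews_corrcoef

from admeseq._nn import MLP, Adam, sigmoid
from admeseq.encoders import EncoderModel

__all__ = [
    "DrugLikenessExample",
    "MLPClassifierConfig",
    "EmbeddingClassifier",
    "MetricReport",
    "train_classifier",
    "predict_score",
    "evaluate",
    "cross_validate",
    "embed_examples",
]

THRESHOLD = 0.5  # fixed decision threshold; score >= 0.5 is called a drug


@dataclass
class DrugLikenessExample:
    """One molecule: canonical key, binary drug label, frozen embedding."""

    key: str
    label: int
    embedding: np.ndarray

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        self.embedding = np.asarray(self.embedding, dtype=float)


@dataclass(frozen=True)
class MLPClassifierConfig:
    hidden: tuple[int, ...] = (128, 128)
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs_max: int = 200
    patience: int = 10
    convergence_tol: float = 1e-4
    val_fraction: float = 0.1


class EmbeddingClassifier:
    """Binary MLP head over fixed embedding vectors."""

    def __init__(self, d_in: int, cfg: MLPClassifierConfig, seed: int):
        self.d_in = d_in
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.net = MLP([d_in, *cfg.hidden, 1], rng)

    def fit(self, x: np.ndarray, y: np.ndarray) -> "EmbeddingClassifier":
        cfg = self.cfg
        n = len(x)
        rng = np.random.default_rng(self.seed + 1)
        val_n = max(1, int(round(cfg.val_fraction * n))) if n >= 10 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:val_n], perm[val_n:]
        optimizer = Adam(self.net.params, lr=cfg.learning_rate)
        best, stale = np.inf, 0
        for epoch in range(cfg.epochs_max):
            order = np.random.default_rng(self.seed + 1000 + epoch).permutation(tr_idx)
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                raw, cache = self.net.forward(x[idx])
                p = sigmoid(raw[:, 0])
                d_raw = ((p - y[idx]) / len(idx))[:, None]
                grads, _ = self.net.backward(d_raw, cache)
                optimizer.step(grads)
            monitor_idx = val_idx if val_n else tr_idx
            p = np.clip(self.predict_proba(x[monitor_idx]), 1e-7, 1 - 1e-7)
            yv = y[monitor_idx]
            loss = float(-np.mean(yv * np.log(p) + (1 - yv) * np.log(1 - p)))
            if loss < best * (1.0 - cfg.convergence_tol):
                best, stale = loss, 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.d_in:
            raise ValueError(
                f"embedding width {x.shape[1]} does not match classifier "
                f"input width {self.d_in}"
            )
        return sigmoid(self.net(x)[:, 0])


@dataclass
class MetricReport:
    """Per-fold MCC / F1 / AUPRC with mean and standard deviation."""

    per_fold: list[dict[str, float]] = field(default_factory=list)

    def _series(self, metric: str) -> np.ndarray:
        return np.array([row[metric] for row in self.per_fold])

    def mean(self, metric: str) -> float:
        return float(np.mean(self._series(metric)))

    def sd(self, metric: str) -> float:
        return float(np.std(self._series(metric), ddof=1)) if len(self.per_fold) > 1 else 0.0

    @property
    def mcc(self) -> float:
        return self.mean("mcc")

    @property
    def f1(self) -> float:
        return self.mean("f1")

    @property
    def auprc(self) -> float:
        return self.mean("auprc")

    def summary(self) -> str:
        lines = ["fold\tmcc\tf1\tauprc"]
        for i, row in enumerate(self.per_fold):
            lines.append(f"{i}\t{row['mcc']:.4f}\t{row['f1']:.4f}\t{row['auprc']:.4f}")
        lines.append(
            "mean (sd)\t"
            + "\t".join(
                f"{self.mean(m):.4f} ({self.sd(m):.4f})" for m in ("mcc", "f1", "auprc")
            )
        )
        return "\n".join(lines)


def _sorted_examples(examples: Sequence[DrugLikenessExample]) -> list[DrugLikenessExample]:
    # canonical internal order: results do not depend on caller ordering
    return sorted(examples, key=lambda e: e.key)


def train_classifier(
    examples: Sequence[DrugLikenessExample],
    folds: Mapping[str, int],
    mlp_cfg: MLPClassifierConfig | None = None,
    seed: int = 0,
) -> dict[int, EmbeddingClassifier]:
    """Train one classifier per cross-validation round.

    Round ``f`` trains on every fold except ``f``.  The encoder that
    produced the embeddings is not visible here, so it cannot be altered.
    Training folds must contain both classes.
    """
    cfg = mlp_cfg or MLPClassifierConfig()
    ordered = _sorted_examples(examples)
    fold_ids = sorted(set(folds.values()))
    x = np.stack([e.embedding for e in ordered])
    y = np.array([e.label for e in ordered], dtype=float)
    assignment = np.array([folds[e.key] for e in ordered])
    classifiers: dict[int, EmbeddingClassifier] = {}
    for f in fold_ids:
        tr = assignment != f
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"training folds for round {f} contain a single class")
        clf = EmbeddingClassifier(x.shape[1], cfg, seed=seed + f)
        clf.fit(x[tr], y[tr])
        classifiers[f] = clf
    return classifiers


def predict_score(classifier: EmbeddingClassifier, embedding: np.ndarray) -> float:
    """Drug-likeness score in [0, 1]; >= 0.5 is classified as a drug."""
    return float(classifier.predict_proba(np.asarray(embedding, dtype=float)[None, :])[0])


def evaluate(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """MCC / F1 at the 0.5 threshold plus average-precision AUPRC.

    Tied scores are grouped at a single precision-recall threshold (the
    standard average-precision convention).  A degenerate MCC denominator
    yields 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class; MCC is undefined")
    hard = (scores >= THRESHOLD).astype(int)
    return {
        "mcc": float(matthews_corrcoef(labels, hard)),
        "f1": float(f1_score(labels, hard, zero_division=0.0)),
        "auprc": float(average_precision_score(labels, scores)),
    }


def cross_validate(
    examples: Sequence[DrugLikenessExample],
    folds: Mapping[str, int],
    mlp_cfg: MLPClassifierConfig | None = None,
    seed: int = 0,
) -> tuple[MetricReport, dict[int, EmbeddingClassifier]]:
    """Full stratified CV: train per round, score the held-out fold, report."""
    ordered = _sorted_examples(examples)
    classifiers = train_classifier(ordered, folds, mlp_cfg, seed)
    x = np.stack([e.embedding for e in ordered])
    y = np.array([e.label for e in ordered])
    assignment = np.array([folds[e.key] for e in ordered])
    report = MetricReport()
    for f in sorted(classifiers):
        test = assignment == f
        scores = classifiers[f].predict_proba(x[test])
        report.per_fold.append(evaluate(scores, y[test]))
    return report, classifiers


def embed_examples(
    model: EncoderModel,
    keys: Sequence[str],
    labels: Mapping[str, int] | Sequence[int],
) -> list[DrugLikenessExample]:
    """Encode molecules with a frozen encoder into classifier examples."""
    if not isinstance(labels, Mapping):
        labels = dict(zip(keys, labels))
    z = model.encode(model.featurize_keys(keys))
    return [
        DrugLikenessExample(key=k, label=int(labels[k]), embedding=z[i])
        for i, k in enumerate(keys)
    ]
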