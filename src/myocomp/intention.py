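"""Motion-intention estimation from EMG features.

Training: labelled feature frames are buffered from instruction segments
(teacher data), standardised, and fed to a small feed-forward network that
learns the mapping from the 24-dimensional band-power feature to the motion
class.  Estimation: each frame's raw prediction passes through a
recognition-stabilization filter — a sliding modal-proportion vote that only
switches the output when one label dominates the recent window — and the
stabilised intention is mapped to a hand command.  Wrist flexion/extension
are trained as explicit classes that map to "hold", so voluntary wrist
motion never opens or closes the hand.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .features import FeatureFrame, feature_matrix
from .synthetic import LabelSchedule

logger = logging.getLogger(__name__)

LABEL_ORDER = ("rest", "grip", "open", "wrist_flex", "wrist_extend")

HAND_COMMANDS = {
    "grip": "close",
    "open": "open",
    "rest": "hold",
    "wrist_flex": "hold",
    "wrist_extend": "hold",
}


@dataclass
class TeacherDataset:
    """Labelled feature pairs buffered from taught segments."""

    X: np.ndarray
    y: np.ndarray
    label_set: tuple
    provenance: list = field(default_factory=list)  # (label, window_start_s, window_end_s)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0] or self.X.shape[0] == 0:
            raise ValueError("X and y must be non-empty with matching first dimension")
        extra = set(map(str, self.y)) - set(self.label_set)
        if extra:
            raise ValueError(f"labels outside the declared set: {sorted(extra)}")

    @property
    def n_examples(self) -> int:
        return self.X.shape[0]


def canonical_label_order(labels) -> tuple:
    """Known labels in canonical order, then unknowns in appearance order."""
    labels = list(dict.fromkeys(map(str, labels)))
    known = [l for l in LABEL_ORDER if l in labels]
    return tuple(known + [l for l in labels if l not in LABEL_ORDER])


def build_teacher_dataset(
    frames: list[FeatureFrame],
    taught_segments: LabelSchedule,
    buffer_s: float = 2.0,
    skip_s: float = 0.5,
) -> TeacherDataset:
    """Buffer labelled feature frames from instruction segments.

    For each taught segment, frames whose centre times lie in
    [start + skip_s, min(start + buffer_s, end)] receive that segment's
    label; everything else is excluded.  Skipping the first ``skip_s``
    avoids contraction-onset transients.
    """
    if not taught_segments.segments:
        raise ValueError("no teacher data: taught_segments is empty")
    if not buffer_s > skip_s >= 0:
        raise ValueError("need buffer_s > skip_s >= 0")
    times, X = feature_matrix(frames)
    rows, labels, provenance = [], [], []
    for start, end, lab in taught_segments.segments:
        w0, w1 = start + skip_s, min(start + buffer_s, end)
        mask = (times >= w0 - 1e-12) & (times <= w1 + 1e-12)
        if mask.any():
            rows.append(X[mask])
            labels.extend([lab] * int(mask.sum()))
            provenance.append((lab, w0, w1))
    if not rows:
        raise ValueError("no teacher data: no frames fell inside any taught window")
    y = np.array(labels)
    label_set = canonical_label_order(y)
    return TeacherDataset(X=np.vstack(rows), y=y, label_set=label_set, provenance=provenance)


@dataclass
class PatternModel:
    """Trained pattern-recognition function: standardise, then MLP forward pass.

    The fitted weights are stored explicitly so the model serialises to JSON
    and reloads bit-exactly; prediction is standardise -> hidden ReLU layers
    -> linear output -> argmax over the ordered class list.
    """

    classes: tuple
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    coefs: list
    intercepts: list
    seed: int
    hyperparams: dict
    train_accuracy: float = float("nan")

    @property
    def input_dim(self) -> int:
        return int(np.asarray(self.coefs[0]).shape[0])

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim:
            raise ValueError(f"feature length {X.shape[1]} != model input dimension {self.input_dim}")
        a = (X - self.scaler_mean) / self.scaler_scale
        for W, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        return a @ self.coefs[-1] + self.intercepts[-1]

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        if scores.shape[1] == 1:  # binary model: single logit column
            idx = (scores[:, 0] > 0).astype(int)
        else:
            idx = scores.argmax(axis=1)
        return np.asarray(self.classes, dtype=object)[idx].astype(str)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "coefs": [np.asarray(W).tolist() for W in self.coefs],
            "intercepts": [np.asarray(b).tolist() for b in self.intercepts],
            "seed": self.seed,
            "hyperparams": self.hyperparams,
            "train_accuracy": self.train_accuracy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatternModel":
        return cls(
            classes=tuple(d["classes"]),
            scaler_mean=np.asarray(d["scaler_mean"], dtype=float),
            scaler_scale=np.asarray(d["scaler_scale"], dtype=float),
            coefs=[np.asarray(W, dtype=float) for W in d["coefs"]],
            intercepts=[np.asarray(b, dtype=float) for b in d["intercepts"]],
            seed=int(d["seed"]),
            hyperparams=dict(d["hyperparams"]),
            train_accuracy=float(d["train_accuracy"]),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "PatternModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_pattern_model(
    dataset: TeacherDataset,
    seed: int = 0,
    hidden_layer_sizes: tuple = (16,),
    max_epochs: int = 500,
    min_per_class: int = 10,
) -> PatternModel:
    """Fit the statistical-learning stage on teacher data.

    A single-hidden-layer network (16 ReLU units by default) on standardised
    features; deterministic given ``seed``.  Non-convergence within
    ``max_epochs`` is logged as a warning but still returns the model.
    """
    labs, counts = np.unique(dataset.y, return_counts=True)
    if labs.size < 2:
        raise ValueError("training requires at least 2 classes")
    if counts.min() < min_per_class:
        worst = labs[counts.argmin()]
        raise ValueError(f"class '{worst}' has {counts.min()} examples; need >= {min_per_class}")

    mean = dataset.X.mean(axis=0)
    std = dataset.X.std(axis=0)
    scale = np.where(std > 0, std, 1.0)
    Xs = (dataset.X - mean) / scale

    clf = MLPClassifier(
        hidden_layer_sizes=hidden_layer_sizes,
        activation="relu",
        solver="adam",
        max_iter=max_epochs,
        random_state=seed,
    )
    order = {lab: i for i, lab in enumerate(dataset.label_set)}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(Xs, dataset.y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            logger.warning("pattern model did not fully converge within %d epochs", max_epochs)

    # reorder output columns to the declared label order
    perm = np.argsort([order[str(c)] for c in clf.classes_])
    coefs = [np.asarray(W, dtype=float) for W in clf.coefs_]
    intercepts = [np.asarray(b, dtype=float) for b in clf.intercepts_]
    if coefs[-1].shape[1] > 1:
        coefs[-1] = coefs[-1][:, perm]
        intercepts[-1] = intercepts[-1][perm]
        classes = tuple(str(clf.classes_[i]) for i in perm)
    else:
        classes = tuple(map(str, clf.classes_))

    model = PatternModel(
        classes=classes,
        scaler_mean=mean,
        scaler_scale=scale,
        coefs=coefs,
        intercepts=intercepts,
        seed=seed,
        hyperparams={"hidden_layer_sizes": list(hidden_layer_sizes), "max_epochs": max_epochs},
    )
    model.train_accuracy = float(np.mean(model.predict_batch(dataset.X) == dataset.y))
    return model


def predict_intention(x: np.ndarray, model: PatternModel) -> str:
    """Raw per-frame intention: argmax class of the pattern model."""
    return str(model.predict_batch(np.atleast_2d(x))[0])


@dataclass(frozen=True)
class RsfConfig:
    """Recognition-stabilization filter: modal vote over a trailing window."""

    window: int = 10
    threshold: float = 0.6

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must lie in (0, 1]")


def stabilize_intentions(
    raw, config: RsfConfig = RsfConfig(), label_order=None, initial: str = "rest"
) -> list:
    """Stabilise a raw intention stream by modal-proportion voting.

    At each frame the trailing window (up to ``config.window`` frames,
    including the current one) is examined; if the modal label's proportion
    reaches the threshold the output switches to it, otherwise the previous
    output is held.  Ties break toward the earliest label in
    ``label_order``.  Output length equals input length.
    """
    raw = [str(r) for r in raw]
    if not raw:
        raise ValueError("empty intention stream")
    order = list(label_order) if label_order is not None else list(canonical_label_order(raw))
    for lab in raw:
        if lab not in order:
            order.append(lab)
    rank = {lab: i for i, lab in enumerate(order)}
    out: list[str] = []
    prev = initial
    for i in range(len(raw)):
        window = raw[max(0, i - config.window + 1) : i + 1]
        counts: dict[str, int] = {}
        for lab in window:
            counts[lab] = counts.get(lab, 0) + 1
        modal = min(counts, key=lambda lab: (-counts[lab], rank[lab]))
        if counts[modal] / len(window) >= config.threshold - 1e-12:
            prev = modal
        out.append(prev)
    return out


def map_to_hand_command(o: str) -> str:
    """Map a stabilised intention to a hand command (close/open/hold).

    Wrist flexion and extension map to ``hold``: wrist motion is excluded
    from hand actions by construction.
    """
    try:
        return HAND_COMMANDS[str(o)]
    except KeyError:
        raise ValueError(f"unknown motion label '{o}'") from None


def command_events(commands) -> dict:
    """Count transitions into each hand command along a command stream."""
    events = {"close": 0, "open": 0, "hold": 0}
    prev = None
    for c in commands:
        if c != prev:
            events[str(c)] += 1
        prev = c
    return events


def switch_count(stream) -> int:
    """Number of label changes along a stream."""
    stream = list(stream)
    return sum(a != b for a, b in zip(stream, stream[1:]))
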