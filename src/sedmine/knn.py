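"""From-scratch k-nearest-neighbour classifier and evaluation protocol.

The training store is an ordered instance memory per classification stage
(motion or audio). Classification takes the k = 3 smallest Euclidean
distances, assigns the majority label, breaks vote ties with the single
nearest neighbour and distance ties by insertion order — all deterministic.
"""
from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import ClassificationError, SplitError

STAGE_LABELS = {
    "motion": frozenset({"still", "active"}),
    "audio": frozenset({"tv", "pc", "unknown"}),
}


@dataclass
class LabeledInstance:
    features: np.ndarray
    label: str
    insertion_index: int

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float).ravel()


@dataclass
class TrainingStore:
    """Ordered labelled instance memory for one stage."""

    stage: str
    instances: list[LabeledInstance] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stage not in STAGE_LABELS:
            raise ClassificationError(f"unknown stage {self.stage!r}")

    @property
    def n(self) -> int:
        return len(self.instances)

    @property
    def feature_length(self) -> int | None:
        return None if not self.instances else len(self.instances[0].features)

    def add(self, features, label: str) -> LabeledInstance:
        if label not in STAGE_LABELS[self.stage]:
            raise ClassificationError(
                f"label {label!r} not allowed in stage {self.stage!r}"
            )
        inst = LabeledInstance(features, label, insertion_index=self.n)
        if self.feature_length is not None and len(inst.features) != self.feature_length:
            raise ClassificationError(
                f"feature length {len(inst.features)} != store length {self.feature_length}"
            )
        self.instances.append(inst)
        return inst

    def matrix(self) -> np.ndarray:
        return np.vstack([inst.features for inst in self.instances])

    # -- JSON round-trip -------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "stage": self.stage,
            "feature_length": self.feature_length,
            "instances": [
                {"features": inst.features.tolist(), "label": inst.label}
                for inst in self.instances
            ],
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TrainingStore":
        payload = json.loads(text)
        store = cls(stage=payload["stage"])
        for rec in payload["instances"]:
            store.add(rec["features"], rec["label"])
        return store


def euclidean(x, y) -> float:
    """Plain Euclidean distance between two equal-length vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ClassificationError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(math.sqrt(np.sum((x - y) ** 2)))


def knn_classify(
    cfv, store: TrainingStore, k: int = 3
) -> tuple[str, np.ndarray, np.ndarray]:
    """Classify a feature vector against the store.

    Returns (label, neighbour insertion indices, their distances). Uses all
    instances when the store holds fewer than k.
    """
    if store.n == 0:
        raise ClassificationError("cannot classify against an empty store")
    if k < 1:
        raise ClassificationError("k must be at least 1")
    cfv = np.asarray(cfv, dtype=float).ravel()
    if len(cfv) != store.feature_length:
        raise ClassificationError(
            f"query length {len(cfv)} != store length {store.feature_length}"
        )
    dists = np.sqrt(np.sum((store.matrix() - cfv) ** 2, axis=1))
    order = np.lexsort((np.arange(store.n), dists))  # distance, then insertion
    top = order[: min(k, store.n)]
    labels = [store.instances[i].label for i in top]
    counts = Counter(labels)
    best = max(counts.values())
    winners = {lab for lab, c in counts.items() if c == best}
    label = labels[0] if len(winners) > 1 else winners.pop()
    return label, top, dists[top]


def split_dataset(
    instances: list[tuple[np.ndarray, str]],
    ratios: tuple[float, float, float] = (0.6, 0.1, 0.3),
    seed: int = 0,
):
    """Stratified train/validation/test split.

    Per label: shuffle with the seed, then cut at the cumulative ratios
    (floor for the first two cuts, remainder to test). Splits are disjoint
    and exhaustive.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise SplitError(f"ratios must sum to 1, got {ratios}")
    by_label: dict[str, list[int]] = {}
    for i, (_, label) in enumerate(instances):
        by_label.setdefault(label, []).append(i)
    for label, idxs in by_label.items():
        if len(idxs) < 3:
            raise SplitError(f"class {label!r} has only {len(idxs)} instances (< 3)")
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for label in sorted(by_label):
        idxs = np.array(by_label[label])
        rng.shuffle(idxs)
        n = len(idxs)
        # Epsilon guards binary-float slack so n divisible by 10 cuts exactly.
        n_train = int(n * ratios[0] + 1e-9)
        n_val = int(n * ratios[1] + 1e-9)
        train.extend(idxs[:n_train])
        val.extend(idxs[n_train : n_train + n_val])
        test.extend(idxs[n_train + n_val :])
    pick = lambda ids: [instances[i] for i in sorted(ids)]
    return pick(train), pick(val), pick(test)


def build_store(stage: str, pairs) -> TrainingStore:
    store = TrainingStore(stage=stage)
    for features, label in pairs:
        store.add(features, label)
    return store


def evaluate(store: TrainingStore, test_set, k: int = 3):
    """Accuracy and confusion matrix (rows = true labels, cols = predicted)."""
    if not test_set:
        raise ClassificationError("test set must be non-empty")
    labels = sorted(STAGE_LABELS[store.stage])
    index = {lab: i for i, lab in enumerate(labels)}
    confusion = np.zeros((len(labels), len(labels)), dtype=int)
    correct = 0
    for features, true_label in test_set:
        pred, _, _ = knn_classify(features, store, k=k)
        confusion[index[true_label], index[pred]] += 1
        correct += pred == true_label
    return correct / len(test_set), {"labels": labels, "matrix": confusion}
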