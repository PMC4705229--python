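"""Winner-take-all decoding and scoring.

The classifier's verdict for a presentation window is the AN cluster with
the highest spike count inside the window; a sample with no AN activity is
*undecided* and always scored as an error. Scores are single-pass test-set
accuracies; a seeded stratified k-fold splitter supports development-time
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .datasets import Dataset
from .network import SimRecord

__all__ = ["EvalResult", "classify_window", "score", "stratified_kfold"]


@dataclass
class EvalResult:
    """Per-sample predictions, accuracy, confusion counts.

    `confusion[i, j]` counts samples of true class i predicted as class j
    (classes indexed by their position in `class_set`); undecided samples
    are tallied per true class in `undecided_per_class` and never count as
    correct, so accuracy = trace(confusion) / n over all n samples.
    """

    predictions: list[int | None]
    labels: np.ndarray
    class_set: tuple[int, ...]
    accuracy: float
    confusion: np.ndarray
    undecided_per_class: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def undecided_count(self) -> int:
        return int(self.undecided_per_class.sum())

    def summary(self) -> str:
        lines = [f"accuracy\t{self.accuracy:.4f}",
                 f"undecided\t{self.undecided_count}"]
        lines.append("confusion (rows true, cols predicted): classes "
                     + ",".join(map(str, self.class_set)))
        for row in self.confusion:
            lines.append("\t".join(map(str, row)))
        return "\n".join(lines)


def classify_window(record: SimRecord, window: tuple[float, float],
                    an_partition: list[np.ndarray],
                    tie_rule: str = "lowest_index",
                    rng: np.random.Generator | None = None) -> int | None:
    """Winning class index for AN spikes inside the half-open window
    [start, end); None when every cluster is silent (undecided).

    Exact ties go to the lowest cluster index by default (reproducible) or
    to a seeded random choice with tie_rule="seeded_random".
    """
    start, end = window
    if end <= start:
        raise ValueError("window must have positive length")
    if start < 0 or end > record.duration + 1e-9:
        raise ValueError("window must lie within the recorded duration")
    an = record.spikes["AN"]
    mask = (an.times >= start) & (an.times < end)
    counts_per_neuron = np.bincount(an.neuron_ids[mask], minlength=an.n_neurons)
    counts = np.array([counts_per_neuron[idx].sum() for idx in an_partition])
    if counts.sum() == 0:
        return None
    top = counts.max()
    winners = np.flatnonzero(counts == top)
    if winners.size == 1:
        return int(winners[0])
    if tie_rule == "seeded_random":
        rng = rng or np.random.default_rng(0)
        return int(rng.choice(winners))
    return int(winners[0])


def score(predictions, labels, class_set: tuple[int, ...] | None = None) -> EvalResult:
    """Accuracy and confusion counts for a sequence of predicted class
    indices (None = undecided) against true labels."""
    labels = np.asarray(labels)
    predictions = list(predictions)
    if len(predictions) != labels.size:
        raise ValueError("predictions and labels must have equal length")
    if class_set is None:
        seen: dict[int, None] = {}
        for lab in labels.tolist():
            seen.setdefault(int(lab), None)
        class_set = tuple(seen)
    index = {c: i for i, c in enumerate(class_set)}
    k = len(class_set)
    confusion = np.zeros((k, k), dtype=np.int64)
    undecided = np.zeros(k, dtype=np.int64)
    correct = 0
    for pred, lab in zip(predictions, labels.tolist()):
        ti = index[int(lab)]
        if pred is None:
            undecided[ti] += 1
            continue
        confusion[ti, int(pred)] += 1
        if int(pred) == ti:
            correct += 1
    n = labels.size
    return EvalResult(predictions=predictions, labels=labels,
                      class_set=class_set,
                      accuracy=correct / n if n else 0.0,
                      confusion=confusion, undecided_per_class=undecided)


def stratified_kfold(dataset: Dataset, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold index splits (per-class proportions kept
    within one sample per fold); the folds partition the index set."""
    counts = dataset.class_counts()
    small = {c: n for c, n in counts.items() if n < k}
    if small:
        raise ValueError(f"classes {sorted(small)} have fewer than k={k} samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(train, test) for train, test in skf.split(dataset.samples, dataset.labels)]
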