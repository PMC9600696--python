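"""Classification metrics and iterative hard majority voting (IHMV).

Metrics treat class 2 (ADHD) as positive: accuracy is the fraction of
correct predictions and the geometric mean is
``sqrt(sensitivity * specificity)``, which drops to zero whenever one
class is fully misclassified, making it robust to class imbalance.

IHMV fuses the per-channel prediction vectors: channels are sorted by
out-of-fold accuracy (descending, ties to the lower channel index) and for
every prefix of size r = 3..C the per-record mode of the top-r predictions
forms a new voted vector, giving C - 2 voted candidates.  The final result
is the most accurate of all C + (C - 2) candidates; accuracy ties prefer a
voted vector over a single channel, then the lower index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .knn import PredictionVector

__all__ = [
    "ConfusionCounts",
    "EnsembleReport",
    "confusion",
    "accuracy",
    "geometric_mean",
    "ihmv",
]

_POSITIVE = 2  # ADHD
_NEGATIVE = 1  # healthy


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _labels_of(pred: PredictionVector | np.ndarray) -> np.ndarray:
    if isinstance(pred, PredictionVector):
        return pred.labels
    return np.asarray(pred, dtype=int)


def confusion(pred: PredictionVector | np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Confusion counts with class 2 (ADHD) as the positive class."""
    p = _labels_of(pred)
    t = np.asarray(truth, dtype=int)
    if p.shape != t.shape:
        raise ValueError(f"prediction length {p.size} != truth length {t.size}")
    if not ({_NEGATIVE, _POSITIVE} <= set(np.unique(t))):
        raise ValueError("truth must contain both classes 1 and 2")
    return ConfusionCounts(
        tp=int(np.sum((p == _POSITIVE) & (t == _POSITIVE))),
        fp=int(np.sum((p == _POSITIVE) & (t == _NEGATIVE))),
        tn=int(np.sum((p == _NEGATIVE) & (t == _NEGATIVE))),
        fn=int(np.sum((p == _NEGATIVE) & (t == _POSITIVE))),
    )


def accuracy(cc: ConfusionCounts) -> float:
    return (cc.tp + cc.tn) / cc.total


def geometric_mean(cc: ConfusionCounts) -> float:
    """sqrt(sensitivity * specificity); 0 if either recall is 0."""
    sens = cc.tp / (cc.tp + cc.fn)
    spec = cc.tn / (cc.tn + cc.fp)
    return float(np.sqrt(sens * spec))


@dataclass
class EnsembleReport:
    """Per-channel and voted metrics plus the selected final result."""

    channel_accuracy: list[float]
    channel_gm: list[float]
    voted_accuracy: list[float]
    voted_gm: list[float]
    channel_order: list[int]  # channels sorted by accuracy, best first
    final_kind: str  # "channel" or "voted"
    final_index: int  # channel index or voted-vector index (0-based)
    final_accuracy: float
    final_gm: float

    @property
    def final_tag(self) -> str:
        return f"{self.final_kind}_{self.final_index + 1}"

    def to_dict(self) -> dict:
        return {
            "channel_accuracy": self.channel_accuracy,
            "channel_gm": self.channel_gm,
            "voted_accuracy": self.voted_accuracy,
            "voted_gm": self.voted_gm,
            "channel_order": self.channel_order,
            "final": {
                "kind": self.final_kind,
                "index": self.final_index,
                "tag": self.final_tag,
                "accuracy": self.final_accuracy,
                "geometric_mean": self.final_gm,
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _mode_rows(stack: np.ndarray) -> np.ndarray:
    """Per-record mode of a (r, n) label stack; ties to the smaller label."""
    n = stack.shape[1]
    out = np.empty(n, dtype=int)
    labels = np.unique(stack)
    counts = np.stack([(stack == lab).sum(axis=0) for lab in labels])
    # argmax returns the first (smallest label) among tied counts
    out = labels[np.argmax(counts, axis=0)]
    return out


def ihmv(
    channel_preds: list[PredictionVector | np.ndarray],
    truth: np.ndarray,
) -> tuple[list[PredictionVector], EnsembleReport]:
    """Iterative hard majority voting over per-channel predictions.

    Returns the C - 2 voted prediction vectors and a report containing the
    per-channel metrics, the voted metrics and the selected final result.
    """
    C = len(channel_preds)
    if C < 3:
        raise ValueError(f"IHMV needs at least 3 prediction vectors, got {C}")
    truth = np.asarray(truth, dtype=int)
    mat = np.stack([_labels_of(p) for p in channel_preds])
    if mat.shape[1] != truth.size:
        raise ValueError("prediction vectors and truth differ in length")

    ch_cc = [confusion(mat[c], truth) for c in range(C)]
    ch_acc = [accuracy(cc) for cc in ch_cc]
    ch_gm = [geometric_mean(cc) for cc in ch_cc]
    order = sorted(range(C), key=lambda c: (-ch_acc[c], c))

    voted: list[PredictionVector] = []
    voted_acc: list[float] = []
    voted_gm: list[float] = []
    for r in range(3, C + 1):
        v = _mode_rows(mat[order[:r]])
        cc = confusion(v, truth)
        voted.append(PredictionVector(labels=v, scheme="voted"))
        voted_acc.append(accuracy(cc))
        voted_gm.append(geometric_mean(cc))

    # candidate key: (accuracy, voted beats channel, lower index)
    candidates = [("channel", c, ch_acc[c], ch_gm[c]) for c in range(C)] + [
        ("voted", i, voted_acc[i], voted_gm[i]) for i in range(len(voted))
    ]
    kind, idx, acc, gm = max(
        candidates, key=lambda t: (t[2], t[0] == "voted", -t[1])
    )
    report = EnsembleReport(
        channel_accuracy=ch_acc,
        channel_gm=ch_gm,
        voted_accuracy=voted_acc,
        voted_gm=voted_gm,
        channel_order=order,
        final_kind=kind,
        final_index=idx,
        final_accuracy=acc,
        final_gm=gm,
    )
    return voted, report
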