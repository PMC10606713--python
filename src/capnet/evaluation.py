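"""Confusion accounting and classification metrics for CAP A/B detection.

The A phase is the positive class.  Besides the usual tp/tn/fp/fn tallies a
per-subtype breakdown is kept: for each true subtype (A1, A2, A3, B) the
number of its instances predicted as A and as B.  The per-subtype
true-positive rate of an A subtype is the share of its instances predicted
as A *at all* (the classifier is binary, so subtype TPR measures binary
detection per subtype, not subtype identification); for B it is the share
correctly kept as B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from capnet.records import A_SUBTYPES, SUBTYPES

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "subtype_tpr",
    "evaluate_predictions",
    "balanced_subsample",
]


@dataclass
class ConfusionCounts:
    """Binary confusion tallies plus the per-subtype prediction split."""

    tp: int
    tn: int
    fp: int
    fn: int
    per_subtype: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_subtype_table(cls, per_subtype: dict[str, tuple[int, int]]) -> "ConfusionCounts":
        """Build binary counts from a {subtype: (predicted_A, predicted_B)} table."""
        tp = sum(per_subtype.get(s, (0, 0))[0] for s in A_SUBTYPES)
        fn = sum(per_subtype.get(s, (0, 0))[1] for s in A_SUBTYPES)
        fp, tn = per_subtype.get("B", (0, 0))
        return cls(tp=tp, tn=tn, fp=fp, fn=fn, per_subtype=dict(per_subtype))


@dataclass
class MetricsReport:
    """Accuracy, precision, recall, specificity, F1 — proportions in [0, 1]."""

    ACC: float
    PRE: float
    REC: float
    SPE: float
    F1: float

    def as_percent(self, decimals: int = 1) -> dict[str, float]:
        """Render as percentages rounded the way results tables print them."""
        return {
            k: round(100 * v, decimals)
            for k, v in self.__dict__.items()
        }


def confusion(
    pred_labels: np.ndarray,
    true_labels: np.ndarray,
    true_subtypes: np.ndarray,
) -> ConfusionCounts:
    """Tally binary predictions against truth, split by true subtype."""
    pred_labels = np.asarray(pred_labels, dtype="U1")
    true_labels = np.asarray(true_labels, dtype="U1")
    true_subtypes = np.asarray(true_subtypes, dtype="U2")
    if not (len(pred_labels) == len(true_labels) == len(true_subtypes)):
        raise ValueError("pred/true/subtype sequences must have equal length")
    implied = np.where(np.isin(true_subtypes, A_SUBTYPES), "A", "B")
    if np.any(implied != true_labels):
        raise ValueError("true_subtypes inconsistent with true_labels")

    per_subtype = {}
    for s in SUBTYPES:
        sel = true_subtypes == s
        pa = int(np.sum(pred_labels[sel] == "A"))
        pb = int(np.sum(pred_labels[sel] == "B"))
        if pa or pb:
            per_subtype[s] = (pa, pb)
    is_a = true_labels == "A"
    pred_a = pred_labels == "A"
    return ConfusionCounts(
        tp=int(np.sum(is_a & pred_a)),
        fn=int(np.sum(is_a & ~pred_a)),
        fp=int(np.sum(~is_a & pred_a)),
        tn=int(np.sum(~is_a & ~pred_a)),
        per_subtype=per_subtype,
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def metrics(c: ConfusionCounts) -> MetricsReport:
    """ACC, PRE, REC, SPE, F1 from the confusion counts.

    Undefined ratios (zero denominators) are reported as NaN with a
    warning, never silently as 0.
    """
    total = c.tp + c.tn + c.fp + c.fn
    if total == 0:
        raise ValueError("all confusion counts are zero")
    return MetricsReport(
        ACC=(c.tp + c.tn) / total,
        PRE=_ratio(c.tp, c.tp + c.fp, "precision"),
        REC=_ratio(c.tp, c.tp + c.fn, "recall"),
        SPE=_ratio(c.tn, c.tn + c.fp, "specificity"),
        F1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "F1"),
    )


def subtype_tpr(c: ConfusionCounts) -> dict[str, float]:
    """Per-subtype true-positive rate.

    For A subtypes: predicted-A share of the column; for B: predicted-B
    (correct) share.  Empty columns give NaN.
    """
    out = {}
    for s, (pa, pb) in c.per_subtype.items():
        total = pa + pb
        if total == 0:
            out[s] = float("nan")
        elif s == "B":
            out[s] = pb / total
        else:
            out[s] = pa / total
    return out


def balanced_subsample(
    labels: np.ndarray, seed: int
) -> np.ndarray:
    """Indices of a class-balanced subset: all A plus an equal random share of B.

    If B is the minority the full index set is returned with a warning.
    """
    labels = np.asarray(labels, dtype="U1")
    a_idx = np.flatnonzero(labels == "A")
    b_idx = np.flatnonzero(labels == "B")
    if len(b_idx) < len(a_idx):
        warnings.warn("fewer B than A samples; not subsampling")
        return np.arange(len(labels))
    rng = np.random.default_rng(seed)
    keep_b = rng.choice(len(b_idx), size=len(a_idx), replace=False)
    return np.sort(np.concatenate([a_idx, b_idx[keep_b]]))


def evaluate_predictions(
    pred_labels: np.ndarray,
    true_labels: np.ndarray,
    true_subtypes: np.ndarray,
    mode: str = "unbalanced",
    seed: int = 0,
) -> tuple[MetricsReport, ConfusionCounts]:
    """Metrics + confusion over a test set, balanced or unbalanced.

    ``balanced`` subsamples B instances (seeded) down to the A count before
    tallying; ``unbalanced`` keeps the natural class ratio.  The prediction
    rule is the same in both modes.
    """
    if mode not in ("balanced", "unbalanced"):
        raise ValueError("mode must be 'balanced' or 'unbalanced'")
    if len(true_labels) == 0:
        raise ValueError("empty test set")
    if mode == "balanced":
        keep = balanced_subsample(np.asarray(true_labels, dtype="U1"), seed)
        pred_labels = np.asarray(pred_labels)[keep]
        true_labels = np.asarray(true_labels)[keep]
        true_subtypes = np.asarray(true_subtypes)[keep]
    c = confusion(pred_labels, true_labels, true_subtypes)
    return metrics(c), c
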