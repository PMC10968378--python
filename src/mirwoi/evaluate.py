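"""Three-class evaluation: confusion matrix, one-vs-rest metrics, macro
averages, and concordance-by-pIF rates.

Convention: confusion-matrix rows are the PREDICTED class, columns the ACTUAL
class, in the order (108h, 120h, 144h). Display percentages round half away
from zero to 2 decimals; concordance percentages truncate to 1 decimal (the
convention used when quoting n/total rates such as 12/19 -> 63.1%).
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Sequence

import numpy as np

CLASSES = (108, 120, 144)
_CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}


def percent(x: float, ndigits: int = 2) -> float:
    """x (a fraction in [0,1]) as a percentage rounded half away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


def truncated_percent(numerator: int, denominator: int) -> float:
    """Exact rational percentage truncated (not rounded) to one decimal."""
    if denominator == 0:
        raise ZeroDivisionError("empty subset")
    return (numerator * 1000 // denominator) / 10


@dataclass
class ConfusionMatrix3:
    """3x3 counts, rows = predicted class, columns = actual class (108/120/144)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassMetrics:
    sen: float | None
    spe: float | None
    ppv: float | None
    npv: float | None


def confusion_matrix(actual: Sequence[int], predicted: Sequence[int]) -> ConfusionMatrix3:
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted must have equal length")
    counts = np.zeros((3, 3), dtype=int)
    for a, p in zip(actual, predicted):
        if a not in _CLASS_INDEX or p not in _CLASS_INDEX:
            raise ValueError(f"labels must be in {CLASSES}, got actual={a}, predicted={p}")
        counts[_CLASS_INDEX[p], _CLASS_INDEX[a]] += 1
    return ConfusionMatrix3(counts)


def one_vs_rest_counts(cm: ConfusionMatrix3, cls: int) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) for one class against the other two collapsed."""
    i = _CLASS_INDEX[cls]
    tp = int(cm.counts[i, i])
    fp = int(cm.counts[i, :].sum()) - tp
    fn = int(cm.counts[:, i].sum()) - tp
    tn = cm.total - tp - fp - fn
    return tp, fp, fn, tn


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def per_class_metrics(cm: ConfusionMatrix3, cls: int) -> ClassMetrics:
    tp, fp, fn, tn = one_vs_rest_counts(cm, cls)
    return ClassMetrics(
        sen=_ratio(tp, tp + fn),
        spe=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
    )


def macro_metrics(cm: ConfusionMatrix3) -> dict[str, float]:
    """Unweighted class means of SEN/SPE/PPV/NPV plus overall accuracy.

    Classes with an undefined metric (zero denominator) are excluded from that
    metric's mean.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per = {cls: per_class_metrics(cm, cls) for cls in CLASSES}
    out: dict[str, float] = {}
    for name in ("sen", "spe", "ppv", "npv"):
        vals = [getattr(per[cls], name) for cls in CLASSES
                if getattr(per[cls], name) is not None]
        out[name] = float(np.mean(vals))
    out["acc"] = float(np.trace(cm.counts) / cm.total)
    return out


def evaluation_report(cm: ConfusionMatrix3) -> dict:
    """JSON-ready report with counts, per-class and macro metrics (percent)."""
    per = {}
    for cls in CLASSES:
        m = per_class_metrics(cm, cls)
        per[str(cls)] = {k: (None if v is None else percent(v))
                         for k, v in vars(m).items()}
    macro = {k: percent(v) for k, v in macro_metrics(cm).items()}
    return {"counts": cm.counts.tolist(), "class_order": list(CLASSES),
            "per_class": per, "macro": macro}


@dataclass
class Concordance:
    concordant: int
    total: int

    @property
    def rate(self) -> float | None:
        return self.concordant / self.total if self.total else None

    @property
    def rate_percent(self) -> float | None:
        return truncated_percent(self.concordant, self.total) if self.total else None


def concordance_by_pif(
    predicted: Sequence[int],
    reference: Sequence[int],
    n_pif: Sequence[int],
    pif_filter: Callable[[int], bool] = lambda _: True,
) -> Concordance:
    """Agreement rate between two classifications over a pIF-filtered subset."""
    if not (len(predicted) == len(reference) == len(n_pif)):
        raise ValueError("predicted, reference and n_pif must be aligned")
    idx = [i for i, pif in enumerate(n_pif) if pif_filter(pif)]
    concordant = sum(1 for i in idx if predicted[i] == reference[i])
    return Concordance(concordant=concordant, total=len(idx))
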