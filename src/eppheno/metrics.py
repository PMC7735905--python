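"""Diagnostic-test validation statistics against a chart-review gold standard.

Implements the full 2x2 suite (sensitivity, specificity, PPV, NPV, Youden
index = sensitivity + specificity − 1, F-score = 2·PPV·sens/(PPV+sens)),
3-level management agreement with a surgical-vs-rest collapse and overall
accuracy, and Cohen's kappa with an asymptotic 95% CI.

All percentages are carried at full precision internally; display rounding is
half-up to one decimal on the percent scale (the convention of published
validation tables).  Metrics with a zero denominator are reported as
``None`` ("undefined"), never silently 0 or 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix2x2",
    "BinaryMetricsReport",
    "ManagementAgreementReport",
    "KappaReport",
    "confusion",
    "binary_metrics",
    "management_agreement",
    "management_agreement_from_matrix",
    "cohens_kappa",
    "kappa_from_table",
    "round_half_up",
]

MANAGEMENT_LEVELS = ("surgical", "medical", "unclassified")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (display convention).

    Python's builtin ``round`` is banker's rounding; validation tables round
    e.g. 88.05 up to 88.1.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """2x2 cross-tabulation of algorithm (predicted) vs chart review (gold)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one unit")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(
    pred: Mapping[str, bool], gold: Mapping[str, bool]
) -> ConfusionMatrix2x2:
    """Cross-tabulate aligned per-unit boolean labels.

    Raises ``ValueError`` if the two label sets cover different unit ids.
    """
    if set(pred) != set(gold):
        only_p = sorted(set(pred) - set(gold))[:5]
        only_g = sorted(set(gold) - set(pred))[:5]
        raise ValueError(
            f"label sets are misaligned (pred-only e.g. {only_p}, gold-only e.g. {only_g})"
        )
    tp = fp = fn = tn = 0
    for uid, p in pred.items():
        g = gold[uid]
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif g:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix2x2(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class BinaryMetricsReport:
    """2x2 test-performance statistics, percent scale, full precision.

    Fields are ``None`` when the corresponding denominator is zero.
    ``counts`` echoes each metric's (numerator, denominator) pair.
    """

    matrix: ConfusionMatrix2x2
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    youden_index: float | None
    f_score: float | None
    counts: dict = field(default_factory=dict)

    def rounded(self, ndigits: int = 1) -> dict:
        """Display values: half-up rounding at ``ndigits`` decimals."""
        return {
            k: (None if v is None else round_half_up(v, ndigits))
            for k, v in {
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "ppv": self.ppv,
                "npv": self.npv,
                "youden_index": self.youden_index,
                "f_score": self.f_score,
            }.items()
        }

    def __str__(self) -> str:
        lines = []
        for key, value in self.rounded().items():
            n, d = self.counts.get(key, (None, None))
            frac = f" ({n}/{d})" if n is not None else ""
            shown = "undefined" if value is None else f"{value:.1f}"
            lines.append(f"{key:>13}: {shown}{frac}")
        return "\n".join(lines)


def binary_metrics(cm: ConfusionMatrix2x2) -> BinaryMetricsReport:
    """Compute the 2x2 statistic suite on the percent scale.

    sensitivity = 100·tp/(tp+fn), specificity = 100·tn/(tn+fp),
    PPV = 100·tp/(tp+fp), NPV = 100·tn/(tn+fn),
    Youden = sensitivity + specificity − 100,
    F = 2·PPV·sensitivity/(PPV + sensitivity).
    A metric whose denominator is zero is ``None``; derived statistics that
    depend on an undefined component are likewise ``None``.
    """

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    sens = ratio(cm.tp, cm.tp + cm.fn)
    spec = ratio(cm.tn, cm.tn + cm.fp)
    ppv = ratio(cm.tp, cm.tp + cm.fp)
    npv = ratio(cm.tn, cm.tn + cm.fn)
    youden = None if (sens is None or spec is None) else sens + spec - 100.0
    if ppv is None or sens is None or (ppv + sens) == 0:
        f = None
    else:
        f = 2.0 * ppv * sens / (ppv + sens)
    return BinaryMetricsReport(
        matrix=cm,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        youden_index=youden,
        f_score=f,
        counts={
            "sensitivity": (cm.tp, cm.tp + cm.fn),
            "specificity": (cm.tn, cm.tn + cm.fp),
            "ppv": (cm.tp, cm.tp + cm.fp),
            "npv": (cm.tn, cm.tn + cm.fn),
        },
    )


@dataclass(frozen=True)
class ManagementAgreementReport:
    """3-level management agreement: chart review (rows) vs electronic (cols).

    ``surgical_binary`` collapses surgical vs {medical, unclassified};
    ``overall_accuracy`` is 100·trace/total.
    """

    matrix3x3: np.ndarray
    surgical_binary: BinaryMetricsReport
    overall_accuracy: float

    def __str__(self) -> str:
        header = "chart \\ electronic: " + "  ".join(MANAGEMENT_LEVELS)
        rows = [
            f"{lvl:>12}: " + "  ".join(f"{int(v):5d}" for v in self.matrix3x3[i])
            for i, lvl in enumerate(MANAGEMENT_LEVELS)
        ]
        return "\n".join(
            [header, *rows, f"overall accuracy: {round_half_up(self.overall_accuracy):.1f}",
             "surgical vs rest:", str(self.surgical_binary)]
        )


def management_agreement_from_matrix(matrix: Sequence[Sequence[int]]) -> ManagementAgreementReport:
    """Build the agreement report from a 3x3 count matrix (chart rows, electronic cols)."""
    m = np.asarray(matrix, dtype=int)
    if m.shape != (3, 3) or (m < 0).any():
        raise ValueError("expected a non-negative 3x3 count matrix")
    total = int(m.sum())
    if total < 1:
        raise ValueError("empty agreement matrix")
    tp = int(m[0, 0])
    fn = int(m[0, 1:].sum())
    fp = int(m[1:, 0].sum())
    tn = int(m[1:, 1:].sum())
    binary = binary_metrics(ConfusionMatrix2x2(tp=tp, fp=fp, fn=fn, tn=tn))
    accuracy = 100.0 * float(np.trace(m)) / total
    return ManagementAgreementReport(matrix3x3=m, surgical_binary=binary, overall_accuracy=accuracy)


def management_agreement(
    pred3: Mapping[str, str], gold3: Mapping[str, str]
) -> ManagementAgreementReport:
    """Cross-tabulate aligned 3-level management labels and derive the report.

    Labels must be in {surgical, medical, unclassified}.
    """
    if set(pred3) != set(gold3):
        raise ValueError("management label sets are misaligned")
    index = {lvl: i for i, lvl in enumerate(MANAGEMENT_LEVELS)}
    m = np.zeros((3, 3), dtype=int)
    for uid, p in pred3.items():
        g = gold3[uid]
        if p not in index or g not in index:
            raise ValueError(f"unknown management label for unit {uid}: {p!r}/{g!r}")
        m[index[g], index[p]] += 1
    return management_agreement_from_matrix(m)


@dataclass(frozen=True)
class KappaReport:
    """Cohen's kappa with 95% CI (normal approximation), truncated to [−1, 1].

    ``kappa`` is ``None`` when chance agreement is 1 (both raters constant
    and equal) — agreement is then undefined by convention.
    """

    kappa: float | None
    ci_low: float | None
    ci_high: float | None
    po: float
    pe: float
    n: int
    note: str = ""


def kappa_from_table(a: int, b: int, c: int, d: int) -> KappaReport:
    """Kappa from a 2x2 agreement table: a = both yes, b/c = discordant, d = both no."""
    n = a + b + c + d
    if n < 2:
        raise ValueError("kappa requires at least 2 units")
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    if pe == 1.0:
        return KappaReport(
            kappa=None, ci_low=None, ci_high=None, po=po, pe=pe, n=n,
            note="both raters constant and identical; kappa undefined by convention",
        )
    kappa = (po - pe) / (1.0 - pe)
    se = math.sqrt(po * (1.0 - po) / n) / (1.0 - pe)
    lo = max(-1.0, kappa - 1.959963984540054 * se)
    hi = min(1.0, kappa + 1.959963984540054 * se)
    return KappaReport(kappa=kappa, ci_low=lo, ci_high=hi, po=po, pe=pe, n=n)


def cohens_kappa(
    labels_a: Mapping[str, bool] | Sequence[bool],
    labels_b: Mapping[str, bool] | Sequence[bool],
) -> KappaReport:
    """Cohen's kappa between two aligned boolean label sets (symmetric)."""
    if isinstance(labels_a, Mapping) and isinstance(labels_b, Mapping):
        if set(labels_a) != set(labels_b):
            raise ValueError("label sets are misaligned")
        pairs = [(labels_a[k], labels_b[k]) for k in labels_a]
    else:
        la, lb = list(labels_a), list(labels_b)
        if len(la) != len(lb):
            raise ValueError("label sequences differ in length")
        pairs = list(zip(la, lb))
    a = sum(1 for x, y in pairs if x and y)
    b = sum(1 for x, y in pairs if x and not y)
    c = sum(1 for x, y in pairs if not x and y)
    d = sum(1 for x, y in pairs if not x and not y)
    return kappa_from_table(a, b, c, d)
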